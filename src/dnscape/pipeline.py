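"""End-to-end orchestration: simulate -> coverage -> nucleosome ->
accessibility -> annotation -> differential accessibility -> expression ->
report, with a machine-readable run manifest.

Every stage reads its inputs from the output directory (or from the
in-memory context of the same run), writes plain-text outputs, and records
SHA-256 checksums in the manifest; re-running with the same config and seed
reproduces identical checksums for all stages.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accessibility import combine_acrs, dns_track, normalize_dns_group, segment_track, spo_to_base, spo_track
from .annotation import classify_acr, gc_content, shuffle_controls, te_enrichment
from .core import derive_seed, track_genome
from .count_stats import window_da
from .coverage import aggregate_profile, fragment_coverage, pool_fragments
from .expression import (
    classify_cistrans,
    classify_heb,
    classify_impact,
    classify_inheritance,
    summarize_categories,
)
from .io import (
    ensure_dir,
    read_fasta,
    read_fragments_bed,
    read_gff3,
    read_tes_bed,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_fragments_bed,
    write_gff3,
    write_tes_bed,
)
from .nucleosome import call_nucleosomes, nucleosome_coverage, phasogram_nrl
from .simulate import (
    TRACK_KEYS,
    ExpressionData,
    Scenario,
    ScenarioConfig,
    build_scenario,
    sample_fragments,
    simulate_counts,
)

STAGES = (
    "simulate",
    "coverage",
    "nucleosome",
    "accessibility",
    "annotation",
    "da",
    "expression",
    "report",
)


class MissingInputError(FileNotFoundError):
    pass


class StageError(RuntimeError):
    pass


def _require(path) -> str:
    if not os.path.exists(path):
        raise MissingInputError(f"missing input file: {path}")
    return str(path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def _scenario_config(cfg: dict, seed: int) -> ScenarioConfig:
    kwargs = dict(cfg.get("scenario", {}))
    kwargs["seed"] = seed
    fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(kwargs) - fields
    if unknown:
        raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
    return ScenarioConfig(**kwargs)


def _config_hash(cfg: dict, seed: int) -> str:
    canon = yaml.safe_dump({"config": cfg, "seed": seed}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# context loading helpers (used when resuming from a later stage)


def _ctx_scenario(ctx, cfg, outdir):
    if "scenario" not in ctx:
        scen_cfg = _scenario_config(cfg, ctx["seed"])
        bundle = os.path.join(outdir, "bundle")
        _require(os.path.join(bundle, "samples.tsv"))
        scenario, truth = build_scenario(scen_cfg)
        ctx["scenario"], ctx["truth"] = scenario, truth
    return ctx["scenario"], ctx["truth"]


def _ctx_fragsets(ctx, cfg, outdir):
    if "fragsets" not in ctx:
        scenario, _ = _ctx_scenario(ctx, cfg, outdir)
        bundle = os.path.join(outdir, "bundle")
        fragsets = {}
        for sample in scenario.samples:
            name = _sample_name(sample)
            path = _require(os.path.join(bundle, f"fragments_{name}.bed"))
            genome = scenario.genomes[track_genome(sample.track_key)]
            fragsets[name] = read_fragments_bed(
                path,
                genome.chroms,
                genotype=sample.genotype,
                subgenome=sample.subgenome,
                digestion=sample.digestion,
                replicate=sample.replicate,
            )
        ctx["fragsets"] = fragsets
    return ctx["fragsets"]


def _sample_name(sample) -> str:
    return f"{sample.track_key.replace(':', '_')}_{sample.digestion}_r{sample.replicate}"


def _pooled(ctx, cfg, outdir, track_key, digestion):
    key = ("pooled", track_key, digestion)
    if key not in ctx:
        fragsets = _ctx_fragsets(ctx, cfg, outdir)
        members = [
            fs
            for name, fs in fragsets.items()
            if name.startswith(f"{track_key.replace(':', '_')}_{digestion}_")
        ]
        ctx[key] = pool_fragments(members)
    return ctx[key]


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, outdir, ctx):
    scen_cfg = _scenario_config(cfg, ctx["seed"])
    scenario, truth = build_scenario(scen_cfg)
    ctx["scenario"], ctx["truth"] = scenario, truth
    bundle = ensure_dir(os.path.join(outdir, "bundle"))
    outputs = []
    for label, genome in scenario.genomes.items():
        if genome.sequence is not None:
            path = os.path.join(bundle, f"genome_{label}.fa")
            write_fasta(genome, path)
            outputs.append(path)
    path = os.path.join(bundle, "genes.gff3")
    write_gff3([g for label in sorted(scenario.genes) for g in scenario.genes[label]], path)
    outputs.append(path)
    path = os.path.join(bundle, "tes.bed")
    write_tes_bed([t for label in sorted(scenario.tes) for t in scenario.tes[label]], path)
    outputs.append(path)

    rows = []
    fragsets = {}
    for sample in scenario.samples:
        name = _sample_name(sample)
        fs = sample_fragments(
            scenario, truth, sample, derive_seed(ctx["seed"], "fragments", name)
        )
        fragsets[name] = fs
        fpath = os.path.join(bundle, f"fragments_{name}.bed")
        write_fragments_bed(fs, fpath)
        outputs.append(fpath)
        rows.append(
            (name, sample.genotype, sample.subgenome, sample.digestion, sample.replicate, sample.n_fragments)
        )
    ctx["fragsets"] = fragsets
    path = os.path.join(bundle, "samples.tsv")
    pd.DataFrame(
        rows, columns=["sample", "genotype", "subgenome", "digestion", "replicate", "n_fragments"]
    ).to_csv(path, sep="\t", index=False)
    outputs.append(path)

    data = simulate_counts(
        truth,
        reps=scen_cfg.expression_replicates,
        seed=derive_seed(ctx["seed"], "counts"),
        library_jitter=scen_cfg.library_jitter,
    )
    ctx["expression_data"] = data
    for fname, df in (
        ("counts.tsv", data.counts),
        ("orthogroups.tsv", data.ogs),
        ("expression_samples.tsv", data.samples),
    ):
        path = os.path.join(bundle, fname)
        df.to_csv(path, sep="\t")
        outputs.append(path)
    path = os.path.join(bundle, "chroms.tsv")
    pd.DataFrame(
        [
            (label, chrom, length)
            for label, genome in sorted(scenario.genomes.items())
            for chrom, length in sorted(genome.chroms.items())
        ],
        columns=["genome", "chrom", "length"],
    ).to_csv(path, sep="\t", index=False)
    outputs.append(path)
    path = os.path.join(bundle, "truth.json")
    with open(path, "w") as fh:
        json.dump(_truth_json(truth), fh, sort_keys=True, default=_json_scalar)
    outputs.append(path)
    return outputs


def _json_scalar(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _truth_json(truth) -> dict:
    return {
        "planted_nrl": truth.planted_nrl,
        "dispersion": truth.dispersion,
        "acr_track_scale": truth.acr_track_scale,
        "planted_dyads": {
            k: {c: v.tolist() for c, v in d.items()} for k, d in truth.planted_dyads.items()
        },
        "planted_acrs": {
            label: [
                {"chrom": a.chrom, "start": a.start, "end": a.end, "kind": a.kind, "strength": a.strength}
                for a in acrs
            ]
            for label, acrs in truth.planted_acrs.items()
        },
        "planted_expression": json.loads(
            truth.planted_expression.to_json(orient="index")
        ),
    }


def _stage_coverage(cfg, outdir, ctx):
    tracks_dir = ensure_dir(os.path.join(outdir, "tracks"))
    outputs = []
    ctx["tracks"] = {}
    for key in TRACK_KEYS:
        for digestion in ("light", "heavy"):
            pooled = _pooled(ctx, cfg, outdir, key, digestion)
            full = fragment_coverage(pooled, mode="full")
            ctx["tracks"][(key, digestion, "full")] = full
            path = os.path.join(tracks_dir, f"{key.replace(':', '_')}_{digestion}.bedgraph")
            write_bedgraph(full, path)
            outputs.append(path)
            if digestion == "heavy":
                trimmed = fragment_coverage(pooled, mode="center_trimmed")
                ctx["tracks"][(key, "heavy", "trimmed")] = trimmed
    return outputs


def _ctx_track(ctx, cfg, outdir, key, digestion, kind):
    if "tracks" not in ctx or (key, digestion, kind) not in ctx.get("tracks", {}):
        pooled = _pooled(ctx, cfg, outdir, key, digestion)
        mode = "center_trimmed" if kind == "trimmed" else "full"
        ctx.setdefault("tracks", {})[(key, digestion, kind)] = fragment_coverage(pooled, mode=mode)
    return ctx["tracks"][(key, digestion, kind)]


def _stage_nucleosome(cfg, outdir, ctx):
    out = ensure_dir(os.path.join(outdir, "nucleosome"))
    outputs = []
    scenario, truth = _ctx_scenario(ctx, cfg, outdir)
    fragsets = _ctx_fragsets(ctx, cfg, outdir)
    rows = []
    for key in TRACK_KEYS:
        trimmed = _ctx_track(ctx, cfg, outdir, key, "heavy", "trimmed")
        calls = call_nucleosomes(trimmed)
        genome = scenario.genomes[track_genome(key)]
        nc = nucleosome_coverage(calls, genome.total_length)
        bed = pd.DataFrame(
            [
                (c.chrom, c.start, c.end, c.label, round(1000 * c.height_score), "+")
                for c in calls
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        path = os.path.join(out, f"calls_{key.replace(':', '_')}.bed")
        write_bed(bed, path)
        outputs.append(path)
        reps = [
            fs
            for name, fs in fragsets.items()
            if name.startswith(f"{key.replace(':', '_')}_heavy_")
        ]
        try:
            ph = phasogram_nrl(reps)
            nrl, nrl_se = ph.nrl, ph.nrl_se
            pd.DataFrame(
                {"lag": ph.lags, "count": ph.counts, "smoothed": ph.smoothed}
            ).to_csv(os.path.join(out, f"phasogram_{key.replace(':', '_')}.tsv"), sep="\t", index=False)
            outputs.append(os.path.join(out, f"phasogram_{key.replace(':', '_')}.tsv"))
        except Exception as exc:  # estimation failure carries on with NaN
            nrl, nrl_se = np.nan, np.nan
        n_w = sum(1 for c in calls if c.label == "W")
        rows.append(
            (key, len(calls), n_w, round(nc, 3), round(nrl, 2), round(nrl_se, 2), truth.planted_nrl[key])
        )
    path = os.path.join(out, "summary.tsv")
    pd.DataFrame(
        rows,
        columns=["track", "n_calls", "n_well_positioned", "nc_percent", "nrl_bp", "nrl_sd", "planted_nrl"],
    ).to_csv(path, sep="\t", index=False)
    outputs.append(path)
    return outputs


def _stage_accessibility(cfg, outdir, ctx):
    out = ensure_dir(os.path.join(outdir, "accessibility"))
    outputs = []
    bc = float(cfg.get("bc", 6.0))
    spo_bc = float(cfg.get("spo_bc", 6.0))
    dns = {}
    for key in TRACK_KEYS:
        light = _ctx_track(ctx, cfg, outdir, key, "light", "full")
        heavy = _ctx_track(ctx, cfg, outdir, key, "heavy", "full")
        dns[key] = dns_track(light, heavy)
    normed = normalize_dns_group([dns[k] for k in TRACK_KEYS])
    dns = dict(zip(TRACK_KEYS, normed))
    ctx["dns"] = dns
    ctx["acrs"] = {}
    rows = []
    for key in TRACK_KEYS:
        safe = key.replace(":", "_")
        path = os.path.join(out, f"dns_{safe}.bedgraph")
        write_bedgraph(dns[key], path)
        outputs.append(path)
        segments = segment_track(dns[key], bc=bc, two_sided=True)
        msf = [s for s in segments if s.polarity == "sensitive"]
        mrf = [s for s in segments if s.polarity == "resistant"]
        pooled_light = _pooled(ctx, cfg, outdir, key, "light")
        spo = spo_track(pooled_light)
        path = os.path.join(out, f"spo_{safe}.bedgraph")
        write_bedgraph(spo, path)
        outputs.append(path)
        # SPO is segmented per genome, never quantile-normalized across them
        spo_segments = [
            s for s in segment_track(spo_to_base(spo), bc=spo_bc, two_sided=False)
            if s.polarity == "sensitive"
        ]
        acrs = combine_acrs(msf, spo_segments)
        ctx["acrs"][key] = acrs
        for name, segs in (("msf", msf), ("mrf", mrf), ("spo_acr", spo_segments)):
            bed = pd.DataFrame(
                [(s.chrom, s.start, s.end, s.polarity, round(abs(s.peak_score), 2)) for s in segs],
                columns=["chrom", "start", "end", "name", "score"],
            )
            path = os.path.join(out, f"{name}_{safe}.bed")
            write_bed(bed, path)
            outputs.append(path)
        bed = pd.DataFrame(
            [(a.chrom, a.start, a.end, a.source, round(abs(a.peak_score), 2)) for a in acrs],
            columns=["chrom", "start", "end", "name", "score"],
        )
        path = os.path.join(out, f"acrs_{safe}.bed")
        write_bed(bed, path)
        outputs.append(path)
        rows.append((key, len(msf), len(mrf), len(spo_segments), len(acrs), sum(a.width for a in acrs)))
    path = os.path.join(out, "summary.tsv")
    pd.DataFrame(
        rows, columns=["track", "n_msf", "n_mrf", "n_spo", "n_acrs", "acr_bp"]
    ).to_csv(path, sep="\t", index=False)
    outputs.append(path)
    return outputs


def _ctx_acrs(ctx, cfg, outdir, key):
    if "acrs" not in ctx or key not in ctx.get("acrs", {}):
        safe = key.replace(":", "_")
        path = _require(os.path.join(outdir, "accessibility", f"acrs_{safe}.bed"))
        from .io import read_bed

        df = read_bed(path, names=("chrom", "start", "end", "name", "score"))
        ctx.setdefault("acrs", {})[key] = df
    return ctx["acrs"][key]


def _stage_annotation(cfg, outdir, ctx):
    out = ensure_dir(os.path.join(outdir, "annotation"))
    outputs = []
    scenario, truth = _ctx_scenario(ctx, cfg, outdir)
    n_perm = int(cfg.get("n_perm", 1000))
    gc_rows = []
    for key in TRACK_KEYS:
        safe = key.replace(":", "_")
        acrs = _ctx_acrs(ctx, cfg, outdir, key)
        glabel = track_genome(key)
        genes = scenario.genes[glabel]
        genome = scenario.genomes[glabel]
        ann = classify_acr(acrs, genes)
        if genome.sequence is not None:
            ann["gc_fraction"] = gc_content(ann, genome.sequence)
            for space, sub in (
                ("distal_space", ann[ann["proximity"] == "distal"]),
                ("genic_proximal_space", ann[ann["proximity"] != "distal"]),
            ):
                if not len(sub):
                    continue
                shuf = shuffle_controls(
                    sub, space, genes, genome.chroms, 1,
                    derive_seed(ctx["seed"], "gc_shuffle", key, space),
                )[0]
                gc_rows.append(
                    (key, space, float(np.nanmean(gc_content(sub, genome.sequence))),
                     float(np.nanmean(gc_content(shuf, genome.sequence))))
                )
        path = os.path.join(out, f"acrs_annotated_{safe}.tsv")
        ann.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        enr = te_enrichment(
            acrs, scenario.tes[glabel], genes, genome.chroms,
            n_perm=n_perm, seed=derive_seed(ctx["seed"], "te_enrichment", key),
        )
        path = os.path.join(out, f"te_enrichment_{safe}.tsv")
        enr.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    if gc_rows:
        path = os.path.join(out, "gc_vs_shuffled.tsv")
        pd.DataFrame(
            gc_rows, columns=["track", "space", "acr_gc", "shuffled_gc"]
        ).to_csv(path, sep="\t", index=False)
        outputs.append(path)
    return outputs


def _stage_da(cfg, outdir, ctx):
    out = ensure_dir(os.path.join(outdir, "da"))
    outputs = []
    window = int(cfg.get("da_window", 200))
    fragsets = _ctx_fragsets(ctx, cfg, outdir)

    def sets_for(track_key):
        prefix = track_key.replace(":", "_") + "_"
        return [fs for name, fs in fragsets.items() if name.startswith(prefix)]

    contrasts = []
    for key in TRACK_KEYS:
        contrasts.append((f"light_vs_heavy_{key}", "light_vs_heavy_within", sets_for(key)))
    for sub, diploid in (("At", "A2"), ("Dt", "D5")):
        contrasts.append(
            (f"hybridization_{sub}", "hybridization", sets_for(f"F1:{sub}") + sets_for(diploid))
        )
        contrasts.append(
            (f"polyploidization_{sub}", "polyploidization", sets_for(f"AD1:{sub}") + sets_for(f"F1:{sub}"))
        )
    rows = []
    for name, kind, sets in contrasts:
        res = window_da(sets, kind, window=window, alpha=float(cfg.get("alpha", 0.05)))
        path = os.path.join(out, f"regions_{name}.tsv")
        res.regions.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        rows.append((name, kind, len(res.regions), res.bp_increase, res.bp_decrease))
    path = os.path.join(out, "summary.tsv")
    pd.DataFrame(
        rows, columns=["contrast", "kind", "n_regions", "bp_increase", "bp_decrease"]
    ).to_csv(path, sep="\t", index=False)
    outputs.append(path)
    return outputs


def _ctx_expression(ctx, cfg, outdir):
    if "expression_data" not in ctx:
        bundle = os.path.join(outdir, "bundle")
        counts = pd.read_csv(_require(os.path.join(bundle, "counts.tsv")), sep="\t", index_col=0)
        samples = pd.read_csv(
            _require(os.path.join(bundle, "expression_samples.tsv")), sep="\t", index_col=0
        )
        ogs = pd.read_csv(_require(os.path.join(bundle, "orthogroups.tsv")), sep="\t", index_col=0)
        ctx["expression_data"] = ExpressionData(counts=counts, samples=samples, ogs=ogs)
    return ctx["expression_data"]


def _stage_expression(cfg, outdir, ctx):
    out = ensure_dir(os.path.join(outdir, "expression"))
    outputs = []
    data = _ctx_expression(ctx, cfg, outdir)
    alpha = float(cfg.get("alpha", 0.05))
    frames = {}
    for genotype in ("F1", "AD1"):
        frames[f"inheritance_{genotype}"] = classify_inheritance(data, genotype, alpha)[["inheritance"]]
        heb = classify_heb(data, genotype, alpha)
        frames[f"heb_{genotype}"] = heb[["B", "fdr_q", "direction"]].rename(
            columns={"B": "B" if genotype == "F1" else "Bp", "fdr_q": f"q_{genotype}"}
        )
    cistrans = classify_cistrans(data, alpha)
    impact = classify_impact(data, alpha)
    table = pd.concat(
        [frames["inheritance_F1"].rename(columns={"inheritance": "inheritance_F1"}),
         frames["inheritance_AD1"].rename(columns={"inheritance": "inheritance_AD1"}),
         frames["heb_F1"], frames["heb_AD1"],
         cistrans[["A", "A_minus_B", "category"]].rename(columns={"category": "cistrans"}),
         impact[["Hr", "Pr", "Wr", "sig_Hr", "sig_Pr", "sig_Wr"]]],
        axis=1,
    )
    path = os.path.join(out, "classification.tsv")
    table.to_csv(path, sep="\t")
    outputs.append(path)
    ctx["classification"] = table
    summaries = []
    for col in ("inheritance_F1", "inheritance_AD1", "cistrans"):
        s = summarize_categories(table[col])
        s.insert(0, "classification", col)
        summaries.append(s.reset_index(names="category"))
    path = os.path.join(out, "category_summary.tsv")
    pd.concat(summaries, ignore_index=True).to_csv(path, sep="\t", index=False)
    outputs.append(path)
    return outputs


def _stage_report(cfg, outdir, ctx):
    out = outdir
    outputs = []
    scenario, truth = _ctx_scenario(ctx, cfg, outdir)
    flank = int(cfg.get("profile_flank", 1000))
    profile_rows = []
    if "dns" in ctx:
        for key in TRACK_KEYS:
            glabel = track_genome(key)
            anchors = [(g.chrom, g.tss, g.strand) for g in scenario.genes[glabel]]
            prof = aggregate_profile(ctx["dns"][key], anchors, flank=flank)
            profile_rows.append(
                pd.DataFrame(
                    {"track": key, "offset": prof.offsets, "mean_dns": prof.mean[0],
                     "ci_half": prof.ci_half[0]}
                )
            )
        path = os.path.join(out, "tss_dns_profiles.tsv")
        pd.concat(profile_rows, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6f")
        outputs.append(path)
    lines = ["# dnscape run report", ""]
    for stage_file, title in (
        (os.path.join(out, "nucleosome", "summary.tsv"), "Nucleosome organization"),
        (os.path.join(out, "accessibility", "summary.tsv"), "Accessible chromatin"),
        (os.path.join(out, "da", "summary.tsv"), "Differential accessibility"),
        (os.path.join(out, "expression", "category_summary.tsv"), "Expression categories"),
    ):
        if os.path.exists(stage_file):
            lines += [f"## {title}", "", pd.read_csv(stage_file, sep="\t").to_markdown(index=False), ""]
    path = os.path.join(out, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    outputs.append(path)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "coverage": _stage_coverage,
    "nucleosome": _stage_nucleosome,
    "accessibility": _stage_accessibility,
    "annotation": _stage_annotation,
    "da": _stage_da,
    "expression": _stage_expression,
    "report": _stage_report,
}


def run_pipeline(config, outdir, seed: int = 0, from_stage=None, until_stage=None) -> dict:
    """Run the pipeline and return the manifest (also written to disk).

    ``from_stage`` skips earlier stages (their on-disk outputs become
    required inputs); ``until_stage`` stops after the named stage.  A stage
    failure raises :class:`StageError` naming the stage; outputs of completed
    stages are retained.
    """
    cfg = load_config(config)
    ensure_dir(outdir)
    for s in (from_stage, until_stage):
        if s is not None and s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages = list(STAGES)
    if until_stage is not None:
        stages = stages[: STAGES.index(until_stage) + 1]
    if from_stage is not None:
        stages = [s for s in stages if STAGES.index(s) >= STAGES.index(from_stage)]
    ctx = {"seed": int(seed)}
    manifest_path = os.path.join(outdir, "manifest.json")
    manifest = {
        "config_hash": _config_hash(cfg, int(seed)),
        "seed": int(seed),
        "version": __version__,
        "stages": {},
    }
    if from_stage is not None and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            prev = json.load(fh)
        manifest["stages"].update(prev.get("stages", {}))
    for name in stages:
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[name](cfg, outdir, ctx)
        except MissingInputError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "outputs": {os.path.relpath(p, outdir): _sha256(p) for p in sorted(map(str, outputs))},
            "wall_time_s": round(time.time() - t0, 3),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def manifest_checksums(manifest: dict) -> dict:
    """Stage -> output checksum map, dropping wall times (for comparisons)."""
    return {name: dict(info["outputs"]) for name, info in manifest["stages"].items()}
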