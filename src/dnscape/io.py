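"""Plain-text genomic format I/O: FASTA, GFF3, BED, BedGraph, TSV.

All writers emit deterministic byte-for-byte output (fixed float formats,
sorted chromosome order) so pipeline re-runs can be checksum-compared.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import GeneModel, Genome, TEInterval

_FASTA_WIDTH = 80


def write_fasta(genome: Genome, path) -> None:
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    with open(path, "w") as fh:
        for chrom in sorted(genome.chroms):
            fh.write(f">{chrom}\n")
            seq = genome.sequence[chrom]
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_fasta(path) -> dict:
    """FASTA -> dict of chrom -> sequence string."""
    seqs: dict = {}
    name = None
    parts: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_gff3(genes, path, source: str = "dnscape") -> None:
    """Write gene models as GFF3 (converting to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path) -> list:
    genes: dict = {}
    exons: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            info = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[info["ID"]] = (chrom, int(start) - 1, int(end), strand)
            elif ftype == "exon":
                exons.setdefault(info["Parent"], []).append((int(start) - 1, int(end)))
    out = []
    for gid, (chrom, s, e, strand) in genes.items():
        out.append(
            GeneModel(chrom, s, e, strand, gid, exons=tuple(sorted(exons.get(gid, []))))
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    """Write a DataFrame with at least chrom/start/end as BED (no header)."""
    cols = cols or [c for c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names))
    df.columns = list(names)[: df.shape[1]] + [
        f"col{i}" for i in range(len(names), df.shape[1])
    ]
    return df


def write_tes_bed(tes, path) -> None:
    rows = [(t.chrom, t.start, t.end, t.superfamily, t.family) for t in tes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_tes_bed(path) -> list:
    df = read_bed(path, names=("chrom", "start", "end", "superfamily", "family"))
    return [
        TEInterval(r.chrom, int(r.start), int(r.end), r.superfamily, r.family)
        for r in df.itertuples()
    ]


def write_bedgraph(track, path) -> None:
    """Run-length compressed BedGraph with fixed 6-decimal values."""
    step = getattr(track, "step", 1)
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            v = np.asarray(track.data[chrom], dtype=float)
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0) + 1
            starts = np.r_[0, change]
            ends = np.r_[change, v.size]
            for s, e, val in zip(starts, ends, v[starts]):
                if val == 0:
                    continue
                fh.write(f"{chrom}\t{s * step}\t{e * step}\t{val:.6f}\n")


def write_fragments_bed(fragset, path) -> None:
    frames = []
    for chrom in sorted(fragset.fragments):
        arr = fragset.fragments[chrom]
        frames.append(pd.DataFrame({"chrom": chrom, "start": arr[:, 0], "end": arr[:, 1]}))
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path, chrom_lengths, **meta):
    from .coverage import FragmentSet

    df = read_bed(path)
    frags = {
        chrom: np.asarray(sub[["start", "end"]], dtype=np.int64)
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    return FragmentSet(fragments=frags, chrom_lengths=dict(chrom_lengths), **meta)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
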