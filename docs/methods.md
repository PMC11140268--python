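# Methods

`dnscape` implements a differential micrococcal-nuclease sensitivity
(DNS-seq) analysis stack for comparing chromatin organization and duplicated
gene expression across two diploid genomes (A and D), their F1 hybrid and an
allopolyploid (AD1) carrying At and Dt subgenomes.  All components run
end-to-end on synthetic scenarios with planted ground truth, so every
estimator in the package has a recovery test against known values.

## The measurement model

A DNS-seq experiment digests fixed chromatin with micrococcal nuclease at
two titrations.  The *heavy* digest liberates mononucleosome-sized fragments
(~147 bp), so fragment midpoints report nucleosome dyad positions.  The
*light* digest additionally recovers "fragile" nucleosomes and
subnucleosome-sized particles (transcription-factor footprints); its small
fragments (0–130 bp) concentrate in accessible chromatin.  Three derived
signals are used throughout:

* **RPM coverage** — per-base fragment depth scaled by 1e6 / fragment count.
  For nucleosome calling, fragments shorter than 260 bp are first replaced
  by a 50 bp window centred on their midpoint (midpoint = floor((start +
  end)/2)); fragments of 260 bp or more are discarded in that mode.
* **DNS score** — light minus heavy RPM coverage per base.  Positive values
  are MNase-*sensitive* (open), negative values *resistant*.  For
  cross-genome comparisons the DNS tracks of all (sub)genomes are
  quantile-normalized together.
* **SPO** (subnucleosomal particle occupancy) — midpoints of ≤130 bp
  light-digest fragments counted into 21 bp windows sliding every 5 bp,
  scaled to RPM.  SPO is deliberately *never* quantile-normalized across
  genomes — its signal is sparse and rank-flattening would destroy it — so
  SPO segmentation runs per genome.

## Nucleosome organization

**Peak calling.**  The center-trimmed heavy track is low-pass filtered by
keeping the lowest 2% of Fourier components; local maxima above the 35th
percentile of the nonzero filtered signal seed 147 bp candidate peaks, and
candidates overlapping by ≥50 bp are merged.  Calls wider than 150 bp are
labelled *overlapping* (≥2 merged dyads).

**W/F scores.**  Published pipelines score peaks with an external package
whose scoring formulas are not restated here; `dnscape` defines two explicit
surrogates.  `height_score` is the empirical-CDF rank of the summit's
filtered value among all nonzero filtered values genome-wide.
`width_score = 1 − fwhm/147`, where `fwhm` counts positions within summit
± 73 bp at or above half the summit value on the *lightly smoothed raw*
coverage (11 bp running mean).  Shape is read from the raw profile because
the detection filter (cut-off wavelength 100 bp) blurs sharp and fuzzy
peaks toward the same width; the raw profile keeps them apart.  A call is
well-positioned (W) when `height_score > 0.6` and `width_score > 0.4`,
otherwise fuzzy (F).  With the generator's jitter settings (σ = 10 bp for
well-positioned arrays, 40 bp for fuzzy ones) the two populations fall on
opposite sides of the 0.6/0.4 thresholds: ~98% of σ=10 dyads and ~15% of
σ=40 dyads are classed W at reference depth.

**NC** (nucleosome coverage) is the percentage of the genome covered by the
union of calls.  **NRL** (nucleosome repeat length) is estimated from the
phasogram — the histogram of pairwise distances between fragment midpoints,
computed exactly per chromosome via FFT autocorrelation of the midpoint
counts (lags 50–1500 bp, 21 bp moving-average smoothing).  Peaks with
prominence ≥5% of the histogram's dynamic range are fit by ordinary least
squares of peak position against peak index; the slope is the NRL.  With
replicates, the NRL is estimated per replicate and reported as mean ± SD.

## Accessible chromatin

Segmentation is a deliberately simple, fully specified stand-in for an
external genomic segmentation algorithm.  A track is robustly standardized
(median and 1.4826×MAD of its nonzero values; the SD of nonzero values
substitutes when the MAD degenerates to 0 on discrete tracks), smoothed with
a 21 bp running mean, and thresholded at the *biological cutoff* BC — the
number of robust SD units above background (default 6.0).  Runs separated by
≤10 bp merge; runs shorter than 10 bp are dropped.  Positive segments are
MNase-sensitive footprints (MSFs), negative ones resistant footprints
(MRFs).  Sensitive MSF and SPO segments are union-merged into the final
accessible chromatin regions (ACRs), with the source (MSF / SPO / combined)
recorded per merged interval.

The default synthetic scenario plants 150 ACRs per genome (200 bp wide,
40% within 1 kb upstream of a TSS, the rest >2 kb from any gene) with a
subnucleosomal midpoint density 20× background and a 0.3× survival of
mononucleosomes inside ACRs ("fragile" depletion).  At the reference depth
(two replicates of 5×10⁵ light fragments over 2 Mb) this puts ACR interiors
8–10 robust SD above the DNS background — i.e. "strong" ACRs are defined
relative to the BC = 6 threshold used to call them.  At 10× density the
interiors sit near z ≈ 5 and are undetectable at BC = 6 by construction;
this arithmetic (amplitude ≈ subnucleosomal depth − mononucleosome dilution,
background scale ≈ phasing oscillation + counting noise) fixed the default
strength before any recovery figures were produced.

## Annotation and TE enrichment

ACRs are classed genic (≥1 bp gene-body overlap), proximal (within 2 kb of
a gene) or distal (>2 kb), and subcategorized by position relative to the
nearest gene: promoter (<1 kb, 1–2 kb, 2–3 kb upstream of the TSS), exon,
intron, downstream (same bins past the TTS), or intergenic (>3 kb both
sides).  Distances are half-open gap lengths between intervals; when two
genes compete, the nearer TSS wins and exact ties go to the lower gene
coordinate, making the labelling a deterministic total function (validated
against a brute-force oracle).

GC content is (G+C)/(A+C+G+T) per interval, ambiguous bases excluded.
Shuffled controls preserve each interval's length and chromosome and draw
uniformly from the allowed space — distal space excludes gene bodies plus
2 kb flanks, genic/proximal space is restricted to them — by direct sampling
over valid start positions (no rejection loop, so infeasible requests fail
immediately with the space deficit named).

TE enrichment per superfamily is `log2(observed / permuted-mean)` of the
ACR bp proportion overlapping the superfamily (element-wise proportions are
reported alongside), with the null from composition-matched shuffles
(distal and genic/proximal subsets shuffled in their own spaces; default
n = 1000).  Permutation p-values are two-sided with a +1 pseudo-count.  TE
*families* additionally get a hypergeometric upper-tail test of overlap bp
against the genome background.  Planting a k-fold thinning of ACR placement
inside TEs yields an expected enrichment of `log2((1/k) / (1 − (1−1/k)·p))`
where p is the TE bp share of the genome — the oracle used by the recovery
tests; it approaches −log2(k) only as p → 0.

## Count statistics

The package carries its own negative-binomial testing stack rather than
depending on an external differential-expression framework: TMM
normalization factors (reference = deepest library, 30%/5% M/A trimming,
precision weights, geometric-mean-1 scaling); per-unit method-of-moments NB
dispersion shrunk 50/50 toward a fitted `a + b/mean` trend (the trend is fit
on *unclipped* moment estimates — clipping first would bias near-Poisson
data conservative); and Wald tests on log2 fold changes of group means
(+0.5 normalized pseudo-count) for two-group and 2×2 interaction contrasts,
with Benjamini–Hochberg correction across units.  Measured calibration at
the reference design (2,000 units, 3 vs 3): type-I error 0.03–0.05 at
nominal 0.05 on Poisson nulls, ~0.06 on NB(φ=0.05) nulls, power ~1.0 at
|log2FC| = 2, mean 200, φ = 0.05.

Windowed differential accessibility counts fragment midpoints into
non-overlapping windows (default 200 bp), TMM-normalizes, and tests
light-vs-heavy within a genotype, the hybridization contrast
(F1:light−heavy vs diploid:light−heavy) and the polyploidization contrast
(AD1 vs F1) as interaction Walds; adjacent significant windows of the same
direction merge into regions, summarized as total bp increased/decreased.

Known limitation: with ≥40% one-directionally differential units between
two conditions, TMM's trimmed mean is contaminated and normalized fold
changes retain a few-percent bias.  This is inherent to composition-based
normalization; the estimator-consistency tests therefore use mostly
conserved compositions (≥70% null), which is also the realistic regime.

## Duplicated-gene expression classification

For each ortho-homoeolog group (OG; one gene each for A2, D5, F1:At, F1:Dt,
AD1:At, AD1:Dt) the package estimates `A = log2(A2/D5)` (parental
divergence), `B = log2(At/Dt)` in the F1 and `Bp` in AD1 (homoeolog
expression bias, HEB).  Cross-genotype normalization uses TMM on the
OG-aligned total matrix (homoeolog counts summed for F1/AD1); homoeolog
ratios are normalization-free because At and Dt share libraries.

**Inheritance** of total (At+Dt) expression tests T against A2, D5 and a
mid-parent formed per replicate as the rounded mean of size-factor
normalized parental counts.  Decision table (precedence: transgressive,
then ELD, then additive): significantly above (below) both parents →
transgressive up (down); equivalent to one parent but different from the
other and from mid-parent → ELD toward that parent; not different from
mid-parent → additive; residual patterns → other_nonadditive.
"Statistically equivalent" means non-rejection at BH-FDR 0.05 — absence of
evidence, not a TOST equivalence test; this is the standard operational
choice and its consequences are visible in the recovery numbers below.

**Cis/trans decomposition** follows the classic allele-specific framework:
cis = B, trans = A − B, with A − B tested as the 2×2 interaction contrast.
The significance/sign triple (A, B, A−B) maps totally onto {cis only, trans
only, cis+trans enhancing, cis+trans compensating, compensatory, conserved}
plus an `ambiguous` residual for inconsistent triples (the mapping is
enumeration-tested over all 64 patterns).

**Evolutionary impact**: Hr = B − A (hybridization), Pr = Bp − A
(allopolyploidization), Wr = Bp − B (genome doubling), each tested as an
interaction contrast; Hr + Wr = Pr holds exactly on point estimates because
all three derive from the same group means.  Non-significant Hr (Pr) is
flagged as parental legacy.  A consensus hook intersects labels across
classification runs (e.g. different mapping strategies), marking
disagreements `inconsistent`.

**Power at the reference conditions** (2,000 OGs, 3 replicates, φ = 0.05,
|effects| = 2): additive and transgressive categories recover at ≥0.97,
HEB power ≈ 0.99 with ≤3% false bias on nulls, cis-vs-trans cross-confusion
≈ 0.  ELD recovers at only ~0.72–0.86: the ELD-defining offset between
total and mid-parent expression is `log2(2·2^A/(1+2^A))` ≈ 0.68 when
|A| = 2 (bounded by 1.0 for any A), and the Wald SE of that contrast at
n = 3, φ = 0.05 is ≈ 0.25 log2 units, capping detection power near 0.6–0.85
at FDR 0.05 regardless of the test used.  Missed ELD OGs fall back to
"additive".  This is a property of the study conditions, not of the
implementation, and is reported honestly by the acceptance checks.

## Synthetic-data generator

The generator's defaults define the reference study conditions: two 1 Mb
chromosomes per genome; 80 genes (2 kb, ≥2 kb apart) per chromosome;
planted NRLs of 198/196 bp in the diploid A/D genomes (matching the F1) and
200/199 bp in AD1, echoing the observation that nucleosome spacing is wider
in the larger A genome and widens after allopolyploidy; 50% of nucleosome
arrays well-positioned (σ = 10 bp dyad jitter) and 50% fuzzy (σ = 40 bp);
heavy fragments ~N(147, 10) truncated to [100, 200] bp; light digests with
35% subnucleosomal fragments (uniform 30–130 bp) and 10% uniform
background; TE intervals (6 superfamilies with lognormal lengths) rejected
with probability 0.9 when overlapping a planted ACR; and the expression
design described above with a 60/10/10/10/10 inheritance mix, half of OGs
cis/trans-divergent, and 10% carrying a genome-doubling shift (Wr ≠ 0).
Homoeolog read assignment is exact (no mapping ambiguity) and sequences are
i.i.d. nucleotides at a configurable GC fraction — so passing tests
demonstrate estimator correctness under the generative model, not
robustness to mapping bias, sequence composition effects, or biological
covariance structure, none of which are modelled.  All randomness flows
through per-operation seeds derived stably from a single scenario seed.

## Numerical and reproducibility choices

* Coordinates are 0-based half-open internally; GFF3 converts on I/O.
  Fragment midpoints round down.  BedGraph output is run-length compressed
  with fixed 6-decimal values so re-runs are checksum-identical.
* Quantile normalization resolves ties by averaging target values over the
  tied rank span by default (order-independent); the cross-genome DNS path
  uses stable-rank assignment instead, which guarantees exactly identical
  sorted value multisets across genomes.  With unequal genome lengths the
  reference distribution is formed by linear rank interpolation, and
  idempotence is exact only for equal lengths.
* The pipeline writes a manifest with SHA-256 checksums of every stage
  output; identical config + seed reproduces identical checksums.  Stages
  are resumable (`--from/--until`); a deleted intermediate fails with the
  missing path named.
* Reference problem sizes (2 × 1 Mb genomes, 5×10⁵ fragments per library,
  2,000 OGs) keep a full pipeline run around a minute on one CPU while
  leaving ≥5,000 nucleosomes per chromosome for stable phasograms.
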