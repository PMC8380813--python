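# Methods

This note documents the models, estimators and numerical choices behind
`nicscall`, what the synthetic cohort does and does not emulate, and the
known limitations.

## Problem setting

An IVF embryo at day 5/6 has two lineages: the inner cell mass (ICM, future
fetus) and the trophectoderm (TE, future placenta). Three sequencing assays
probe its chromosomal state: the whole embryo (gold standard), a 3–5-cell TE
biopsy (PGT-A), and cell-free DNA from the spent culture medium (NICS).
All three are whole-genome amplified (MALBAC), sequenced to ~2 million
reads, counted in 1 Mb bins, and called for chromosome-level copy number.
The scientific questions are (a) how faithfully each screening assay
reproduces the whole-embryo ploidy and (b) whether NICS can rank embryos
for transfer.

## Genome model

Coordinates are 0-based half-open everywhere; on disk the BED dialect is
used. Chromosome order is fixed 1..22, X, Y. The packaged chromosome-length
table is the standard hg19 assembly (integer bp), so a grid is always
buildable offline; bins are 1 Mb with the chromosome remainder in the last
bin. Y is carried in the grid and reported, but excluded from abnormality
tallies and all concordance sets, which cover the 22 autosomes plus X
(23 "chromosome sets" per embryo). Per-bin GC is a deterministic smooth
synthetic track (mean 0.42, range ±0.07) generated with a fixed internal
seed, so identical grids are bit-identical; users may supply real GC values.

Karyotype strings follow the bracketed report convention
(`[47, XY, +21]`, `[46, XX, -8mos]`, `[46, XY, +16q(q11.2->qter, ~47M)]`).
The parser accepts the typographic variants seen in reports (en-dash or
Unicode minus for losses, `∼`/`~`, `→`/`->`, optional space before `mos`);
the writer emits one canonical ASCII form, making parse∘format the identity
on canonical strings. The chromosome count is 46 plus the net of full
whole-chromosome events; mosaic and segmental events do not change it.

## Synthetic cohort

Ground truth per embryo: sex (1:1), a category drawn from the mix
euploid 0.50 / whole-chromosome aneuploid 0.20 / segmental 0.08 /
mosaic 0.15 / MAC 0.07 (defaults chosen to resemble the composition of a
donated-embryo validation cohort in which ~37% of whole embryos were
abnormal and ~7% of medium samples showed MAC), and events:

* **aneuploid** — 1–2 full whole-chromosome gains/losses in both lineages;
* **segmental** — one terminal segment of 20–80 Mb, full, both lineages;
* **mosaic** — 1–2 whole-chromosome events with cell fraction U(0.2, 0.8);
  with probability 0.25 the event is restricted to one lineage (this is
  what produces TE-vs-whole and NICS-vs-whole discordances downstream);
* **MAC** — 5–8 events at fractions U(0.3, 0.8): a chaotic-mosaic profile,
  the form in which embryos with many abnormal chromosomes are typically
  observed.

Chromosomes are picked with probability ∝ 1/length, reflecting the strong
excess of small-chromosome aneuploidies in embryos.

Counts: the expected count of bin *b* is
`depth · w_b · (c_b/2) · g(gc_b)`, where `w_b` are length-proportional
normalized bin weights, `c_b` the effective copy number of the sampled
material, and `g(gc) = 1 + s·((gc−0.42) − 6(gc−0.42)²)` a smooth quadratic
amplification bias (strength `s`, default 1, clipped at 0.05). Draws are
negative-binomial with variance `μ(1 + αμ)`; `α` is assay-specific with
defaults whole 0.004 < TE 0.008 < medium 0.014 (medium cfDNA is the
noisiest input). These dispersions were set so that samples carrying real
aneuploidies still pass the CV < 0.2 amplification gate, as the observed
~97% qualified-trio rate implies for the real assay; the CV of a profile
includes its genuine copy-number variance, so noise and signal compete in
that statistic (see QC below). A `noise="poisson"` and a deterministic
`noise="none"` mode exist for exact limit tests.

Assay composition: whole embryo = 50/50 ICM/TE; biopsy = TE lineage; medium
= a 50/50 ICM/TE mix (the true origin of medium cfDNA is unresolved and the
share is a free parameter) further mixed with a maternal euploid 46,XX
contaminant at fraction `f ~ Beta(1.5, 6)` (mean 0.2) per embryo — cumulus
cells carry balanced chromosomes, so contamination pulls medium profiles
toward euploid female, shrinking called levels monotonically in `f` and
masking male X signals at high `f`. Blanks draw ~0.2% of the usual depth.
A per-sample Bernoulli(0.0115) flag inflates dispersion to 0.125
(CV ≈ 0.36), emulating failed amplifications; at 265 embryos this leaves
about 9 embryos without a full qualified trio.

What the simulator does **not** emulate: read-level errors, mappability and
real GC structure, segmental events away from telomeres, uniparental
disomy, triploidy, biopsy sampling noise (the 3–5-cell biopsy reads the TE
fraction exactly), or embryo-to-embryo depth variation. Passing recovery
tests therefore demonstrates correctness of the analysis chain under the
stated noise model, not performance on real sequencing data.

## Copy-number calling

1. **QC** — CV = sd/mean (sample sd, ddof 1) of raw read density (reads per
   Mb) over usable autosomal bins; pass requires CV < 0.2 strictly. Sex
   chromosomes are excluded so male X does not inflate the metric. Note the
   CV deliberately measures the raw profile: heavy CNV load itself raises
   it, so extreme chaotic profiles can be rejected as "uncertain" — mirroring
   practice, where such samples land in the unreliable/MAC bucket.
2. **GC normalization** — lowess of density on GC (span 0.3, 2 robustness
   iterations, delta 1% of the GC range), rescaled to mean 1 and divided
   out. Degenerate GC (constant) is a no-op.
3. **Reference normalization** — a panel of ≥1 (packaged: 24) euploid-XX
   samples, GC-normalized, each scaled to mean 1 over usable autosomal
   bins; the per-bin reference is the 10%-trimmed mean, rescaled to mean 1;
   bins with reference < 0.1 are masked (this removes Y against the female
   panel — sex inference instead uses raw Y density against a blank-level
   floor of 10% of the autosomal mean). The sample is scaled by the
   *median* bin ratio to the reference, so a trisomic chromosome cannot
   drag its own baseline; copy number is `2 · density / (scale · ref)`.
   The packaged panel is generated at runtime from the simulator's euploid
   mode with a fixed internal seed and is therefore identical everywhere.
4. **Segmentation** — in-house CBS per chromosome. All arcs (i, j) of the
   current segment are scanned with prefix sums; the two-sample t-statistic
   uses pooled variance floored at 1e-9. Because arc and complement are
   interchangeable for a two-sample statistic, scanning linear windows
   covers the full circular arc set without doubling the sequence. Ties
   break toward the smallest i, then smallest j. A split must leave every
   resulting piece ≥ `min_bins` (default 3) and is accepted when the
   permutation p ≤ α (default 0.01; `p = (1 + #{perm max|t| > obs}) /
   (1 + n_perm)`, n_perm = 1000). Permutations use *strict* exceedance:
   with continuous noise ties have probability zero, and on degenerate
   noiseless inputs this lets an exact-fit split through instead of being
   vetoed by tied permutations; a constant segment is guarded to p = 1.
   Permutation evaluation is batched and stops early once enough
   exceedances make p > α certain (the decision is unchanged; only wasted
   permutations are skipped). Afterwards, adjacent segments with mean
   difference < `merge_tol` (default 0.3) are re-merged. Defaults resolve
   ≥3 Mb events at 2M reads; all are estimator parameters, and the
   published-table statistics never depend on them.

`CopyNumberCaller` exposes the chain sklearn-style: `fit(panel)` learns the
reference, `predict(tables)` returns QC-gated, segmented profiles;
`random_state` seeds the permutation tests, so profiles are reproducible.

## Ploidy classification

Deviation is measured in copy doses `d = (mean_cn − baseline)/(baseline/2)`
with baseline 2 for autosomes and female X, 1 for male X. Segments with
|d| ≥ 0.3 are deviating; if deviating segments cover ≥ 80% of a
chromosome's usable bins the event is whole-chromosome, otherwise the
widest deviating segment is reported as segmental when it spans ≥ 10 Mb
(the smallest events reported in practice are tens of Mb). |d| ≥ 0.7 is a
full event; 0.3 ≤ |d| < 0.7 is mosaic with estimated cell fraction |d|.
The [0.3, 0.7) mosaic band follows common PGT-A practice; both cutoffs are
configuration. Segment arms are assigned by midpoint against the
chromosome midpoint (no centromere table — a nominal p/q label).

An embryo's abnormality count is the number of non-euploid chromosomes
among the 22 autosomes + X (a chromosome with several events counts once;
segmental events count the same as whole-chromosome ones). Five or more
abnormal chromosomes define MAC. Category maps to prioritization group:
euploid → A, abnormal → B, MAC → C; "abnormal vs normal" for concordance is
category ≠ euploid, and mosaics count as abnormal. Group C contains MAC
calls only; QC failures are a separate no-result state rather than being
folded into C. Sex is inferred from median X copy number (< 1.4 → XY,
> 1.6 → XX, ambiguous band decided by Y density evidence).

## Concordance engine

Positive = chromosomally abnormal throughout. Wilson score intervals use
z = Φ⁻¹(0.975); bounds are exact 0/1 at k = 0/n. Cohen's κ is computed
from the 2×2 table with chance agreement from the marginals; its CI uses
the Fleiss–Cohen–Everitt large-sample variance clipped to [−1, 1] —
published CIs computed with a different variance variant may differ in the
third decimal, so only κ point estimates are pinned. The exact paired test
is two-sided McNemar with p capped at 1; the stratum (e.g. gold-positive
embryos for a sensitivity comparison) is an explicit caller choice.
Chromosome-set comparisons collapse mosaic/segmental onto their direction
(gain/loss) by default, mirroring the "including mosaic" agreement rule;
`collapse_mosaic=False` disables this. Karyotype-level concordance is
full / partial / discordant by comparing abnormal-chromosome sets (signs
and mosaic status intentionally ignored — reciprocal losses and gains
count as concordant). Percentages are reported at 1 decimal, κ at 3,
with half-up rounding.

The packaged reference cohort is the unique per-embryo joint distribution
consistent with the published pairwise and group contingency tables; the
package recomputes all published summary statistics from it. The
chromosome-set table is a synthetic reconstruction matching the published
aggregate region counts (the per-embryo placement of discordant sets was
not published); the 69 sets where the medium assay differs from both others
are placed in the TE=whole region, the dominant published discordance
class.

## Validation studies and problem sizes

`validation.cbs_breakpoint_recovery` plants a unit step at bin 40 of 100
with N(0, 0.1) noise and checks a recovered boundary within ±1 bin
(100 replicates). `validation.whole_embryo_recovery` simulates 200 embryos
at 2M reads, calls the whole-embryo samples, and scores (a) recall of full
whole-chromosome events with correct sign and (b) mosaic-fraction error
for events with effective fraction in [0.3, 0.7], estimated as the
deviation of the chromosome's median copy number from 2 — the measurement
itself, deliberately independent of the call threshold, since whether a
borderline event is *called* is a recall question. QC-failed samples yield
no result and are skipped (counted). These sizes keep the full validation
run in a few minutes on one CPU while leaving binomial error on the recall
estimate near 1–2%.

## Known limitations

* The mosaic-band thresholds, CBS parameters and the reference-panel
  construction of the original proprietary pipeline are not public; ours
  are explicit configuration, and the published-table reproduction is
  threshold-independent by design.
* The CV gate's sensitivity to genuine CNV load (see QC above) means
  extreme chaotic profiles may be rejected rather than called; the
  trade-off is inherent to defining QC on the raw density profile.
* Segmental calls report one event per chromosome (the widest); multiple
  independent segmental events on one chromosome collapse into the
  abnormality count but not the karyotype detail.
* The maternal-contamination model uses a single per-embryo fraction; real
  contamination may vary within a culture drop, and DNA degradation is not
  modeled.
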