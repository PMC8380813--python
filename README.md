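# nicscall

Copy-number calling and validation statistics for **non-invasive chromosome
screening (NICS)** of IVF embryos.

In preimplantation genetic testing for aneuploidy (PGT-A), a trophectoderm
(TE) biopsy is sequenced at low coverage to decide whether an embryo is
chromosomally normal. NICS replaces the biopsy with the cell-free DNA an
embryo sheds into its spent culture medium. Validating either assay against
the ground truth — the whole embryo — is a diagnostic-concordance problem:
per-embryo binary calls (abnormal vs normal), sensitivity/specificity/NPV/PPV
with Wilson score intervals, Cohen's kappa, exact McNemar tests, and
per-chromosome agreement across the three assays.

`nicscall` implements the full analysis as a tested pipeline, for people who
work on embryo CNV screening methods and want a reproducible, download-free
reference implementation:

* **genome model** — 1 Mb bin grid over an hg19-like genome (packaged
  chromosome lengths), BED/TSV I/O, read binning, and a parser/writer for
  karyotype strings such as `[46, XY, +16q(q11.2->qter, ~47M)]`;
* **synthetic cohort** — trio samples (whole embryo, TE biopsy, spent
  medium) with MALBAC-like negative-binomial overdispersion, GC
  amplification bias, lineage-restricted mosaicism, chaotic-mosaic MAC
  embryos (≥5 abnormal chromosomes), maternal 46,XX contamination of the
  medium, and a QC-failure mechanism;
* **CNV calling** — CV quality gate (CV < 0.2), lowess GC normalization,
  trimmed-mean reference-panel normalization, and an in-house circular
  binary segmentation (CBS) with permutation testing, wrapped as the
  sklearn-style estimator `CopyNumberCaller` (`fit` on a euploid panel,
  `predict` profiles);
* **ploidy classification** — per-chromosome calls (full / mosaic /
  segmental gains and losses), embryo category (euploid / abnormal / MAC)
  and prioritization group A/B/C, karyotype string assembly;
* **concordance engine** — confusion tables, Wilson CIs, kappa with
  asymptotic CI, exact paired tests, chromosome-set agreement partitions,
  group tables and secondary-validation reclassification;
* **CLI** — `nics simulate | call | concordance | all`.

The package bundles the published 256-embryo NICS validation cohort at the
binary-call level (`nicscall/data/reference_cohort.tsv`) — the unique
per-embryo expansion of the study's printed contingency tables — so every
published summary statistic is recomputed, not transcribed.

## The statistics at the core

For an assay vs the whole-embryo gold standard with confusion counts
(tp, fp, fn, tn):

* sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), NPV = tn/(tn+fn),
  PPV = tp/(tp+fp), each with the Wilson score interval
  `(p̂ + z²/2n ± z√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)`;
* observed concordance p₀ = (tp+tn)/n and Cohen's
  κ = (p₀ − pₑ)/(1 − pₑ) with pₑ from the marginals, CI via the
  Fleiss–Cohen–Everitt large-sample variance;
* exact McNemar for paired assays: with discordant counts b, c,
  p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½);
* CBS: recursively split each chromosome at the circular arc maximizing the
  two-sample t-statistic, accepting a split when a label-permutation test
  gives p ≤ α.

## Worked example

```python
import numpy as np
from nicscall import build_bin_grid, SimulationConfig, default_reference_panel
from nicscall.simulate import EmbryoTruth, TruthEvent, simulate_counts
from nicscall.cnv import CopyNumberCaller
from nicscall.classify import call_embryo

grid = build_bin_grid()                      # hg19-like 1 Mb grid, 3113 bins
caller = CopyNumberCaller(random_state=7).fit(default_reference_panel(grid))

# an embryo with a double trisomy (+6, +20), sequenced as a whole-embryo sample
truth = EmbryoTruth("E1", "XY", (TruthEvent("6", +1), TruthEvent("20", +1)),
                    "abnormal", maternal_fraction=0.1)
cfg = SimulationConfig(n_embryos=0, seed=1)
table = simulate_counts(truth, "whole", grid, cfg, np.random.default_rng(42))

profile = caller.predict(table)
print(round(profile.cv, 3), profile.qc_pass)   # 0.158 True
call = call_embryo(profile, embryo_id="E1")
print(call.karyotype().text, call.category)    # [48, XY, +6, +20] abnormal
```

The CV of 0.158 passes the < 0.2 amplification-quality gate; segmentation
finds single whole-chromosome segments near copy number 3 on chromosomes 6
and 20, which classify as full gains and assemble into the karyotype
`[48, XY, +6, +20]`.

Reproduce the published summary tables from the packaged cohort:

```bash
nics concordance --fixtures reference --out report/
```

`report/report.md` then shows, among others: TE-PGT sensitivity 89.6%
(81.9–94.2), specificity 80.0% (73.1–85.5), NPV 92.8%, PPV 72.9%,
concordance 83.6% with κ = 0.665; NICS NPV 90.0% with κ = 0.561; and the
prioritization groups A/B/C with 90.0 / 72.2 / 27.8% gold-standard
agreement.

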