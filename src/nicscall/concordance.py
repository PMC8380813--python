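"""Diagnostic concordance statistics for paired embryo assays.

Implements the statistical engine used to validate a screening assay
against a gold standard: 2x2 confusion tables with sensitivity /
specificity / NPV / PPV and Wilson score intervals, exact McNemar tests
for paired binary outcomes, Cohen's kappa with an asymptotic CI,
chromosome-set agreement partitions across three assays, embryo
prioritization group tables, and secondary-validation reclassification.

"Positive" throughout means chromosomally abnormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (matches printed tables)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# confusion tables and diagnostic summaries


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Rows = assay call (+/-), columns = gold standard (+/-)."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


def confusion(calls_assay: Mapping, calls_gold: Mapping) -> ConfusionTable:
    """Cross-tabulate binary abnormal calls against the gold standard.

    Inputs map embryo id -> bool (abnormal).  Embryos missing from either
    side are excluded; an empty intersection is an error.
    """
    a = pd.Series(calls_assay)
    g = pd.Series(calls_gold)
    ids = a.index.intersection(g.index)
    if len(ids) == 0:
        raise ValueError("no embryos shared between assay and gold standard")
    a, g = a[ids].astype(bool), g[ids].astype(bool)
    return ConfusionTable(
        tp=int((a & g).sum()),
        fp=int((a & ~g).sum()),
        fn=int((~a & g).sum()),
        tn=int((~a & ~g).sum()),
    )


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("wilson_ci needs n >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    phat = k / n
    denom = 1 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, centre - half)  # exact at the boundary
    hi = 1.0 if k == n else min(1.0, centre + half)
    return (lo, hi)


@dataclass(frozen=True)
class Proportion:
    k: int
    n: int
    conf: float = 0.95

    @property
    def value(self) -> float:
        return self.k / self.n

    @property
    def ci(self) -> tuple[float, float]:
        return wilson_ci(self.k, self.n, self.conf)

    @property
    def pct(self) -> float:
        return round_half_up(100 * self.value, 1)

    @property
    def ci_pct(self) -> tuple[float, float]:
        lo, hi = self.ci
        return (round_half_up(100 * lo, 1), round_half_up(100 * hi, 1))


@dataclass
class DiagnosticSummary:
    """Sensitivity/specificity/NPV/PPV with Wilson 95% CIs.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """

    sensitivity: Proportion | None
    specificity: Proportion | None
    npv: Proportion | None
    ppv: Proportion | None

    def to_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "npv", "ppv"):
            p = getattr(self, name)
            if p is None:
                out[name] = None
            else:
                lo, hi = p.ci_pct
                out[name] = {"pct": p.pct, "ci": [lo, hi], "k": p.k, "n": p.n}
        return out


def diagnostic_summary(ct: ConfusionTable, conf: float = 0.95) -> DiagnosticSummary:
    def prop(k, n):
        return Proportion(k, n, conf) if n > 0 else None

    return DiagnosticSummary(
        sensitivity=prop(ct.tp, ct.tp + ct.fn),
        specificity=prop(ct.tn, ct.tn + ct.fp),
        npv=prop(ct.tn, ct.tn + ct.fn),
        ppv=prop(ct.tp, ct.tp + ct.fp),
    )


# ---------------------------------------------------------------------------
# paired exact test (McNemar)


def exact_mcnemar(b: int, c: int) -> float:
    """Two-sided exact McNemar p-value from discordant counts b, c.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    no discordant pairs gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return 1.0
    return min(1.0, 2.0 * stats.binom.cdf(min(b, c), m, 0.5))


def exact_paired_test(outcomes_a: Iterable, outcomes_b: Iterable) -> float:
    """Exact test for paired binary outcomes (same embryos, pre-stratified)."""
    a = np.asarray(list(outcomes_a), dtype=bool)
    bb = np.asarray(list(outcomes_b), dtype=bool)
    if len(a) != len(bb):
        raise ValueError("paired vectors must have equal length")
    b = int((a & ~bb).sum())
    c = int((~a & bb).sum())
    return exact_mcnemar(b, c)


# ---------------------------------------------------------------------------
# Cohen's kappa


@dataclass
class AgreementResult:
    po: float  # observed concordance
    pe: float  # chance agreement
    kappa: float
    kappa_ci: tuple[float, float]
    n: int

    @property
    def po_pct(self) -> float:
        return round_half_up(100 * self.po, 1)

    @property
    def kappa_3dp(self) -> float:
        return round_half_up(self.kappa, 3)


def cohen_kappa(table, conf: float = 0.95) -> AgreementResult:
    """Cohen's kappa for a square agreement table, with asymptotic 95% CI.

    Accepts a :class:`ConfusionTable` or any square count matrix (rows =
    rater 1, columns = rater 2).  The CI uses the Fleiss–Cohen–Everitt
    large-sample variance, clipped to [-1, 1].
    """
    if isinstance(table, ConfusionTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("agreement table must be square")
    n = arr.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    p = arr / n
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(rows @ cols)
    if abs(1 - pe) < 1e-12:
        raise ValueError("degenerate marginals: kappa undefined (pe = 1)")
    kappa = (po - pe) / (1 - pe)

    k = arr.shape[0]
    a = sum(
        p[i, i] * (1 - (rows[i] + cols[i]) * (1 - kappa)) ** 2 for i in range(k)
    )
    b = (1 - kappa) ** 2 * sum(
        p[i, j] * (cols[i] + rows[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    c = (kappa - pe * (1 - kappa)) ** 2
    var = max((a + b - c) / (n * (1 - pe) ** 2), 0.0)
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    half = z * math.sqrt(var)
    ci = (max(-1.0, kappa - half), min(1.0, kappa + half))
    return AgreementResult(po=po, pe=pe, kappa=float(kappa), kappa_ci=ci, n=int(n))


# ---------------------------------------------------------------------------
# chromosome-set agreement across three assays


_STATUS_CLASS = {
    "euploid": "euploid",
    "gain": "gain",
    "loss": "loss",
    "mosaic_gain": "gain",
    "mosaic_loss": "loss",
    "segmental_gain": "gain",
    "segmental_loss": "loss",
}


def status_class(status: str, collapse_mosaic: bool = True) -> str:
    """Ploidy class used for set-wise comparison.

    With ``collapse_mosaic`` (default) a mosaic or segmental event of the
    same direction counts as consistent with a full event, mirroring the
    "including mosaic" comparison rule.
    """
    if collapse_mosaic:
        return _STATUS_CLASS.get(status, status)
    return status


@dataclass
class ChromSetVenn:
    """Agreement partition of per-embryo chromosome sets across 3 assays."""

    n_sets: int
    all_three: int
    nics_te_only: int
    nics_whole_only: int
    te_whole_only: int
    all_different: int

    def to_dict(self) -> dict:
        return {
            "n_sets": self.n_sets,
            "all_three": self.all_three,
            "nics_te_only": self.nics_te_only,
            "nics_whole_only": self.nics_whole_only,
            "te_whole_only": self.te_whole_only,
            "all_different": self.all_different,
        }


def chrom_set_venn(
    sets: pd.DataFrame,
    mac_min: int = 5,
    collapse_mosaic: bool = True,
) -> ChromSetVenn:
    """Partition chromosome sets by which assays agree.

    ``sets`` is long-format with columns ``embryo_id, chrom, te, nics,
    whole`` (status per set).  Only non-MAC embryos are allowed: any
    embryo with >= ``mac_min`` abnormal chromosomes in any assay is
    rejected — callers must pre-filter.
    """
    required = {"embryo_id", "chrom", "te", "nics", "whole"}
    missing = required - set(sets.columns)
    if missing:
        raise ValueError(f"chromosome-set table missing column(s): {sorted(missing)}")
    cls = sets[["te", "nics", "whole"]].map(lambda s: status_class(s, collapse_mosaic))
    for assay in ("te", "nics", "whole"):
        abn = (
            (cls[assay] != "euploid")
            .groupby(sets["embryo_id"], sort=False)
            .sum()
        )
        offenders = abn[abn >= mac_min]
        if len(offenders):
            raise ValueError(
                f"MAC embryo(s) present in assay {assay!r}: {list(offenders.index[:5])}"
            )
    te, ni, wh = cls["te"], cls["nics"], cls["whole"]
    tn = te == ni
    nw = ni == wh
    tw = te == wh
    allc = int((tn & nw).sum())
    return ChromSetVenn(
        n_sets=len(sets),
        all_three=allc,
        nics_te_only=int((tn & ~nw).sum()),
        nics_whole_only=int((nw & ~tn).sum()),
        te_whole_only=int((tw & ~tn & ~nw).sum()),
        all_different=int((~tn & ~nw & ~tw).sum()),
    )


def karyotype_concordance(k1, k2) -> str:
    """{full, partial, discordant} between two embryo calls.

    Full if both are euploid or the same chromosomes are abnormal (sign
    and mosaic differences allowed — reciprocal losses and gains count);
    partial if at least one abnormal chromosome is shared; discordant
    otherwise.
    """

    def chromset(k) -> frozenset:
        if hasattr(k, "abnormal_chroms"):
            return frozenset(k.abnormal_chroms)
        return frozenset(k)

    s1, s2 = chromset(k1), chromset(k2)
    if s1 == s2:
        return "full"
    if s1 & s2:
        return "partial"
    return "discordant"


# ---------------------------------------------------------------------------
# embryo grouping and secondary validation


def group_table(groups: Mapping, gold_abnormal: Mapping) -> pd.DataFrame:
    """Per-group (A/B/C) totals and gold-standard splits.

    ``groups`` maps embryo id -> A/B/C for the assay under evaluation;
    ``gold_abnormal`` maps embryo id -> bool.  The "consistent" count is
    gold-normal for group A and gold-abnormal for groups B and C.
    """
    g = pd.Series(groups)
    gold = pd.Series(gold_abnormal)
    ids = g.index.intersection(gold.index)
    g, gold = g[ids], gold[ids].astype(bool)
    rows = []
    for grp in ("A", "B", "C"):
        members = g.index[g == grp]
        n = len(members)
        n_abn = int(gold[members].sum())
        n_nml = n - n_abn
        consistent = n_nml if grp == "A" else n_abn
        rows.append(
            {
                "group": grp,
                "n": n,
                "gold_normal": n_nml,
                "gold_abnormal": n_abn,
                "consistent": consistent,
                "consistent_pct": round_half_up(100 * consistent / n, 1) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SecondaryValidation:
    """Re-evaluation of one primary-assay group by a secondary assay."""

    group: str
    n: int
    primary_accuracy: tuple[int, int]  # (consistent-with-gold, n) by the primary call
    secondary_accuracy: tuple[int, int]  # same, by the secondary call
    recategorized_normal: int  # secondary calls the embryo normal
    crosstab: pd.DataFrame

    @property
    def secondary_accuracy_pct(self) -> float:
        k, n = self.secondary_accuracy
        return round_half_up(100 * k / n, 1) if n else float("nan")

    @property
    def primary_accuracy_pct(self) -> float:
        k, n = self.primary_accuracy
        return round_half_up(100 * k / n, 1) if n else float("nan")


def secondary_validation(
    primary_groups: Mapping,
    secondary_abnormal: Mapping,
    gold_abnormal: Mapping,
    group: str,
) -> SecondaryValidation:
    """Within a primary-assay group (B or C), score the secondary assay.

    The primary assay called every embryo in the stratum abnormal, so its
    accuracy there is the gold-abnormal fraction; the secondary assay's
    accuracy is its raw agreement with gold, and embryos it calls normal
    are the ones it would re-categorize into the transferable group.
    """
    if group not in ("B", "C"):
        raise ValueError("secondary validation applies to group B or C")
    g = pd.Series(primary_groups)
    sec = pd.Series(secondary_abnormal)
    gold = pd.Series(gold_abnormal)
    ids = g.index[g == group].intersection(sec.index).intersection(gold.index)
    sec, gold = sec[ids].astype(bool), gold[ids].astype(bool)
    n = len(ids)
    rows = []
    for gold_state, sel in (("abnormal", gold), ("normal", ~gold)):
        rows.append(
            {
                "gold": gold_state,
                "n": int(sel.sum()),
                "secondary_abnormal": int((sec & sel).sum()),
                "secondary_normal": int((~sec & sel).sum()),
            }
        )
    return SecondaryValidation(
        group=group,
        n=n,
        primary_accuracy=(int(gold.sum()), n),
        secondary_accuracy=(int((sec == gold).sum()), n),
        recategorized_normal=int((~sec).sum()),
        crosstab=pd.DataFrame(rows),
    )
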