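"""Per-chromosome ploidy calls and embryo-level categorization.

A segmented copy-number profile becomes, per chromosome, one of: euploid,
full gain/loss, mosaic gain/loss (intermediate level), or a segmental
event.  Embryos are then categorized as euploid, abnormal, or MAC
(multiple abnormal chromosomes: five or more abnormal), which maps onto
the prioritization groups A (normal), B (abnormal), C (MAC).

Call thresholds express deviation ``d = mean_cn - baseline`` in units of
half the baseline (one copy dose): ``|d| >= 0.7`` of a dose is a full
single-copy event, ``0.3 <= |d| < 0.7`` is mosaic with estimated cell
fraction ``|d|`` per dose, below 0.3 is noise.  Both cutoffs follow common
PGT-A practice and are configuration, not claims; downstream concordance
statistics never depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import CopyNumberProfile, ProfileSegment
from .genome import AUTOSOMES, CONCORDANCE_CHROMS
from .karyotype import Event, KaryotypeString

MAC_MIN_ABNORMAL = 5

STATUSES = (
    "euploid",
    "gain",
    "loss",
    "mosaic_gain",
    "mosaic_loss",
    "segmental_gain",
    "segmental_loss",
    "segmental_mosaic",
    "no_call",
)


@dataclass
class CallThresholds:
    mosaic_low: float = 0.3  # |d| per copy dose below which a chromosome is euploid
    full: float = 0.7  # |d| per copy dose at/above which an event is non-mosaic
    whole_coverage: float = 0.8  # deviating fraction of bins => whole-chromosome event
    min_segment_mb: float = 10.0  # smallest reportable segmental event
    mac_min: int = MAC_MIN_ABNORMAL
    y_density_floor: float = 0.1  # Y presence evidence vs blank level


@dataclass
class ChromosomeCall:
    chrom: str
    status: str = "euploid"
    sign: int = 0  # +1 gain, -1 loss (0 for euploid)
    level: float | None = None  # estimated mosaic fraction in (0, 1]; 1 = full
    span_mb: float | None = None  # segmental events only
    arm: str | None = None

    @property
    def abnormal(self) -> bool:
        return self.status not in ("euploid", "no_call")

    @property
    def mosaic(self) -> bool:
        return self.status in ("mosaic_gain", "mosaic_loss", "segmental_mosaic")

    @property
    def segmental(self) -> bool:
        return self.status.startswith("segmental")


def call_chromosome(
    segments: list[ProfileSegment],
    chrom: str,
    baseline: float = 2.0,
    thresholds: CallThresholds | None = None,
) -> ChromosomeCall:
    """Classify one chromosome from its segments against a ploidy baseline.

    ``baseline`` is 2 for autosomes and female X, 1 for male X.  Whole-
    chromosome events require deviating segments to cover at least 80% of
    the chromosome's usable bins; otherwise the largest deviating segment
    is reported as segmental if it spans >= 10 Mb.
    """
    th = thresholds or CallThresholds()
    if not segments:
        return ChromosomeCall(chrom, status="no_call")
    dose = baseline / 2.0
    devs = [(s, s.mean_cn - baseline) for s in segments]
    deviating = [(s, d) for s, d in devs if abs(d) >= th.mosaic_low * dose]
    if not deviating:
        return ChromosomeCall(chrom)
    total_bins = sum(s.n_bins for s in segments)
    dev_bins = sum(s.n_bins for s, _ in deviating)
    if dev_bins / total_bins >= th.whole_coverage:
        w = np.array([s.n_bins for s, _ in deviating], dtype=float)
        d = float(np.average([d for _, d in deviating], weights=w))
        level = min(abs(d) / dose, 1.0)
        sign = 1 if d > 0 else -1
        if abs(d) >= th.full * dose:
            status = "gain" if sign > 0 else "loss"
        else:
            status = "mosaic_gain" if sign > 0 else "mosaic_loss"
        return ChromosomeCall(chrom, status=status, sign=sign, level=level)
    # segmental: report the widest deviating segment if large enough
    seg, d = max(deviating, key=lambda sd: sd[0].span_mb)
    if seg.span_mb < th.min_segment_mb:
        return ChromosomeCall(chrom)
    sign = 1 if d > 0 else -1
    level = min(abs(d) / dose, 1.0)
    if abs(d) >= th.full * dose:
        status = "segmental_gain" if sign > 0 else "segmental_loss"
    else:
        status = "segmental_mosaic"
    chrom_len = max(s.end_bp for s in segments)
    mid = 0.5 * (seg.start_bp + seg.end_bp)
    arm = "p" if mid < chrom_len / 2 else "q"  # nominal arm (no centromere table)
    return ChromosomeCall(
        chrom, status=status, sign=sign, level=level, span_mb=seg.span_mb, arm=arm
    )


def infer_sex(profile: CopyNumberProfile, thresholds: CallThresholds | None = None) -> str:
    """XX/XY from median X copy number and raw Y read density."""
    th = thresholds or CallThresholds()
    x_cn = profile.median_cn("X")
    y_present = profile.y_density_ratio > th.y_density_floor
    if np.isnan(x_cn):
        return "XY" if y_present else "XX"
    if x_cn < 1.4:
        return "XY"
    if x_cn > 1.6:
        return "XX"
    return "XY" if y_present else "XX"  # ambiguous X band: decide on Y evidence


@dataclass
class EmbryoCall:
    """Full classification of one sample: calls, category, group, karyotype."""

    embryo_id: str
    assay: str
    sex: str
    calls: dict = field(default_factory=dict)  # chrom -> ChromosomeCall (autosomes + X)
    qc_pass: bool = True
    cv: float = float("nan")

    @property
    def n_abnormal(self) -> int:
        return sum(1 for c in self.calls.values() if c.abnormal)

    @property
    def category(self) -> str:
        if not self.qc_pass:
            return "no_result"
        n = self.n_abnormal
        if n == 0:
            return "euploid"
        return "MAC" if n >= MAC_MIN_ABNORMAL else "abnormal"

    @property
    def group(self) -> str:
        return {"euploid": "A", "abnormal": "B", "MAC": "C"}.get(self.category, "")

    @property
    def abnormal(self) -> bool:
        return self.category in ("abnormal", "MAC")

    @property
    def abnormal_chroms(self) -> frozenset[str]:
        return frozenset(c.chrom for c in self.calls.values() if c.abnormal)

    def karyotype(self) -> KaryotypeString:
        events = []
        for call in self.calls.values():
            if not call.abnormal:
                continue
            events.append(
                Event(
                    chrom=call.chrom,
                    sign=call.sign,
                    mosaic=call.mosaic,
                    arm=call.arm if call.segmental else None,
                    span_mb=round(call.span_mb) if call.span_mb is not None else None,
                )
            )
        count = 46 + sum(e.sign for e in events if not e.segmental and not e.mosaic)
        return KaryotypeString(count=count, sex=self.sex, events=tuple(events))


def classify_embryo(
    calls: dict[str, ChromosomeCall],
    embryo_id: str = "",
    assay: str = "whole",
    sex: str = "XX",
    qc_pass: bool = True,
    cv: float = float("nan"),
) -> EmbryoCall:
    """Assemble chromosome calls into an embryo call (autosomes + X).

    A chromosome with any non-euploid status counts once toward the MAC
    tally; Y never enters the tally or the concordance sets.
    """
    missing = [c for c in CONCORDANCE_CHROMS if c not in calls]
    if missing:
        raise ValueError(f"missing chromosome call(s): {missing}")
    kept = {c: calls[c] for c in CONCORDANCE_CHROMS}
    return EmbryoCall(
        embryo_id=embryo_id, assay=assay, sex=sex, calls=kept, qc_pass=qc_pass, cv=cv
    )


def call_embryo(
    profile: CopyNumberProfile,
    embryo_id: str | None = None,
    thresholds: CallThresholds | None = None,
) -> EmbryoCall:
    """Profile -> embryo call: sex inference, per-chromosome calls, category."""
    th = thresholds or CallThresholds()
    if not profile.qc_pass:
        return EmbryoCall(
            embryo_id=embryo_id or profile.sample_id,
            assay=profile.assay,
            sex="",
            qc_pass=False,
            cv=profile.cv,
        )
    sex = infer_sex(profile, th)
    calls = {}
    for chrom in CONCORDANCE_CHROMS:
        baseline = 1.0 if (chrom == "X" and sex == "XY") else 2.0
        calls[chrom] = call_chromosome(
            profile.chrom_segments(chrom), chrom, baseline=baseline, thresholds=th
        )
    return classify_embryo(
        calls,
        embryo_id=embryo_id or profile.sample_id,
        assay=profile.assay,
        sex=sex,
        cv=profile.cv,
    )


def calls_to_frame(embryo_calls: list[EmbryoCall]) -> pd.DataFrame:
    """Wide calls table (one row per sample) — the interchange format."""
    rows = []
    for ec in embryo_calls:
        row = {
            "embryo_id": ec.embryo_id,
            "assay": ec.assay,
            "sex": ec.sex,
            "qc_pass": int(ec.qc_pass),
            "cv": round(ec.cv, 4) if np.isfinite(ec.cv) else "",
            "n_abnormal": ec.n_abnormal if ec.qc_pass else "",
            "category": ec.category,
            "group": ec.group,
            "karyotype": ec.karyotype().text if ec.qc_pass else "",
        }
        for chrom in CONCORDANCE_CHROMS:
            call = ec.calls.get(chrom)
            row[f"chr{chrom}_status"] = call.status if call else ""
            row[f"chr{chrom}_level"] = (
                round(call.level, 3) if call and call.level is not None else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)
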