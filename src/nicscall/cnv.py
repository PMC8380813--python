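"""Copy-number calling from binned low-coverage counts.

The chain mirrors standard shallow-WGS aneuploidy screening of amplified
single-embryo material:

1. **QC** — coefficient of variation of raw read density over autosomal
   bins; CV < 0.2 (strict) is a successful amplification.
2. **GC normalization** — divide counts by a lowess fit of count on GC
   fraction, removing the smooth amplification bias.
3. **Reference normalization** — divide by a trimmed-mean euploid reference
   panel and scale so the euploid level is copy number 2.
4. **Segmentation** — per-chromosome circular binary segmentation.

`CopyNumberCaller` wraps the chain as an sklearn-style estimator: ``fit``
learns the reference panel, ``predict`` turns count tables into profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from scipy.stats import trim_mean
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinGrid, CountTable
from .segment import Segment, cbs_segment

CV_THRESHOLD = 0.2


def read_density(table: CountTable) -> np.ndarray:
    """Reads per Mb in each bin (length-corrected raw density)."""
    return table.counts / (table.grid.lengths_bp / 1e6)


def compute_cv(table: CountTable, grid: BinGrid | None = None) -> float:
    """CV of raw read density over usable autosomal bins (sd/mean, ddof=1).

    Sex chromosomes are excluded so a male X does not inflate the metric.
    Returns ``inf`` for a zero-count sample (always a QC failure).
    """
    grid = grid or table.grid
    sel = grid.mask & grid.is_autosome
    if sel.sum() < 2:
        raise ValueError("need at least 2 usable autosomal bins")
    d = read_density(table)[sel]
    mean = d.mean()
    if mean <= 0:
        return float("inf")
    return float(d.std(ddof=1) / mean)


def gc_normalize(
    table: CountTable,
    grid: BinGrid | None = None,
    frac: float = 0.3,
    it: int = 2,
) -> np.ndarray:
    """Remove the smooth GC-only trend from read density.

    Fits lowess of density on GC over usable bins and divides it out; the
    fit is rescaled to mean 1, so the output stays on the density scale.
    Degenerate GC (all equal) makes this a no-op.
    """
    grid = grid or table.grid
    dens = read_density(table).astype(float)
    sel = grid.mask
    x = grid.gc[sel]
    y = dens[sel]
    if np.ptp(x) < 1e-12 or y.sum() <= 0:
        return dens
    fitted = lowess(
        y, x, frac=frac, it=it, delta=0.01 * np.ptp(x), return_sorted=False
    )
    fitted = np.maximum(fitted, 0.05 * y.mean())
    ghat = fitted / fitted.mean()
    out = dens.copy()
    out[sel] = y / ghat
    return out


class EmptyPanelError(ValueError):
    def __init__(self):
        super().__init__(
            "reference panel is empty; pass >= 1 euploid sample densities or use "
            "nicscall.cnv.default_reference_panel() for the packaged simulated panel"
        )


@dataclass
class ReferencePanel:
    """Per-bin expected euploid density (trimmed mean over panel samples)."""

    grid: BinGrid
    ref: np.ndarray  # mean-1 scaled; near-zero where the panel sees no reads
    n_samples: int

    @classmethod
    def from_densities(cls, densities: np.ndarray, grid: BinGrid, trim: float = 0.1):
        densities = np.atleast_2d(np.asarray(densities, dtype=float))
        if densities.size == 0 or densities.shape[0] == 0:
            raise EmptyPanelError()
        sel = grid.mask & grid.is_autosome
        scaled = densities / densities[:, sel].mean(axis=1, keepdims=True)
        ref = trim_mean(scaled, trim, axis=0) if scaled.shape[0] >= 3 else scaled.mean(axis=0)
        ref = ref / ref[sel].mean()
        return cls(grid=grid, ref=ref, n_samples=densities.shape[0])

    @classmethod
    def from_tables(cls, tables, grid: BinGrid, trim: float = 0.1, **gc_kw):
        dens = [gc_normalize(t, grid, **gc_kw) for t in tables]
        if not dens:
            raise EmptyPanelError()
        return cls.from_densities(np.vstack(dens), grid, trim=trim)


def reference_normalize(
    density: np.ndarray, panel: ReferencePanel, ref_floor: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Relative copy number vs the euploid panel (euploid = 2).

    Returns ``(cn, usable)`` where bins with panel reference below
    ``ref_floor`` (dead bins, e.g. Y in a female panel) are masked out.
    The sample is put on the panel scale by the *median* bin ratio over
    usable autosomal bins, so one aneuploid chromosome cannot drag the
    baseline and deflate its own apparent copy number.
    """
    grid = panel.grid
    usable = grid.mask & (panel.ref >= ref_floor)
    sel = usable & grid.is_autosome
    scale = float(np.median(density[sel] / panel.ref[sel]))
    if scale <= 0:
        raise ValueError("sample has no signal on usable autosomal bins")
    cn = np.full(len(density), np.nan)
    cn[usable] = 2.0 * (density[usable] / scale) / panel.ref[usable]
    return cn, usable


@dataclass
class ProfileSegment:
    chrom: str
    start_bp: int
    end_bp: int
    n_bins: int
    mean_cn: float
    p: float

    @property
    def span_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class CopyNumberProfile:
    """QC-gated, normalized, segmented profile of one sample."""

    grid: BinGrid
    sample_id: str
    assay: str
    cv: float
    qc_pass: bool
    density: np.ndarray | None = None
    cn: np.ndarray | None = None
    usable: np.ndarray | None = None
    segments: list[ProfileSegment] = field(default_factory=list)
    y_density_ratio: float = 0.0  # mean Y density / mean autosomal density

    def chrom_segments(self, chrom: str) -> list[ProfileSegment]:
        return [s for s in self.segments if s.chrom == str(chrom)]

    def median_cn(self, chrom: str) -> float:
        idx = self.grid.chrom_index(chrom)
        vals = self.cn[idx]
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if len(vals) else float("nan")

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "n_bins": s.n_bins,
                    "mean_cn": round(s.mean_cn, 4),
                    "p": s.p,
                }
                for s in self.segments
            ],
            columns=["chrom", "start_bp", "end_bp", "n_bins", "mean_cn", "p"],
        )


class CopyNumberCaller(BaseEstimator):
    """Estimator mapping binned counts to segmented copy-number profiles.

    Parameters follow the processing chain: ``cv_threshold`` gates QC,
    ``lowess_frac``/``lowess_it`` control GC normalization, ``trim`` and
    ``ref_floor`` the reference panel, and ``alpha``/``n_perm``/
    ``min_bins``/``merge_tol`` the CBS stage.  ``random_state`` seeds the
    permutation tests, making profiles fully reproducible.
    """

    def __init__(
        self,
        cv_threshold: float = CV_THRESHOLD,
        alpha: float = 0.01,
        n_perm: int = 1000,
        min_bins: int = 3,
        merge_tol: float = 0.3,
        lowess_frac: float = 0.3,
        lowess_it: int = 2,
        trim: float = 0.1,
        ref_floor: float = 0.1,
        random_state: int = 0,
    ):
        self.cv_threshold = cv_threshold
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_bins = min_bins
        self.merge_tol = merge_tol
        self.lowess_frac = lowess_frac
        self.lowess_it = lowess_it
        self.trim = trim
        self.ref_floor = ref_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        """Learn the euploid reference from panel count tables.

        ``X``: list of :class:`CountTable` (>= 1 euploid samples), or an
        existing :class:`ReferencePanel`.
        """
        if isinstance(X, ReferencePanel):
            self.panel_ = X
            self.grid_ = X.grid
            return self
        tables = list(X)
        if not tables:
            raise EmptyPanelError()
        self.grid_ = tables[0].grid
        self.panel_ = ReferencePanel.from_tables(
            tables, self.grid_, trim=self.trim, frac=self.lowess_frac, it=self.lowess_it
        )
        return self

    def predict(self, X):
        """Profile one CountTable or a list of them."""
        if not hasattr(self, "panel_"):
            raise RuntimeError("CopyNumberCaller is not fitted; call fit() first")
        if isinstance(X, CountTable):
            return self._profile(X)
        return [self._profile(t) for t in X]

    def _profile(self, table: CountTable) -> CopyNumberProfile:
        grid = self.grid_
        cv = compute_cv(table, grid)
        qc_pass = cv < self.cv_threshold
        if not qc_pass:
            return CopyNumberProfile(
                grid, table.sample_id, table.assay, cv=cv, qc_pass=False
            )
        density = gc_normalize(table, grid, frac=self.lowess_frac, it=self.lowess_it)
        cn, usable = reference_normalize(density, self.panel_, self.ref_floor)

        aut = grid.mask & grid.is_autosome
        y_bins = grid.chrom == "Y"
        aut_mean = density[aut].mean()
        y_ratio = float(density[y_bins].mean() / aut_mean) if y_bins.any() and aut_mean > 0 else 0.0

        rng = np.random.default_rng(self.random_state)
        segments: list[ProfileSegment] = []
        for c in grid.chromosomes():
            idx = grid.chrom_index(c)
            idx = idx[usable[idx]]
            if len(idx) == 0:
                continue
            for seg in cbs_segment(
                cn[idx],
                alpha=self.alpha,
                n_perm=self.n_perm,
                min_bins=self.min_bins,
                merge_tol=self.merge_tol,
                rng=rng,
            ):
                segments.append(
                    ProfileSegment(
                        chrom=c,
                        start_bp=int(grid.start[idx[seg.start]]),
                        end_bp=int(grid.end[idx[seg.end - 1]]),
                        n_bins=seg.n_bins,
                        mean_cn=seg.mean,
                        p=seg.p,
                    )
                )
        return CopyNumberProfile(
            grid,
            table.sample_id,
            table.assay,
            cv=cv,
            qc_pass=True,
            density=density,
            cn=cn,
            usable=usable,
            segments=segments,
            y_density_ratio=y_ratio,
        )


def call_profile(
    table: CountTable,
    grid: BinGrid | None = None,
    panel: ReferencePanel | None = None,
    **params,
) -> CopyNumberProfile:
    """One-shot wrapper: fit a caller on ``panel`` and profile ``table``."""
    grid = grid or table.grid
    if panel is None:
        panel = default_reference_panel(grid)
    caller = CopyNumberCaller(**params)
    caller.fit(panel)
    return caller.predict(table)


_PANEL_SEED = 7_141_312  # fixed: the packaged panel must be bit-stable
_panel_cache: dict[int, ReferencePanel] = {}


def default_reference_panel(grid: BinGrid, n_samples: int = 24) -> ReferencePanel:
    """Packaged reference panel: simulated euploid 46,XX whole-embryo samples.

    Generated at import-use time from the cohort simulator with a fixed
    internal seed, so it is identical in every installation.  A female
    panel keeps chromosome X at reference level 1 (male samples then read
    cn ~ 1 on X) and leaves Y reference-masked; sex inference therefore
    uses raw Y density, not cn.
    """
    from .simulate import EmbryoTruth, SimulationConfig, simulate_counts

    key = (id(grid), n_samples)
    if key in _panel_cache:
        return _panel_cache[key]
    config = SimulationConfig(n_embryos=0, seed=_PANEL_SEED)
    rng = np.random.default_rng(_PANEL_SEED)
    tables = [
        simulate_counts(
            EmbryoTruth(f"REF{i:02d}", "XX", (), "euploid", 0.0),
            "whole",
            grid,
            config,
            rng,
        )
        for i in range(n_samples)
    ]
    panel = ReferencePanel.from_tables(tables, grid)
    _panel_cache[key] = panel
    return panel
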