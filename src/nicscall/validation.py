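"""Self-validation routines: recovery of known truth from simulated data.

These run the full calling chain on simulated cohorts where the ground
truth is known, and measure how well it is recovered: whole-chromosome
trisomy/monosomy recall, mosaic-fraction estimation error, breakpoint
localization of the segmentation stage, and the response of the CV QC
metric to amplification noise.
"""

from __future__ import annotations

import numpy as np

from .classify import call_embryo
from .cnv import CopyNumberCaller, compute_cv, default_reference_panel
from .genome import BinGrid, build_bin_grid
from .segment import cbs_segment
from .simulate import EmbryoTruth, SimulationConfig, simulate_counts, simulate_truth


def cbs_breakpoint_recovery(
    n_reps: int = 100,
    n_bins: int = 100,
    break_at: int = 40,
    delta: float = 1.0,
    sigma: float = 0.1,
    tol_bins: int = 1,
    seed: int = 0,
) -> dict:
    """Fraction of noisy single-step signals whose breakpoint is localized.

    Each replicate is a two-level signal (step ``delta`` at ``break_at``)
    plus N(0, sigma) noise; recovery means some segment boundary falls
    within ``tol_bins`` of the true break.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        x = np.where(np.arange(n_bins) < break_at, 2.0, 2.0 + delta)
        x = x + rng.normal(0.0, sigma, n_bins)
        segs = cbs_segment(x, rng=rng)
        bounds = {s.start for s in segs} | {s.end for s in segs}
        if any(abs(b - break_at) <= tol_bins for b in bounds):
            hits += 1
    return {"recovered": hits, "n_reps": n_reps, "fraction": hits / n_reps}


def whole_embryo_recovery(
    n_embryos: int = 200,
    depth: int = 2_000_000,
    seed: int = 0,
    grid: BinGrid | None = None,
    caller: CopyNumberCaller | None = None,
) -> dict:
    """Call simulated whole-embryo samples and score truth recovery.

    * **recall**: among ground-truth whole-chromosome full (non-mosaic)
      gains/losses, the fraction called abnormal with the correct sign;
    * **mosaic error**: for whole-chromosome events whose effective cell
      fraction in the whole-embryo sample lies in [0.3, 0.7], the error of
      the estimated fraction against truth.  The estimate is the deviation
      of the chromosome's median copy number from the disomic baseline —
      the measurement itself, independent of the call threshold (whether a
      borderline event is *called* is a recall question, not an estimation
      one).
    """
    if grid is None:
        grid = build_bin_grid()
    config = SimulationConfig(n_embryos=n_embryos, depth=depth, seed=seed, qc_fail_rate=0.0)
    rng = np.random.default_rng(seed)
    truths = simulate_truth(config, rng, grid)
    if caller is None:
        caller = CopyNumberCaller(random_state=seed)
    if not hasattr(caller, "panel_"):
        caller.fit(default_reference_panel(grid))

    n_full = n_full_hit = n_qc_failed = 0
    mosaic_errors: list[float] = []
    for truth in truths:
        if not truth.events:
            continue
        table = simulate_counts(truth, "whole", grid, config, rng)
        profile = caller.predict(table)
        call = call_embryo(profile, embryo_id=truth.embryo_id)
        if not call.qc_pass:  # failed amplification: no result, as in practice
            n_qc_failed += 1
            continue
        for ev in truth.events:
            if not ev.whole_chrom:
                continue
            f_eff = 0.5 * (ev.frac_icm + ev.frac_te)
            chrom_call = call.calls[ev.chrom]
            if ev.frac_icm == 1.0 and ev.frac_te == 1.0:
                n_full += 1
                if chrom_call.abnormal and chrom_call.sign == ev.delta:
                    n_full_hit += 1
            elif 0.3 <= f_eff <= 0.7:
                estimate = abs(profile.median_cn(ev.chrom) - 2.0)
                mosaic_errors.append(abs(estimate - f_eff))
    errors = np.array(mosaic_errors)
    return {
        "n_qc_failed": n_qc_failed,
        "n_full_events": n_full,
        "full_recall": n_full_hit / n_full if n_full else float("nan"),
        "n_mosaic_events": len(errors),
        "mosaic_mean_abs_err": float(errors.mean()) if len(errors) else float("nan"),
        "mosaic_max_abs_err": float(errors.max()) if len(errors) else float("nan"),
    }


def cv_dispersion_curve(
    dispersions=(0.002, 0.01, 0.05, 0.125),
    depth: int = 2_000_000,
    seed: int = 0,
    grid: BinGrid | None = None,
    n_samples: int = 5,
) -> list[float]:
    """Mean CV of euploid samples at each overdispersion level (same seed)."""
    if grid is None:
        grid = build_bin_grid()
    out = []
    truth = EmbryoTruth("CVTEST", "XX", (), "euploid", 0.0)
    for alpha in dispersions:
        config = SimulationConfig(
            n_embryos=0,
            depth=depth,
            seed=seed,
            dispersion={"whole": alpha, "TE": alpha, "medium": alpha, "blank": alpha},
        )
        rng = np.random.default_rng(seed)
        cvs = [
            compute_cv(simulate_counts(truth, "whole", grid, config, rng))
            for _ in range(n_samples)
        ]
        out.append(float(np.mean(cvs)))
    return out
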