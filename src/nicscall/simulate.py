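"""Synthetic embryo-trio cohort generator.

Ground truth is generated at the level a biologist would describe it:
each embryo has two cell lineages — inner cell mass (ICM, the future
fetus) and trophectoderm (TE, the future placenta) — each with integer
per-chromosome copy states, and abnormalities may be mosaic (present in
only a fraction of cells) or lineage-restricted.  From one embryo three
sequencing samples are drawn:

* ``whole``   — the whole embryo (gold standard), a 50/50 lineage mix;
* ``TE``      — the trophectoderm biopsy (TE lineage only);
* ``medium``  — cell-free DNA in the spent culture medium, a lineage mix
  further diluted by a maternal (euploid 46,XX cumulus-cell) fraction
  drawn per embryo from a Beta distribution;
* ``blank``   — culture medium without an embryo (near-zero input).

Counts per 1 Mb bin are negative-binomial around
``depth * w_b * (c_b / 2) * g(gc_b)`` where ``w_b`` are normalized bin
weights, ``c_b`` the effective copy number of the sampled material and
``g`` a smooth quadratic GC amplification bias.  Overdispersion is
assay-specific (medium >> biopsy > whole embryo, reflecting MALBAC
amplification of minute cfDNA input), and a small fraction of samples is
drawn with inflated dispersion to emulate failed amplifications that the
CV < 0.2 quality gate must reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, BIN_SIZE, ASSAYS, BinGrid, CountTable, build_bin_grid
from .karyotype import Event, KaryotypeString

CATEGORIES = ("euploid", "abnormal", "MAC")
MAC_MIN_ABNORMAL = 5  # five or more abnormal chromosomes defines MAC


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the validation setting being emulated: 2 million reads
    per sample on a 1 Mb hg19-like grid, and a QC failure rate leaving
    roughly 256 of 265 embryos with a full qualified trio.
    """

    n_embryos: int = 265
    depth: int = 2_000_000
    #: negative-binomial overdispersion (variance = mu * (1 + dispersion * mu))
    dispersion: dict = field(
        default_factory=lambda: {"whole": 0.004, "TE": 0.008, "medium": 0.014, "blank": 0.05}
    )
    qc_dispersion: float = 0.125  # inflated dispersion for designated QC failures
    gc_bias_strength: float = 1.0
    contamination_beta: tuple = (1.5, 6.0)  # maternal fraction f in medium, mean 0.2
    category_mix: dict = field(
        default_factory=lambda: {
            "euploid": 0.50,
            "aneuploid": 0.20,
            "segmental": 0.08,
            "mosaic": 0.15,
            "mac": 0.07,
        }
    )
    medium_icm_fraction: float = 0.5  # lineage origin of medium cfDNA is an open question
    lineage_discordance: float = 0.25  # P(mosaic event restricted to one lineage)
    qc_fail_rate: float = 0.0115  # per sample; ~3.4% of trios lose a member
    noise: str = "nb"  # nb | poisson | none
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimulationConfig.seed is mandatory")
        if self.n_embryos < 0:
            raise ValueError("n_embryos must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1 (got {total})")
        if self.noise not in ("nb", "poisson", "none"):
            raise ValueError(f"unknown noise model: {self.noise!r}")
        if not 0 <= self.qc_fail_rate <= 1:
            raise ValueError("qc_fail_rate must be in [0, 1]")


@dataclass(frozen=True)
class TruthEvent:
    """A ground-truth abnormality with per-lineage cell fractions."""

    chrom: str
    delta: int  # +1 gain, -1 loss
    frac_icm: float = 1.0
    frac_te: float = 1.0
    start_mb: float | None = None  # None = whole chromosome
    end_mb: float | None = None
    arm: str | None = None

    @property
    def whole_chrom(self) -> bool:
        return self.start_mb is None


@dataclass
class EmbryoTruth:
    embryo_id: str
    sex: str  # XX / XY
    events: tuple[TruthEvent, ...]
    category: str  # euploid / abnormal / MAC
    maternal_fraction: float  # medium contamination f


def _base_copy(grid: BinGrid, sex: str) -> np.ndarray:
    c = np.full(grid.n_bins, 2.0)
    x = grid.chrom == "X"
    y = grid.chrom == "Y"
    if sex == "XY":
        c[x] = 1.0
        c[y] = 1.0
    else:
        c[y] = 0.0
    return c


def _event_bins(ev: TruthEvent, grid: BinGrid) -> np.ndarray:
    idx = grid.chrom_index(ev.chrom)
    if ev.whole_chrom:
        return idx
    lo, hi = ev.start_mb * 1e6, ev.end_mb * 1e6
    sel = (grid.start[idx] < hi) & (grid.end[idx] > lo)
    return idx[sel]


def lineage_copy(truth: EmbryoTruth, lineage: str, grid: BinGrid) -> np.ndarray:
    """Effective per-bin copy number of one lineage (mosaic-weighted)."""
    c = _base_copy(grid, truth.sex)
    for ev in truth.events:
        frac = ev.frac_icm if lineage == "icm" else ev.frac_te
        if frac > 0:
            c[_event_bins(ev, grid)] += ev.delta * frac
    return c


def sample_copy(truth: EmbryoTruth, assay: str, grid: BinGrid, config: SimulationConfig) -> np.ndarray:
    """Effective copy number of the material in one assay sample."""
    if assay == "blank":
        return np.zeros(grid.n_bins)
    icm = lineage_copy(truth, "icm", grid)
    te = lineage_copy(truth, "te", grid)
    if assay == "whole":
        return 0.5 * icm + 0.5 * te
    if assay == "TE":
        return te
    if assay == "medium":
        m = config.medium_icm_fraction
        embryo = m * icm + (1.0 - m) * te
        maternal = _base_copy(grid, "XX")
        f = truth.maternal_fraction
        return (1.0 - f) * embryo + f * maternal
    raise ValueError(f"unknown assay label: {assay!r}")


def gc_bias(gc: np.ndarray, strength: float) -> np.ndarray:
    """Smooth unimodal amplification bias: quadratic in (gc - 0.42)."""
    d = gc - 0.42
    return np.clip(1.0 + strength * (d - 6.0 * d * d), 0.05, None)


def expected_counts(
    truth: EmbryoTruth, assay: str, grid: BinGrid, config: SimulationConfig
) -> np.ndarray:
    """Per-bin expected read count (the noiseless mean structure)."""
    w = np.where(grid.mask, grid.lengths_bp.astype(float), 0.0)
    w /= w.sum()
    g = gc_bias(grid.gc, config.gc_bias_strength)
    if assay == "blank":
        return config.depth * w * 0.002  # background DNA only
    c = sample_copy(truth, assay, grid, config)
    return config.depth * w * (c / 2.0) * g


def simulate_counts(
    truth: EmbryoTruth,
    assay: str,
    grid: BinGrid,
    config: SimulationConfig,
    rng: np.random.Generator,
    qc_fail: bool = False,
) -> CountTable:
    """Draw one sample's binned counts under the configured noise model."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay label: {assay!r}")
    mu = expected_counts(truth, assay, grid, config)
    if config.noise == "none":
        counts = np.rint(mu).astype(np.int64)
    elif config.noise == "poisson":
        counts = rng.poisson(mu)
    else:
        alpha = config.qc_dispersion if qc_fail else config.dispersion[assay]
        if alpha <= 0:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            counts = rng.negative_binomial(r, r / (r + mu))
    return CountTable(grid, counts, sample_id=f"{truth.embryo_id}_{assay}", assay=assay)


# ---------------------------------------------------------------------------
# ground-truth generation


def _autosome_weights(grid: BinGrid) -> tuple[list[str], np.ndarray]:
    """Aneuploidy propensity per autosome present in the grid: 1/length.

    Embryo aneuploidies are observed far more often on the small
    chromosomes; weighting by inverse length is a simple monotone stand-in.
    """
    autos = [c for c in grid.chromosomes() if c in AUTOSOMES]
    lengths = np.array([grid.chrom_length(c) for c in autos], dtype=float)
    w = 1.0 / lengths
    return autos, w / w.sum()


def _draw_events(
    category: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    autos: list[str],
    chrom_weights: np.ndarray,
):
    """Event set for one embryo of the given truth category (autosomal events)."""

    def pick(k):
        k = min(k, len(autos))  # tiny test genomes may have few autosomes
        idx = rng.choice(len(autos), size=k, replace=False, p=chrom_weights)
        return [autos[i] for i in idx]

    if category == "euploid":
        return ()
    if category == "aneuploid":
        k = 1 + int(rng.random() < 0.3)
        return tuple(TruthEvent(str(c), int(rng.choice([-1, 1]))) for c in pick(k))
    if category == "segmental":
        c = str(pick(1)[0])
        span = float(rng.uniform(20.0, 80.0))
        return (
            TruthEvent(
                c,
                int(rng.choice([-1, 1])),
                start_mb=0.0,  # placed terminally by the caller (needs length)
                end_mb=span,
                arm="p",
            ),
        )
    if category == "mosaic":
        k = 1 + int(rng.random() < 0.3)
        out = []
        for c in pick(k):
            frac = float(rng.uniform(0.2, 0.8))
            delta = int(rng.choice([-1, 1]))
            if rng.random() < config.lineage_discordance:
                if rng.random() < 0.5:
                    out.append(TruthEvent(str(c), delta, frac_icm=frac, frac_te=0.0))
                else:
                    out.append(TruthEvent(str(c), delta, frac_icm=0.0, frac_te=frac))
            else:
                out.append(TruthEvent(str(c), delta, frac_icm=frac, frac_te=frac))
        return tuple(out)
    if category == "mac":
        # chaotic-mosaic profile: many chromosomes at intermediate levels
        k = int(rng.integers(MAC_MIN_ABNORMAL, 9))
        return tuple(
            TruthEvent(
                str(c),
                int(rng.choice([-1, 1])),
                frac_icm=(f := float(rng.uniform(0.3, 0.8))),
                frac_te=f,
            )
            for c in pick(k)
        )
    raise ValueError(f"unknown category: {category!r}")


def _place_segmental(events, grid: BinGrid, rng: np.random.Generator):
    """Anchor segmental events at a random chromosome end (terminal segments)."""
    placed = []
    for ev in events:
        if ev.whole_chrom:
            placed.append(ev)
            continue
        length_mb = grid.chrom_length(ev.chrom) / 1e6
        span = min(ev.end_mb - ev.start_mb, length_mb * 0.8)
        if rng.random() < 0.5:
            placed.append(
                TruthEvent(ev.chrom, ev.delta, ev.frac_icm, ev.frac_te, 0.0, span, "p")
            )
        else:
            placed.append(
                TruthEvent(
                    ev.chrom, ev.delta, ev.frac_icm, ev.frac_te, length_mb - span, length_mb, "q"
                )
            )
    return tuple(placed)


def truth_category(events) -> str:
    n_abn = len({e.chrom for e in events})
    if n_abn == 0:
        return "euploid"
    return "MAC" if n_abn >= MAC_MIN_ABNORMAL else "abnormal"


def simulate_truth(
    config: SimulationConfig, rng: np.random.Generator, grid: BinGrid | None = None
) -> list[EmbryoTruth]:
    """Draw ground-truth embryos from the configured category mix."""
    config.validate()
    if grid is None:
        grid = build_bin_grid()
    names = list(config.category_mix)
    probs = np.array([config.category_mix[n] for n in names], dtype=float)
    autos, weights = _autosome_weights(grid)
    truths = []
    for i in range(config.n_embryos):
        sex = "XX" if rng.random() < 0.5 else "XY"
        cat = names[int(rng.choice(len(names), p=probs))]
        events = _place_segmental(_draw_events(cat, config, rng, autos, weights), grid, rng)
        f = float(rng.beta(*config.contamination_beta))
        truths.append(
            EmbryoTruth(
                embryo_id=f"E{i + 1:04d}",
                sex=sex,
                events=events,
                category=truth_category(events),
                maternal_fraction=f,
            )
        )
    return truths


def lineage_karyotype(truth: EmbryoTruth, lineage: str) -> str:
    """Karyotype string of one lineage of the ground truth."""
    evs = []
    for ev in truth.events:
        frac = ev.frac_icm if lineage == "icm" else ev.frac_te
        if frac <= 0:
            continue
        span = None if ev.whole_chrom else ev.end_mb - ev.start_mb
        evs.append(
            Event(
                chrom=ev.chrom,
                sign=1 if ev.delta > 0 else -1,
                mosaic=frac < 1.0,
                arm=ev.arm if not ev.whole_chrom else None,
                span_mb=span,
            )
        )
    count = 46 + sum(e.sign for e in evs if not e.segmental and not e.mosaic)
    return KaryotypeString(count=count, sex=truth.sex, events=tuple(evs)).text


@dataclass
class Cohort:
    truths: list[EmbryoTruth]
    tables: dict[str, CountTable]  # sample_id -> counts
    manifest: pd.DataFrame
    grid: BinGrid


MANIFEST_COLUMNS = [
    "sample_id",
    "embryo_id",
    "assay",
    "sex",
    "category",
    "icm_karyotype",
    "te_karyotype",
    "mosaic_fractions",
    "maternal_fraction",
    "designated_qc_fail",
    "seed",
]


def simulate_cohort(
    config: SimulationConfig, grid: BinGrid | None = None, n_blanks: int = 0
) -> Cohort:
    """Full trio cohort: 3 samples per embryo (+ optional blanks) and a manifest."""
    config.validate()
    if grid is None:
        grid = build_bin_grid()
    rng = np.random.default_rng(config.seed)
    truths = simulate_truth(config, rng, grid)
    tables: dict[str, CountTable] = {}
    rows = []
    for truth in truths:
        fracs = ";".join(
            f"{e.chrom}:{max(e.frac_icm, e.frac_te):.2f}" for e in truth.events
        )
        for assay in ("whole", "TE", "medium"):
            qc_fail = bool(rng.random() < config.qc_fail_rate)
            table = simulate_counts(truth, assay, grid, config, rng, qc_fail=qc_fail)
            tables[table.sample_id] = table
            rows.append(
                {
                    "sample_id": table.sample_id,
                    "embryo_id": truth.embryo_id,
                    "assay": assay,
                    "sex": truth.sex,
                    "category": truth.category,
                    "icm_karyotype": lineage_karyotype(truth, "icm"),
                    "te_karyotype": lineage_karyotype(truth, "te"),
                    "mosaic_fractions": fracs,
                    "maternal_fraction": round(truth.maternal_fraction, 4),
                    "designated_qc_fail": int(qc_fail),
                    "seed": config.seed,
                }
            )
    blank_truth = EmbryoTruth("BLANK", "XX", (), "euploid", 0.0)
    for j in range(n_blanks):
        table = simulate_counts(blank_truth, "blank", grid, config, rng)
        sid = f"BLANK{j + 1:02d}_blank"
        table.sample_id = sid
        tables[sid] = table
        rows.append(
            {
                "sample_id": sid,
                "embryo_id": f"BLANK{j + 1:02d}",
                "assay": "blank",
                "sex": "",
                "category": "",
                "icm_karyotype": "",
                "te_karyotype": "",
                "mosaic_fractions": "",
                "maternal_fraction": 0.0,
                "designated_qc_fail": 0,
                "seed": config.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return Cohort(truths=truths, tables=tables, manifest=manifest, grid=grid)
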