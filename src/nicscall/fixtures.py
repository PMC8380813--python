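"""Packaged reference datasets for the concordance engine.

``reference_cohort`` is the published 256-embryo NICS validation cohort at
the binary-call level: for each embryo the whole-embryo (gold standard),
trophectoderm-biopsy (TE-PGT) and spent-medium (NICS) abnormal/normal call
plus each screening assay's prioritization group (A normal, B abnormal,
C MAC).  The per-embryo rows are the unique expansion of the study's
printed pairwise and group contingency tables — those tables are mutually
consistent with exactly one joint distribution, which this file encodes —
so every published summary statistic is recomputable from it.

``reference_chromosome_sets`` is a synthetic reconstruction of the 5,267
per-chromosome comparison sets (22 autosomes + X for each of the 229
non-MAC embryos): only the aggregate agreement counts were published, so
discordant sets are placed on arbitrary embryos/chromosomes while exactly
matching the published region totals.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .genome import CONCORDANCE_CHROMS

#: published agreement region counts over the 5,267 chromosome sets
CHROM_SET_REGIONS = {
    "all_three": 5140,
    "nics_te_only": 37,
    "nics_whole_only": 21,
    "nics_differs_from_both": 69,
}


def load_reference_cohort() -> pd.DataFrame:
    """The 256-embryo validation cohort call table."""
    ref = importlib.resources.files("nicscall.data") / "reference_cohort.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    expected = {"embryo_id", "whole_call", "te_call", "te_group", "nics_call", "nics_group"}
    if set(df.columns) != expected:
        raise ValueError("reference cohort fixture is corrupted")
    return df


def reference_chromosome_sets() -> pd.DataFrame:
    """Synthetic 229-embryo x 23-chromosome status table (see module docstring).

    The 69 sets where NICS differs from both other assays are placed in
    the TE=whole region (the dominant published discordance class); no
    reconstruction embryo reaches the MAC threshold in any assay.
    """
    n_embryos = 229
    rows = []
    k_nics_te = CHROM_SET_REGIONS["nics_te_only"]
    k_nics_whole = CHROM_SET_REGIONS["nics_whole_only"]
    k_nics_diff = CHROM_SET_REGIONS["nics_differs_from_both"]
    for i in range(n_embryos):
        eid = f"NM{i + 1:03d}"
        for j, chrom in enumerate(CONCORDANCE_CHROMS):
            te = nics = whole = "euploid"
            if j == 0:  # at most one discordant set per embryo
                if i < k_nics_te:
                    te = nics = "gain"
                elif i < k_nics_te + k_nics_whole:
                    nics = whole = "gain"
                elif i < k_nics_te + k_nics_whole + k_nics_diff:
                    nics = "gain"
            rows.append(
                {"embryo_id": eid, "chrom": chrom, "te": te, "nics": nics, "whole": whole}
            )
    return pd.DataFrame(rows)
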