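"""End-to-end orchestration: simulate -> call -> classify -> score.

Also builds the full concordance report, either from the packaged
reference cohort (reproducing the published summary tables) or from any
calls table with a gold-standard assay.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import classify as _classify
from .cnv import CopyNumberCaller, default_reference_panel
from .concordance import (
    ChromSetVenn,
    chrom_set_venn,
    cohen_kappa,
    confusion,
    diagnostic_summary,
    exact_paired_test,
    group_table,
    karyotype_concordance,
    secondary_validation,
)
from .fixtures import load_reference_cohort, reference_chromosome_sets
from .genome import CONCORDANCE_CHROMS
from .simulate import Cohort, SimulationConfig, simulate_cohort

#: cohort assay label -> role in the comparison
ASSAY_ROLES = {"whole": "whole", "TE": "te", "medium": "nics"}


def _agreement(table) -> dict:
    """Concordance/kappa block; kappa is None on degenerate marginals."""
    try:
        agr = cohen_kappa(table)
        return {
            "concordance_pct": agr.po_pct,
            "kappa": agr.kappa_3dp,
            "kappa_ci": [round(agr.kappa_ci[0], 3), round(agr.kappa_ci[1], 3)],
        }
    except ValueError:
        arr = table.as_array() if hasattr(table, "as_array") else np.asarray(table, dtype=float)
        po = float(np.trace(arr) / arr.sum())
        from .concordance import round_half_up

        return {"concordance_pct": round_half_up(100 * po, 1), "kappa": None, "kappa_ci": None}


def _pair_section(assay_abn: pd.Series, gold_abn: pd.Series) -> dict:
    ct = confusion(assay_abn, gold_abn)
    diag = diagnostic_summary(ct)
    return {
        "confusion": {"tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn},
        "diagnostics": diag.to_dict(),
        **_agreement(ct),
    }


def _paired_pvalues(te: pd.Series, nics: pd.Series, gold: pd.Series) -> dict:
    """Exact paired tests comparing TE vs NICS correctness per stratum."""
    pos, neg = gold[gold].index, gold[~gold].index
    out = {}
    if len(pos):
        out["sensitivity"] = exact_paired_test(te[pos], nics[pos])
    if len(neg):
        out["specificity"] = exact_paired_test(~te[neg], ~nics[neg])
    return out


def concordance_report(
    calls: pd.DataFrame, chrom_sets: pd.DataFrame | None = None
) -> dict:
    """Full report from a per-embryo calls table.

    ``calls`` needs columns ``embryo_id, whole_call, te_call, te_group,
    nics_call, nics_group`` (calls are "normal"/"abnormal"; groups A/B/C).
    ``chrom_sets`` optionally adds the per-chromosome agreement section.
    """
    df = calls.set_index("embryo_id")
    gold = df["whole_call"].eq("abnormal")
    te = df["te_call"].eq("abnormal")
    nics = df["nics_call"].eq("abnormal")

    def cross(a: pd.Series, b: pd.Series) -> dict:
        tab = np.array(
            [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]],
            dtype=float,
        )
        return _agreement(tab)

    report = {
        "all": {
            "n": len(df),
            "te": _pair_section(te, gold),
            "nics": _pair_section(nics, gold),
            "nics_vs_te": cross(nics, te),
            "paired_p": _paired_pvalues(te, nics, gold),
        }
    }

    nomac = df[(df["te_group"] != "C") & (df["nics_group"] != "C")]
    gm, tm, nm = (
        nomac["whole_call"].eq("abnormal"),
        nomac["te_call"].eq("abnormal"),
        nomac["nics_call"].eq("abnormal"),
    )
    report["mac_excluded"] = {
        "n": len(nomac),
        "te": _pair_section(tm, gm),
        "nics": _pair_section(nm, gm),
        "nics_vs_te": cross(nm, tm),
        "paired_p": _paired_pvalues(tm, nm, gm),
    }

    report["groups"] = {
        "nics": group_table(df["nics_group"], gold).to_dict(orient="records"),
        "te": group_table(df["te_group"], gold).to_dict(orient="records"),
    }

    secondary = {}
    for primary, sec_abn, tag in (("nics", te, "te"), ("te", nics, "nics")):
        for grp in ("B", "C"):
            sv = secondary_validation(df[f"{primary}_group"], sec_abn, gold, grp)
            secondary[f"{primary}_group_{grp}"] = {
                "n": sv.n,
                "secondary_assay": tag,
                "primary_accuracy_pct": sv.primary_accuracy_pct,
                "secondary_accuracy_pct": sv.secondary_accuracy_pct,
                "secondary_accuracy": list(sv.secondary_accuracy),
                "recategorized_normal": sv.recategorized_normal,
                "crosstab": sv.crosstab.to_dict(orient="records"),
            }
    report["secondary_validation"] = secondary

    if chrom_sets is not None:
        report["chromosome_sets"] = chrom_set_venn(chrom_sets).to_dict()
    return report


def reference_report() -> dict:
    """The report on the packaged reference cohort (published tables)."""
    return concordance_report(load_reference_cohort(), reference_chromosome_sets())


# ---------------------------------------------------------------------------
# synthetic-cohort end-to-end


def call_cohort(
    cohort: Cohort,
    caller: CopyNumberCaller | None = None,
    thresholds: _classify.CallThresholds | None = None,
) -> tuple[list, list]:
    """Profile and classify every sample of a cohort.

    Returns ``(profiles, embryo_calls)`` in manifest order.
    """
    if caller is None:
        caller = CopyNumberCaller()
    if not hasattr(caller, "panel_"):
        caller.fit(default_reference_panel(cohort.grid))
    profiles, calls = [], []
    for sid in cohort.manifest["sample_id"]:
        table = cohort.tables[sid]
        profile = caller.predict(table)
        profiles.append(profile)
        embryo_id = sid.rsplit("_", 1)[0]
        calls.append(_classify.call_embryo(profile, embryo_id=embryo_id, thresholds=thresholds))
    return profiles, calls


def calls_to_cohort_table(embryo_calls: list) -> pd.DataFrame:
    """Per-embryo wide table (whole/te/nics call + groups) from sample calls.

    Embryos lacking a QC-passing call in any of the three assays are
    dropped (they would have no conclusive trio result).
    """
    by_embryo: dict[str, dict] = {}
    for ec in embryo_calls:
        role = ASSAY_ROLES.get(ec.assay)
        if role is None:
            continue
        by_embryo.setdefault(ec.embryo_id, {})[role] = ec
    rows = []
    for eid, roles in by_embryo.items():
        if set(roles) != {"whole", "te", "nics"}:
            continue
        if not all(ec.qc_pass for ec in roles.values()):
            continue
        rows.append(
            {
                "embryo_id": eid,
                "whole_call": "abnormal" if roles["whole"].abnormal else "normal",
                "te_call": "abnormal" if roles["te"].abnormal else "normal",
                "te_group": roles["te"].group,
                "nics_call": "abnormal" if roles["nics"].abnormal else "normal",
                "nics_group": roles["nics"].group,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "whole_call", "te_call", "te_group", "nics_call", "nics_group"],
    )


def cohort_chromosome_sets(embryo_calls: list, mac_min: int = 5) -> pd.DataFrame:
    """Long status table of non-MAC embryos with a full qualified trio."""
    by_embryo: dict[str, dict] = {}
    for ec in embryo_calls:
        role = ASSAY_ROLES.get(ec.assay)
        if role and ec.qc_pass:
            by_embryo.setdefault(ec.embryo_id, {})[role] = ec
    rows = []
    for eid, roles in sorted(by_embryo.items()):
        if set(roles) != {"whole", "te", "nics"}:
            continue
        if any(ec.n_abnormal >= mac_min for ec in roles.values()):
            continue
        for chrom in CONCORDANCE_CHROMS:
            rows.append(
                {
                    "embryo_id": eid,
                    "chrom": chrom,
                    "te": roles["te"].calls[chrom].status,
                    "nics": roles["nics"].calls[chrom].status,
                    "whole": roles["whole"].calls[chrom].status,
                }
            )
    return pd.DataFrame(rows, columns=["embryo_id", "chrom", "te", "nics", "whole"])


def run_end_to_end(config: SimulationConfig, caller: CopyNumberCaller | None = None) -> dict:
    """simulate -> call -> classify -> full concordance report."""
    cohort = simulate_cohort(config)
    _, calls = call_cohort(cohort, caller)
    table = calls_to_cohort_table(calls)
    sets = cohort_chromosome_sets(calls)
    report = concordance_report(table, sets if len(sets) else None)
    report["qc"] = {
        "n_embryos": config.n_embryos,
        "n_qualified_trios": len(table),
        "n_excluded": config.n_embryos - len(table),
    }
    return report


def report_markdown(report: dict) -> str:
    """Human-readable summary mirroring the published table layout."""
    lines = ["# Concordance report", ""]
    for scope in ("all", "mac_excluded"):
        if scope not in report:
            continue
        sec = report[scope]
        lines.append(f"## {'All embryos' if scope == 'all' else 'MAC embryos excluded'} (n={sec['n']})")
        lines.append("")
        lines.append("| Assay | Sensitivity | Specificity | NPV | PPV | Concordance | Kappa |")
        lines.append("|---|---|---|---|---|---|---|")
        for assay in ("te", "nics"):
            d = sec[assay]["diagnostics"]

            def fmt(m):
                if d[m] is None:
                    return "–"
                lo, hi = d[m]["ci"]
                return f"{d[m]['pct']} ({lo}–{hi})"

            lines.append(
                f"| {assay.upper()} | {fmt('sensitivity')} | {fmt('specificity')} | "
                f"{fmt('npv')} | {fmt('ppv')} | {sec[assay]['concordance_pct']}% | "
                f"{sec[assay]['kappa']} |"
            )
        x = sec["nics_vs_te"]
        lines.append(f"| NICS vs TE |  |  |  |  | {x['concordance_pct']}% | {x['kappa']} |")
        lines.append("")
    if "groups" in report:
        lines.append("## Prioritization groups")
        lines.append("")
        lines.append("| Assay | Group | n | Consistent with gold | % |")
        lines.append("|---|---|---|---|---|")
        for assay in ("nics", "te"):
            for rec in report["groups"][assay]:
                lines.append(
                    f"| {assay.upper()} | {rec['group']} | {rec['n']} | "
                    f"{rec['consistent']} | {rec['consistent_pct']} |"
                )
        lines.append("")
    if "secondary_validation" in report:
        lines.append("## Secondary validation")
        lines.append("")
        lines.append("| Stratum | n | Primary acc. % | Secondary acc. % | Re-categorized normal |")
        lines.append("|---|---|---|---|---|")
        for key, sv in report["secondary_validation"].items():
            lines.append(
                f"| {key} | {sv['n']} | {sv['primary_accuracy_pct']} | "
                f"{sv['secondary_accuracy_pct']} | {sv['recategorized_normal']} |"
            )
        lines.append("")
    if "chromosome_sets" in report:
        v = report["chromosome_sets"]
        lines.append("## Chromosome-set agreement")
        lines.append("")
        lines.append(f"- total sets: {v['n_sets']}")
        lines.append(f"- concordant in all three assays: {v['all_three']}")
        lines.append(f"- NICS = TE only: {v['nics_te_only']}")
        lines.append(f"- NICS = whole embryo only: {v['nics_whole_only']}")
        lines.append(f"- TE = whole embryo only: {v['te_whole_only']}")
        lines.append(f"- all different: {v['all_different']}")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, json_path, md_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if md_path is not None:
        with open(md_path, "w") as fh:
            fh.write(report_markdown(report))
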