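"""Publication-shaped report tables for scan results.

Demographic rows follow the cohort-table dialect ``N, age mean (sd),
male/female, cases/controls/missing``; scan tables report nominal p-values
in scientific notation (e.g. 1.0E-04) and corrected p-values to three
significant figures, with and without the familial-risk covariate.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .network import BranchPartition
from .treescan import ScanResult


def demographics_row(label: str, subset: pd.DataFrame) -> dict:
    """One demographic table row for a set of subjects."""
    n = len(subset)
    if n == 0:
        return {
            "group": label, "n": 0, "age": "0.00 (0.00)",
            "male_female": "0/0", "cases_controls_missing": "0/0/0",
        }
    age_mean = subset["age"].mean()
    age_sd = subset["age"].std(ddof=1) if n > 1 else 0.0
    males = int((subset["male"] == 1).sum())
    cases = int((subset["ad_status"] == 1).sum())
    ctrls = int((subset["ad_status"] == 0).sum())
    missing = int(subset["ad_status"].isna().sum())
    return {
        "group": label,
        "n": n,
        "age": f"{age_mean:.2f} ({age_sd:.2f})",
        "male_female": f"{males}/{n - males}",
        "cases_controls_missing": f"{cases}/{ctrls}/{missing}",
    }


def report_clade(
    result: ScanResult,
    partitions: Sequence[BranchPartition],
    subjects: pd.DataFrame,
) -> dict:
    """Demographic row for the carriers of a scan result's clade (side_b)."""
    part = next(p for p in partitions if p.branch_id == result.branch_id)
    carriers = subjects[subjects["haplotype"].isin(part.side_b)]
    return demographics_row(result.branch_id, carriers)


def format_nominal_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return f"{p:.1E}"


def format_corrected_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return f"{p:.3g}"


def scan_table(
    results: Sequence[ScanResult],
    with_familial: Optional[Mapping[str, ScanResult]] = None,
) -> pd.DataFrame:
    """Scan results as a table (one row per branch and round).

    ``with_familial`` optionally maps branch id -> the same branch's result
    from a familial-risk-adjusted run, adding the second p-value pair.
    """
    rows = []
    for r in results:
        row = {
            "branch": r.branch_id,
            "round": r.round,
            "nominal_p": format_nominal_p(r.nominal_p),
            "corrected_p": format_corrected_p(r.corrected_p),
            "statistic": "NA" if math.isnan(r.statistic) else f"{r.statistic:.4f}",
            "direction": "NA" if math.isnan(r.beta) else r.direction,
            "cases_controls_side_a": f"{r.n_case_a}/{r.n_ctrl_a}",
            "cases_controls_clade": f"{r.n_case_b}/{r.n_ctrl_b}",
            "defining_variants": ",".join(v.token() for v in r.defining_variants),
            "n_resolutions": r.n_resolutions,
            "degenerate": int(r.degenerate),
        }
        if with_familial is not None:
            fr = with_familial.get(r.branch_id)
            row["nominal_p_famrisk"] = format_nominal_p(fr.nominal_p) if fr else "NA"
            row["corrected_p_famrisk"] = format_corrected_p(fr.corrected_p) if fr else "NA"
        rows.append(row)
    return pd.DataFrame(rows)


def demographics_table(
    subjects: pd.DataFrame,
    significant: Sequence[ScanResult],
    partitions: Sequence[BranchPartition],
) -> pd.DataFrame:
    """Cohort-wide row plus one row per significant clade."""
    rows = [demographics_row("Total", subjects)]
    for r in significant:
        rows.append(report_clade(r, partitions, subjects))
    return pd.DataFrame(rows)
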