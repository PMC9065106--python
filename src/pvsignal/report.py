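"""Summary tables: per-SOC proportions of positive PTs and descriptives.

``soc_positive_proportions`` reproduces the classic radial-plot summary of
a class scan: for each drug and each System Organ Class, the fraction of
Preferred Terms reported with the drug whose IC025 is positive.  A PT
counts as *tested* only if it occurs at least once with the drug — a PT
never reported with the drug is not a tested hypothesis, so the denominator
is the number of distinct PTs reported with the drug in that SOC, not the
dictionary size.

``describe`` computes the per-drug descriptive table (report counts, age
median/IQR, % female, % physician reporters, % reports with a fatal event,
% with a hospitalisation-serious event, PTs per report median/IQR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .icsr import ICSRDataset, normalize_drug_name
from .meddra import TermLevel
from .scan import ScanConfig, _counts_frame, _evaluate_frame

__all__ = ["soc_positive_proportions", "describe"]

PROPORTION_COLUMNS = [
    "soc_code", "soc_name", "drug_name", "n_pt_tested", "n_pt_positive", "proportion",
]


def soc_positive_proportions(ds: ICSRDataset, cfg: ScanConfig) -> pd.DataFrame:
    """One row per (SOC, drug): proportion of tested PTs with positive IC025.

    SOCs where a drug has no positive PT still appear (proportion 0, or NaN
    when no PT in the SOC was reported with the drug at all); filtering
    all-zero SOCs is a display choice, not done here.  In ``soc_axis='all'``
    mode a multi-axial PT contributes to every SOC it belongs to; in
    ``'primary'`` mode (default) the per-drug denominators partition the
    PTs reported with the drug.
    """
    soc_codes = ds.dictionary.level_index[TermLevel.SOC]
    amap = ds.dictionary.pt_ancestor_frame(TermLevel.SOC, soc_axis=cfg.soc_axis)
    amap = amap.rename(columns={"ancestor_code": "soc_code"})
    rows = []
    for drug in cfg.class_drugs:
        ids = ds.reports_with_drug({drug}, roles=cfg.roles)
        counts = _counts_frame(ds, TermLevel.PT, cfg.soc_axis, {drug: ids})
        tested = counts[counts["n_obs"] >= 1]
        res = _evaluate_frame(tested, cfg.ic_method, background=cfg.background)
        res = res.merge(amap, left_on="term_code", right_on="pt_code")
        grp = res.groupby("soc_code")
        n_tested = grp.size()
        n_pos = grp["is_signal"].sum()
        for soc in soc_codes:
            nt = int(n_tested.get(soc, 0))
            np_ = int(n_pos.get(soc, 0))
            rows.append(
                {
                    "soc_code": soc,
                    "soc_name": ds.dictionary.terms[soc].name,
                    "drug_name": drug,
                    "n_pt_tested": nt,
                    "n_pt_positive": np_,
                    "proportion": np_ / nt if nt else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=PROPORTION_COLUMNS)


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    v = values.dropna()
    if v.empty:
        return (np.nan, np.nan, np.nan)
    return (float(v.median()), float(v.quantile(0.25)), float(v.quantile(0.75)))


def describe(ds: ICSRDataset, drug_names) -> pd.DataFrame:
    """Per-drug descriptive summary, one row per drug.

    Missing ages are excluded from the age statistics (count reported in
    ``n_missing_age``); sex percentages use reports with known sex.
    """
    rows = []
    for drug in drug_names:
        norm = normalize_drug_name(drug)
        if not (ds.drugs["drug_name"] == norm).any():
            raise KeyError(f"unknown drug: {drug!r}")
        ids = ds.reports_with_drug({drug})
        rep = ds.reports[ds.reports["report_id"].isin(ids)]
        rxn = ds.reactions[ds.reactions["report_id"].isin(ids)]
        n = len(rep)
        age_med, age_q1, age_q3 = _median_iqr(rep["age_years"])
        sex_known = rep["sex"].isin(["female", "male"])
        pct_female = (
            100.0 * (rep.loc[sex_known, "sex"] == "female").mean()
            if sex_known.any()
            else np.nan
        )
        fatal_ids = set(rxn.loc[rxn["fatal"].astype(bool), "report_id"])
        serious_ids = set(rxn.loc[rxn["serious"].astype(bool), "report_id"])
        pts_per_report = rxn.drop_duplicates(["report_id", "pt_code"]).groupby("report_id").size()
        k_med, k_q1, k_q3 = _median_iqr(pts_per_report)
        rows.append(
            {
                "drug_name": drug,
                "n_reports": n,
                "age_median": age_med,
                "age_q1": age_q1,
                "age_q3": age_q3,
                "n_missing_age": int(rep["age_years"].isna().sum()),
                "pct_female": pct_female,
                "pct_physician_reporter": 100.0 * (rep["reporter"] == "physician").mean(),
                "pct_fatal": 100.0 * len(fatal_ids) / n if n else np.nan,
                "pct_serious": 100.0 * len(serious_ids) / n if n else np.nan,
                "pts_per_report_median": k_med,
                "pts_per_report_q1": k_q1,
                "pts_per_report_q3": k_q3,
            }
        )
    return pd.DataFrame(rows)
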