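"""Staged disproportionality scan over the adverse-event hierarchy.

The scan mirrors the screening strategy used in large spontaneous-report
studies of a drug class:

1. **SOC screen** — IC025 for the whole drug class at the most general
   hierarchy level (System Organ Class).
2. **Drill-down** — for every SOC with a positive class-level IC025, IC025
   for the class and for each drug separately at more specific levels
   (HLGT, HLT by default).
3. **Drug comparisons** — head-to-head reporting odds ratios between class
   members for a configured list of focus events.
4. **Dose stratification** — for drugs with a dose rule (high = daily dose
   strictly over the threshold), IC025 within each stratum and the ROR of
   high- versus low-dose reporting (low dose as reference).

All stages are deterministic given the dataset and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .icsr import ContingencyTable, ICSRDataset
from .meddra import TermLevel
from . import stats
from .stats import RorResult, SignalResult

__all__ = [
    "ScanConfig",
    "ScanReport",
    "TermSignal",
    "soc_screen",
    "drilldown",
    "compare_drugs",
    "dose_stratified_scan",
    "run_scan",
]

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "term_code", "term_name", "level", "drug_scope",
    "n_obs", "n_drug", "n_effect", "n_total",
    "expected", "ic", "ic025", "ic975", "is_signal",
]


@dataclass
class ScanConfig:
    """Configuration of one staged scan."""

    class_drugs: tuple = ()
    soc_axis: str = "primary"  # 'primary' | 'all'
    levels: tuple = (TermLevel.HLGT, TermLevel.HLT)  # drill-down levels
    selected_terms: tuple = ()  # ((term_code, TermLevel), ...) focus events
    dose_rules: dict = field(default_factory=dict)  # drug -> threshold mg/day
    background: str = "full"  # 'full' | 'other_drugs'
    roles: tuple = ("suspected",)
    ic_method: str = "gamma"
    seed: int = 0

    def __post_init__(self):
        self.class_drugs = tuple(self.class_drugs)
        self.levels = tuple(TermLevel[l] if isinstance(l, str) else TermLevel(l) for l in self.levels)
        self.selected_terms = tuple(
            (c, TermLevel[l] if isinstance(l, str) else TermLevel(l))
            for c, l in self.selected_terms
        )
        if any(v <= 0 for v in self.dose_rules.values()):
            raise ValueError("dose thresholds must be positive")
        if list(self.levels) != sorted(self.levels, reverse=True):
            raise ValueError("levels must be ordered general -> specific")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "class_drugs", "soc_axis", "levels", "selected_terms",
            "dose_rules", "background", "roles", "ic_method", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "roles" in kwargs:
            kwargs["roles"] = tuple(kwargs["roles"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "class_drugs": list(self.class_drugs),
            "soc_axis": self.soc_axis,
            "levels": [l.name for l in self.levels],
            "selected_terms": [[c, l.name] for c, l in self.selected_terms],
            "dose_rules": dict(self.dose_rules),
            "background": self.background,
            "roles": list(self.roles),
            "ic_method": self.ic_method,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TermSignal:
    """One scan result row: a SignalResult tagged with term and scope."""

    term_code: str
    term_name: str
    level: TermLevel
    drug_scope: str  # 'class' or a drug name
    signal: SignalResult


def _evaluate_frame(df: pd.DataFrame, method: str, background: str = "full") -> pd.DataFrame:
    """Vectorised IC evaluation over a counts frame (n_obs..n_total columns)."""
    out = df.copy()
    if len(out) == 0:
        for c in ("expected", "ic", "ic025", "ic975"):
            out[c] = pd.Series(dtype=float)
        out["is_signal"] = pd.Series(dtype=bool)
        return out
    n_obs = out["n_obs"].to_numpy(dtype=float)
    n_drug = out["n_drug"].to_numpy(dtype=float)
    n_effect = out["n_effect"].to_numpy(dtype=float)
    n_total = out["n_total"].to_numpy(dtype=float)
    if background == "other_drugs":
        expected = n_drug * (n_effect - n_obs) / (n_total - n_drug)
    else:
        expected = n_drug * n_effect / n_total
    lo, hi = stats.ic_credibility_interval(n_obs, expected, method=method)
    out["expected"] = expected
    out["ic"] = stats.information_component(n_obs, expected)
    out["ic025"] = np.atleast_1d(lo)
    out["ic975"] = np.atleast_1d(hi)
    out["is_signal"] = out["ic025"] > 0.0
    return out


def _rows_to_signals(df: pd.DataFrame) -> list[TermSignal]:
    rows = []
    for r in df.itertuples(index=False):
        table = ContingencyTable(
            n_obs=int(r.n_obs), n_drug=int(r.n_drug),
            n_effect=int(r.n_effect), n_total=int(r.n_total),
        )
        rows.append(
            TermSignal(
                term_code=r.term_code,
                term_name=r.term_name,
                level=TermLevel[r.level] if isinstance(r.level, str) else TermLevel(r.level),
                drug_scope=r.drug_scope,
                signal=SignalResult(
                    table=table, expected=float(r.expected), ic=float(r.ic),
                    ic025=float(r.ic025), ic975=float(r.ic975),
                ),
            )
        )
    return rows


def _report_term_pairs(ds: ICSRDataset, level: TermLevel, soc_axis: str) -> pd.DataFrame:
    """Unique (report_id, ancestor term at level) pairs over all reactions."""
    rx = ds.reactions[["report_id", "pt_code"]].drop_duplicates()
    amap = ds.dictionary.pt_ancestor_frame(level, soc_axis=soc_axis)
    merged = rx.merge(amap, on="pt_code", how="inner")
    return merged[["report_id", "ancestor_code"]].drop_duplicates()


def _counts_frame(
    ds: ICSRDataset,
    level: TermLevel,
    soc_axis: str,
    scopes: dict[str, set],
    term_codes=None,
) -> pd.DataFrame:
    """Counts for every (scope, term at level), vectorised.

    ``scopes`` maps a scope label ('class' or drug name) to its exposed
    report-id set.  Terms with zero reports in the database still appear
    (n_effect = 0) so screens cover the whole level.
    """
    pairs = _report_term_pairs(ds, level, soc_axis)
    if term_codes is None:
        term_codes = ds.dictionary.level_index[level]
    term_codes = sorted(term_codes)
    n_effect_full = pairs.groupby("ancestor_code").size()
    frames = []
    for label, ids in scopes.items():
        in_scope = pairs["report_id"].isin(ids)
        n_obs = pairs[in_scope].groupby("ancestor_code").size()
        df = pd.DataFrame(
            {
                "term_code": term_codes,
                "term_name": [ds.dictionary.terms[c].name for c in term_codes],
                "level": TermLevel(level).name,
                "drug_scope": label,
                "n_obs": [int(n_obs.get(c, 0)) for c in term_codes],
                "n_effect": [int(n_effect_full.get(c, 0)) for c in term_codes],
            }
        )
        df["n_drug"] = len(ids)
        df["n_total"] = ds.n_total
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["term_code", "term_name", "level", "drug_scope", "n_obs", "n_drug", "n_effect", "n_total"]]


def soc_screen(ds: ICSRDataset, cfg: ScanConfig) -> list[TermSignal]:
    """Class-level IC025 for every SOC, sorted by ic025 descending."""
    if not cfg.class_drugs:
        raise ValueError("class_drugs must be non-empty")
    class_ids = ds.reports_with_drug(cfg.class_drugs, roles=cfg.roles)
    df = _counts_frame(ds, TermLevel.SOC, cfg.soc_axis, {"class": class_ids})
    df = _evaluate_frame(df, cfg.ic_method, background=cfg.background)
    df = df.sort_values(["ic025", "term_code"], ascending=[False, True])
    return _rows_to_signals(df)


def drilldown(ds: ICSRDataset, cfg: ScanConfig, positive_socs) -> list[TermSignal]:
    """Class and per-drug IC025 at the drill-down levels under positive SOCs."""
    positive_socs = set(positive_socs)
    unknown = [c for c in positive_socs if c not in ds.dictionary]
    if unknown:
        raise KeyError(f"unknown SOC code(s): {sorted(unknown)}")
    if not positive_socs:
        return []
    scopes = {"class": ds.reports_with_drug(cfg.class_drugs, roles=cfg.roles)}
    for drug in cfg.class_drugs:
        scopes[drug] = ds.reports_with_drug({drug}, roles=cfg.roles)
    results: list[TermSignal] = []
    for level in cfg.levels:
        if level == TermLevel.SOC:
            continue
        gated = [
            c
            for c in ds.dictionary.level_index[level]
            if ds.dictionary.ancestors_at_level(c, TermLevel.SOC, soc_axis=cfg.soc_axis)
            & positive_socs
        ]
        if not gated:
            continue
        df = _counts_frame(ds, level, cfg.soc_axis, scopes, term_codes=gated)
        df = _evaluate_frame(df, cfg.ic_method, background=cfg.background)
        df = df.sort_values(["drug_scope", "ic025"], ascending=[True, False])
        results.extend(_rows_to_signals(df))
    return results


@dataclass(frozen=True)
class ComparisonRow:
    drug_a: str
    drug_b: str
    term_code: str
    term_name: str
    level: TermLevel
    ror: RorResult


def compare_drugs(ds: ICSRDataset, cfg: ScanConfig) -> list[ComparisonRow]:
    """Head-to-head RORs for all ordered drug pairs x selected focus events."""
    if not cfg.selected_terms:
        raise ValueError("selected_terms must be non-empty for drug comparisons")
    for code, level in cfg.selected_terms:
        flagged = False
        for drug in cfg.class_drugs:
            t = ds.contingency({drug}, code, level, roles=cfg.roles)
            if stats.evaluate_signal(t, method=cfg.ic_method).is_signal:
                flagged = True
                break
        if not flagged:
            logger.warning(
                "selected term %s has no positive IC025 for any class drug", code
            )
    rows = []
    for code, level in cfg.selected_terms:
        name = ds.dictionary.terms[code].name
        for drug_a in cfg.class_drugs:
            for drug_b in cfg.class_drugs:
                if drug_a == drug_b:
                    continue
                ror = stats.ror_drug_vs_drug(
                    ds, drug_a, drug_b, code, level, roles=cfg.roles
                )
                rows.append(ComparisonRow(drug_a, drug_b, code, name, level, ror))
    return rows


@dataclass(frozen=True)
class DoseTermResult:
    """Per-term dose-stratified output for one drug.

    ``high``/``low`` are within-stratum IC results (exposure restricted to
    the stratum, background per config); ``ror`` is high- vs low-dose with
    the low stratum as reference.
    """

    drug: str
    term_code: str
    term_name: str
    level: TermLevel
    threshold_mg: float
    n_high: int
    n_low: int
    n_missing_dose: int
    high: SignalResult
    low: SignalResult
    ror: RorResult


def _stratum_signal(ds, ids, event_ids):
    return ContingencyTable(
        n_obs=len(ids & event_ids),
        n_drug=len(ids),
        n_effect=len(event_ids),
        n_total=ds.n_total,
    )


def dose_stratified_scan(ds: ICSRDataset, cfg: ScanConfig, drug: str) -> list[DoseTermResult]:
    """IC per dose stratum and high-vs-low ROR for each selected term.

    High dose means daily dose strictly over the drug's threshold; reports
    lacking a dose are excluded from stratification (count recorded).  A
    term is skipped with a warning when either stratum has zero reports.
    """
    if drug not in cfg.dose_rules:
        raise ValueError(f"drug {drug!r} has no dose rule")
    thr = float(cfg.dose_rules[drug])
    drug_ids = ds.reports_with_drug({drug}, roles=cfg.roles)
    d = ds.drugs
    mask = (d["drug_name"] == drug.strip().lower()) & d["role"].isin(cfg.roles)
    dosed = d.loc[mask & d["daily_dose_mg"].notna()]
    high_ids = set(dosed.loc[dosed["daily_dose_mg"] > thr, "report_id"])
    low_ids = set(dosed.loc[dosed["daily_dose_mg"] <= thr, "report_id"]) - high_ids
    n_missing = len(drug_ids - high_ids - low_ids)
    if n_missing:
        logger.info("%s: %d report(s) lack daily_dose_mg, excluded", drug, n_missing)
    out = []
    for code, level in cfg.selected_terms:
        if not high_ids or not low_ids:
            logger.warning("%s/%s: empty dose stratum, term skipped", drug, code)
            continue
        event_ids = ds.reports_with_event(code, level)
        th = _stratum_signal(ds, high_ids, event_ids)
        tl = _stratum_signal(ds, low_ids, event_ids)
        ror = stats.reporting_odds_ratio(th.n_obs, th.n_drug - th.n_obs,
                                         tl.n_obs, tl.n_drug - tl.n_obs)
        out.append(
            DoseTermResult(
                drug=drug,
                term_code=code,
                term_name=ds.dictionary.terms[code].name,
                level=level,
                threshold_mg=thr,
                n_high=len(high_ids),
                n_low=len(low_ids),
                n_missing_dose=n_missing,
                high=stats.evaluate_signal(th, method=cfg.ic_method, background=cfg.background),
                low=stats.evaluate_signal(tl, method=cfg.ic_method, background=cfg.background),
                ror=ror,
            )
        )
    return out


@dataclass
class ScanReport:
    """Full staged-scan output plus run metadata."""

    soc_results: list = field(default_factory=list)
    drilldown_results: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)
    dose_results: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    @property
    def positive_socs(self) -> list[str]:
        return [r.term_code for r in self.soc_results if r.signal.is_signal]

    # -- serialization -----------------------------------------------------

    @staticmethod
    def _signal_frame(rows) -> pd.DataFrame:
        recs = []
        for r in rows:
            s = r.signal
            t = s.table
            recs.append(
                {
                    "term_code": r.term_code, "term_name": r.term_name,
                    "level": r.level.name, "drug_scope": r.drug_scope,
                    "n_obs": t.n_obs, "n_drug": t.n_drug,
                    "n_effect": t.n_effect, "n_total": t.n_total,
                    "expected": s.expected, "ic": s.ic,
                    "ic025": s.ic025, "ic975": s.ic975,
                    "is_signal": s.is_signal,
                }
            )
        return pd.DataFrame(recs, columns=SIGNAL_COLUMNS)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        comp = pd.DataFrame(
            [
                {
                    "drug_a": r.drug_a, "drug_b": r.drug_b,
                    "term_code": r.term_code, "term_name": r.term_name,
                    "level": r.level.name,
                    "a": r.ror.a, "b": r.ror.b, "c": r.ror.c, "d": r.ror.d,
                    "ror": r.ror.ror, "ci_low": r.ror.ci_low,
                    "ci_high": r.ror.ci_high,
                    "continuity_corrected": r.ror.continuity_corrected,
                }
                for r in self.comparisons
            ],
            columns=[
                "drug_a", "drug_b", "term_code", "term_name", "level",
                "a", "b", "c", "d", "ror", "ci_low", "ci_high",
                "continuity_corrected",
            ],
        )
        dose = pd.DataFrame(
            [
                {
                    "drug": r.drug, "term_code": r.term_code,
                    "term_name": r.term_name, "level": r.level.name,
                    "threshold_mg": r.threshold_mg,
                    "n_high": r.n_high, "n_low": r.n_low,
                    "n_missing_dose": r.n_missing_dose,
                    "ic_high": r.high.ic, "ic025_high": r.high.ic025,
                    "is_signal_high": r.high.is_signal,
                    "ic_low": r.low.ic, "ic025_low": r.low.ic025,
                    "is_signal_low": r.low.is_signal,
                    "ror_high_vs_low": r.ror.ror,
                    "ci_low": r.ror.ci_low, "ci_high": r.ror.ci_high,
                    "continuity_corrected": r.ror.continuity_corrected,
                }
                for r in self.dose_results
            ],
            columns=[
                "drug", "term_code", "term_name", "level", "threshold_mg",
                "n_high", "n_low", "n_missing_dose",
                "ic_high", "ic025_high", "is_signal_high",
                "ic_low", "ic025_low", "is_signal_low",
                "ror_high_vs_low", "ci_low", "ci_high", "continuity_corrected",
            ],
        )
        return {
            "soc_screen": self._signal_frame(self.soc_results),
            "drilldown": self._signal_frame(self.drilldown_results),
            "comparisons": comp,
            "dose_stratified": dose,
        }

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in self.to_frames().items():
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False, float_format="%.6g")
            paths[name] = p
        meta = out / "metadata.json"
        meta.write_text(json.dumps({"metadata": self.metadata, "errors": self.errors}, indent=2))
        paths["metadata"] = meta
        return paths


def run_scan(ds: ICSRDataset, cfg: ScanConfig) -> ScanReport:
    """Run all scan stages; deterministic given (dataset, config).

    A stage failure is recorded in ``report.errors`` and later stages still
    run where their inputs allow.
    """
    report = ScanReport()
    class_ids = ds.reports_with_drug(cfg.class_drugs, roles=cfg.roles)
    per_drug = {
        d: ds.reports_with_drug({d}, roles=cfg.roles) for d in cfg.class_drugs
    }
    n_co_suspected = sum(len(a & b) for i, a in enumerate(per_drug.values())
                         for b in list(per_drug.values())[i + 1:])
    report.metadata = {
        "config": cfg.to_dict(),
        "n_total_reports": ds.n_total,
        "n_class_reports": len(class_ids),
        "reports_per_drug": {d: len(v) for d, v in per_drug.items()},
        "n_co_suspected_reports": n_co_suspected,
        "n_rejected_no_reaction": ds.n_rejected_no_reaction,
    }
    try:
        report.soc_results = soc_screen(ds, cfg)
    except Exception as e:  # pragma: no cover - defensive
        report.errors.append({"stage": "soc_screen", "error": str(e)})
        return report
    try:
        report.drilldown_results = drilldown(ds, cfg, report.positive_socs)
    except Exception as e:
        report.errors.append({"stage": "drilldown", "error": str(e)})
    if cfg.selected_terms:
        try:
            report.comparisons = compare_drugs(ds, cfg)
        except Exception as e:
            report.errors.append({"stage": "compare_drugs", "error": str(e)})
        for drug in cfg.dose_rules:
            if drug not in cfg.class_drugs:
                continue
            try:
                report.dose_results.extend(dose_stratified_scan(ds, cfg, drug))
            except Exception as e:
                report.errors.append(
                    {"stage": "dose_stratified_scan", "drug": drug, "error": str(e)}
                )
    return report
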