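"""Synthetic spontaneous-reporting database generator.

Emulates the statistical structure of a large pharmacovigilance database:
a big background of reports for many uninteresting drugs, a handful of
index drugs with distinct demographic/indication/dose profiles, multi-event
reports (median 2 PTs per report, IQR 1-3), and *planted* drug-event
associations of known relative reporting rate at a chosen hierarchy level.

Event generation model
----------------------
Each report draws K = 1 + Poisson(lambda) reaction PTs (lambda tuned so the
PT-per-report distribution has median 2 and IQR 1-3) from a power-law
weight vector over all PTs in the dictionary (rank-r weight proportional to
r^-alpha).  For an index drug with a planted signal (term, rate_ratio), the
weights of all PTs under the term are multiplied by rate_ratio and the
vector renormalised — so a planted signal slightly deflates the other
events for that drug, and recovery checks at small n should use realised,
not nominal, ratios.  A planted signal may be restricted to a dose stratum
(e.g. only high-dose reports of the drug).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .meddra import (
    MedDRADictionary,
    Term,
    TermLevel,
    load_dictionary,
    write_dictionary,
)
from .icsr import (
    DRUG_COLUMNS,
    REACTION_COLUMNS,
    REPORT_COLUMNS,
    ICSRDataset,
    read_icsr_dataset,
)

__all__ = [
    "DrugProfile",
    "PlantedSignal",
    "GeneratorConfig",
    "GroundTruth",
    "generate_dictionary",
    "generate_dataset",
    "write_dataset",
    "default_config",
]


@dataclass(frozen=True)
class DrugProfile:
    """Reporting profile of one index drug.

    ``dose_options`` is a tuple of (daily dose in mg/day or None for a
    missing dose field, probability); probabilities must sum to 1.  Ages are
    drawn from a normal distribution parameterised by the median and IQR
    (quartiles at median +/- 0.6745 sd), truncated to [0, 100].
    """

    name: str
    n_reports: int
    dose_options: tuple = ((None, 1.0),)
    indications: tuple = (("unspecified", 1.0),)
    age_median: float = 60.0
    age_iqr: tuple = (48.0, 72.0)
    frac_female: float = 0.5
    frac_physician: float = 0.2
    frac_fatal: float = 0.02
    frac_serious: float = 0.12


@dataclass(frozen=True)
class PlantedSignal:
    """A drug-event association planted at a known relative reporting rate.

    ``stratum``/``dose_threshold_mg`` optionally restrict the boost to the
    high (dose > threshold) or low (dose <= threshold) stratum of the drug.
    """

    drug_name: str
    term_code: str
    level: TermLevel
    rate_ratio: float
    stratum: str | None = None  # 'high' | 'low' | None
    dose_threshold_mg: float | None = None

    def __post_init__(self):
        if self.rate_ratio <= 0:
            raise ValueError("rate_ratio must be > 0")
        if self.stratum is not None:
            if self.stratum not in ("high", "low"):
                raise ValueError("stratum must be 'high', 'low' or None")
            if self.dose_threshold_mg is None:
                raise ValueError("a stratum restriction needs dose_threshold_mg")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_background_reports: int = 200_000
    n_background_drugs: int = 50
    drug_profiles: tuple = ()
    dictionary_shape: tuple = (27, 3, 3, 3)  # (n_soc, hlgt/soc, hlt/hlgt, pt/hlt)
    multiaxial_fraction: float = 0.0
    baseline_power_law_alpha: float = 1.0
    events_per_report_lambda: float = 1.38  # K = 1 + Poisson(lambda)
    planted_signals: tuple = ()

    def __post_init__(self):
        if any(s < 1 for s in self.dictionary_shape):
            raise ValueError("dictionary_shape entries must all be >= 1")


@dataclass
class GroundTruth:
    """Echo of the planted signals with realised counts for recovery checks."""

    planted: list = field(default_factory=list)  # dicts per planted signal
    reports_per_drug: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "reports_per_drug": self.reports_per_drug},
            indent=2,
        )


def default_config(
    seed: int = 0,
    n_background_reports: int = 200_000,
    n_index_reports: int = 5_000,
    planted_signals: tuple = (),
) -> GeneratorConfig:
    """Three index drugs with realistic, distinct profiles.

    The defaults mirror typical spontaneous-reporting descriptives for the
    first three approved JAK inhibitors: ruxolitinib reports skew older
    (median age 70) with myeloproliferative-neoplasm indications and a high
    fatal fraction; tofacitinib and baricitinib reports skew female (~78%)
    with rheumatoid-arthritis indications and the marketed daily doses
    (tofacitinib 5/10 mg, baricitinib 2/4 mg).
    """
    profiles = (
        DrugProfile(
            name="ruxolitinib",
            n_reports=n_index_reports,
            dose_options=((10.0, 0.3), (20.0, 0.3), (30.0, 0.25), (None, 0.15)),
            indications=(
                ("myelofibrosis", 0.435),
                ("polycythemia vera", 0.193),
                ("other", 0.372),
            ),
            age_median=70.0,
            age_iqr=(60.0, 78.0),
            frac_female=0.49,
            frac_physician=0.29,
            frac_fatal=0.140,
            frac_serious=0.163,
        ),
        DrugProfile(
            name="tofacitinib",
            n_reports=n_index_reports,
            dose_options=((5.0, 0.40), (10.0, 0.45), (None, 0.15)),
            indications=(("rheumatoid arthritis", 0.55), ("other", 0.45)),
            age_median=61.0,
            age_iqr=(50.0, 70.0),
            frac_female=0.78,
            frac_physician=0.12,
            frac_fatal=0.019,
            frac_serious=0.096,
        ),
        DrugProfile(
            name="baricitinib",
            n_reports=n_index_reports,
            dose_options=((2.0, 0.40), (4.0, 0.45), (None, 0.15)),
            indications=(("rheumatoid arthritis", 0.797), ("other", 0.203)),
            age_median=61.0,
            age_iqr=(50.0, 70.0),
            frac_female=0.78,
            frac_physician=0.13,
            frac_fatal=0.014,
            frac_serious=0.129,
        ),
    )
    return GeneratorConfig(
        seed=seed,
        n_background_reports=n_background_reports,
        drug_profiles=profiles,
        planted_signals=tuple(planted_signals),
    )


# -- dictionary ------------------------------------------------------------


def generate_dictionary(
    shape=(27, 3, 3, 3), multiaxial_fraction: float = 0.0, seed: int = 0
) -> MedDRADictionary:
    """Balanced four-level tree (plus one LLT per PT) with deterministic codes.

    Codes are hierarchical: SOC ``S01``, HLGT ``S01G02``, HLT ``S01G02T03``,
    PT ``S01G02T03P01``, LLT = PT code + ``L01``.  With
    ``multiaxial_fraction > 0``, that fraction of PTs receives a second HLT
    parent drawn from another SOC; the original SOC stays primary.
    """
    n_soc, n_hlgt, n_hlt, n_pt = shape
    rng = np.random.default_rng(seed)
    terms: list[Term] = []
    pt_entries: list[tuple[str, str, str]] = []  # (code, hlt parent, soc)
    hlt_codes: list[tuple[str, str]] = []  # (code, soc)
    for s in range(1, n_soc + 1):
        soc = f"S{s:02d}"
        terms.append(Term(soc, f"System Organ Class {s:02d}", TermLevel.SOC))
        for g in range(1, n_hlgt + 1):
            hlgt = f"{soc}G{g:02d}"
            terms.append(
                Term(hlgt, f"Group term {hlgt}", TermLevel.HLGT, frozenset({soc}))
            )
            for t in range(1, n_hlt + 1):
                hlt = f"{hlgt}T{t:02d}"
                terms.append(
                    Term(hlt, f"High level term {hlt}", TermLevel.HLT, frozenset({hlgt}))
                )
                hlt_codes.append((hlt, soc))
                for p in range(1, n_pt + 1):
                    pt = f"{hlt}P{p:02d}"
                    pt_entries.append((pt, hlt, soc))

    n_multi = int(round(multiaxial_fraction * len(pt_entries)))
    multi_idx = set(
        rng.choice(len(pt_entries), size=n_multi, replace=False).tolist()
        if n_multi
        else []
    )
    for i, (pt, hlt, soc) in enumerate(pt_entries):
        parents = {hlt}
        if i in multi_idx and n_soc > 1:
            foreign = [h for h, s_ in hlt_codes if s_ != soc]
            parents.add(foreign[int(rng.integers(len(foreign)))])
        terms.append(
            Term(
                pt,
                f"Preferred term {pt}",
                TermLevel.PT,
                frozenset(parents),
                primary_soc=soc,
            )
        )
        terms.append(
            Term(f"{pt}L01", f"Lowest level term {pt}L01", TermLevel.LLT, frozenset({pt}))
        )
    return MedDRADictionary(terms)


# -- dataset ---------------------------------------------------------------


def _sample_categorical(rng, options, n):
    """options: sequence of (value, prob). Returns an object array of values."""
    values = [v for v, _ in options]
    probs = np.array([p for _, p in options], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"probabilities must sum to 1, got {probs.sum()}")
    idx = rng.choice(len(values), size=n, p=probs / probs.sum())
    return np.array(values, dtype=object)[idx]


def _sample_ages(rng, median, iqr, n):
    sd = (iqr[1] - iqr[0]) / (2 * 0.6744897501960817)
    return np.clip(np.round(rng.normal(median, sd, size=n), 1), 0.0, 100.0)


def _boosted_weights(base, dictionary, signals, drug, stratum_of=None):
    """Multiply baseline PT weights under each planted term, renormalise."""
    pt_codes = dictionary.level_index[TermLevel.PT]
    pos = {c: i for i, c in enumerate(pt_codes)}
    w = base.copy()
    for sig in signals:
        if sig.drug_name != drug or (sig.stratum or None) != stratum_of:
            continue
        under = dictionary.descendants_at_level(sig.term_code, TermLevel.PT)
        idx = [pos[c] for c in under]
        w[idx] *= sig.rate_ratio
    return w / w.sum()


def generate_dataset(cfg: GeneratorConfig, dictionary: MedDRADictionary | None = None):
    """Generate a full synthetic database.

    Returns ``(ICSRDataset, GroundTruth)``.  Background reports carry one
    suspected background drug each; index-drug reports carry the index drug
    as suspected with dose/indication/demographics from its profile.
    """
    rng = np.random.default_rng(cfg.seed)
    if dictionary is None:
        dictionary = generate_dictionary(
            cfg.dictionary_shape, cfg.multiaxial_fraction, seed=cfg.seed
        )
    pt_codes = np.array(dictionary.level_index[TermLevel.PT], dtype=object)
    n_pt = len(pt_codes)
    for sig in cfg.planted_signals:
        if sig.term_code not in dictionary:
            raise ValueError(f"planted term {sig.term_code!r} not in dictionary")
    ranks = np.arange(1, n_pt + 1, dtype=float)
    baseline = ranks ** (-cfg.baseline_power_law_alpha)
    baseline /= baseline.sum()

    rep_rows: list[pd.DataFrame] = []
    drug_rows: list[pd.DataFrame] = []
    rxn_report: list[np.ndarray] = []
    rxn_pt: list[np.ndarray] = []
    next_id = 0

    def _new_ids(n):
        nonlocal next_id
        ids = np.array([f"R{j:08d}" for j in range(next_id, next_id + n)], dtype=object)
        next_id += n
        return ids

    def _draw_events(ids, weights):
        k = 1 + rng.poisson(cfg.events_per_report_lambda, size=len(ids))
        draws = rng.choice(n_pt, size=int(k.sum()), p=weights)
        rxn_report.append(np.repeat(ids, k))
        rxn_pt.append(pt_codes[draws])
        return k

    # background block
    n_bg = cfg.n_background_reports
    if n_bg:
        ids = _new_ids(n_bg)
        _draw_events(ids, baseline)
        bg_names = np.array(
            [f"background-{i + 1:03d}" for i in range(cfg.n_background_drugs)],
            dtype=object,
        )
        rep_rows.append(
            pd.DataFrame(
                {
                    "report_id": ids,
                    "age_years": _sample_ages(rng, 58.0, (45.0, 72.0), n_bg),
                    "sex": _sample_categorical(
                        rng, (("female", 0.52), ("male", 0.46), ("unknown", 0.02)), n_bg
                    ),
                    "reporter": _sample_categorical(
                        rng,
                        (
                            ("physician", 0.25),
                            ("other_health_professional", 0.35),
                            ("consumer", 0.35),
                            ("other", 0.05),
                        ),
                        n_bg,
                    ),
                    "country": "XX",
                }
            )
        )
        drug_rows.append(
            pd.DataFrame(
                {
                    "report_id": ids,
                    "drug_name": bg_names[rng.integers(0, len(bg_names), size=n_bg)],
                    "role": "suspected",
                    "daily_dose_mg": np.nan,
                    "indication": "unspecified",
                }
            )
        )

    truth = GroundTruth()
    for prof in cfg.drug_profiles:
        n = prof.n_reports
        ids = _new_ids(n)
        dose = _sample_categorical(rng, prof.dose_options, n)
        dose = np.array([np.nan if d is None else float(d) for d in dose])
        # stratum-restricted boosts need the dose before event sampling
        strata = sorted(
            {
                (s.stratum, s.dose_threshold_mg)
                for s in cfg.planted_signals
                if s.drug_name == prof.name and s.stratum is not None
            }
        )
        assigned = np.zeros(n, dtype=bool)
        for stratum, thr in strata:
            mask = (
                (~np.isnan(dose)) & (dose > thr)
                if stratum == "high"
                else (~np.isnan(dose)) & (dose <= thr)
            ) & ~assigned
            assigned |= mask
            w = _boosted_weights(
                baseline, dictionary, cfg.planted_signals, prof.name, stratum
            )
            # unstratified signals for the drug also apply inside the stratum
            w = _boosted_weights(w, dictionary, cfg.planted_signals, prof.name, None)
            if mask.any():
                _draw_events(ids[mask], w)
        rest = ~assigned
        if rest.any():
            w = _boosted_weights(baseline, dictionary, cfg.planted_signals, prof.name, None)
            _draw_events(ids[rest], w)

        rep_rows.append(
            pd.DataFrame(
                {
                    "report_id": ids,
                    "age_years": _sample_ages(rng, prof.age_median, prof.age_iqr, n),
                    "sex": _sample_categorical(
                        rng,
                        (
                            ("female", prof.frac_female),
                            ("male", max(0.0, 0.98 - prof.frac_female)),
                            ("unknown", 0.02),
                        ),
                        n,
                    ),
                    "reporter": _sample_categorical(
                        rng,
                        (
                            ("physician", prof.frac_physician),
                            ("other_health_professional", 0.3),
                            ("consumer", max(0.0, 0.65 - prof.frac_physician)),
                            ("other", 0.05),
                        ),
                        n,
                    ),
                    "country": "XX",
                }
            )
        )
        drug_rows.append(
            pd.DataFrame(
                {
                    "report_id": ids,
                    "drug_name": prof.name,
                    "role": "suspected",
                    "daily_dose_mg": dose,
                    "indication": _sample_categorical(rng, prof.indications, n),
                }
            )
        )
        truth.reports_per_drug[prof.name] = int(n)

    reports = pd.concat(rep_rows, ignore_index=True)
    drugs = pd.concat(drug_rows, ignore_index=True)
    rxn_ids = np.concatenate(rxn_report)
    reactions = pd.DataFrame(
        {
            "report_id": rxn_ids,
            "pt_code": np.concatenate(rxn_pt),
            "serious": False,
            "fatal": False,
        }
    )

    # per-report fatal / serious flags applied to the first reaction row
    fatal_p = pd.Series(0.05, index=reports["report_id"])
    serious_p = pd.Series(0.12, index=reports["report_id"])
    for prof in cfg.drug_profiles:
        sel = drugs.loc[drugs["drug_name"] == prof.name, "report_id"]
        fatal_p.loc[sel] = prof.frac_fatal
        serious_p.loc[sel] = prof.frac_serious
    first = ~reactions["report_id"].duplicated()
    u = rng.random(len(reports))
    v = rng.random(len(reports))
    fatal_ids = set(reports.loc[u < fatal_p.to_numpy(), "report_id"])
    serious_ids = set(reports.loc[v < serious_p.to_numpy(), "report_id"])
    reactions.loc[first & reactions["report_id"].isin(fatal_ids), "fatal"] = True
    reactions.loc[first & reactions["report_id"].isin(serious_ids), "serious"] = True

    ds = ICSRDataset(reports, drugs, reactions, dictionary)
    for sig in cfg.planted_signals:
        t = ds.contingency({sig.drug_name}, sig.term_code, sig.level)
        truth.planted.append(
            {
                "drug_name": sig.drug_name,
                "term_code": sig.term_code,
                "level": TermLevel(sig.level).name,
                "rate_ratio": sig.rate_ratio,
                "stratum": sig.stratum,
                "dose_threshold_mg": sig.dose_threshold_mg,
                "n_obs": t.n_obs,
                "n_expected": t.n_drug * t.n_effect / t.n_total,
            }
        )
    return ds, truth


def write_dataset(ds: ICSRDataset, out_dir, ground_truth: GroundTruth | None = None):
    """Write the three ICSR CSVs, the dictionary CSV and the ground-truth JSON.

    ``read_icsr_dataset`` on the written files round-trips the dataset.
    Returns the dict of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reports": out / "reports.csv",
        "drugs": out / "drugs.csv",
        "reactions": out / "reactions.csv",
        "dictionary": out / "dictionary.csv",
    }
    ds.reports[REPORT_COLUMNS].to_csv(paths["reports"], index=False)
    ds.drugs[DRUG_COLUMNS].to_csv(paths["drugs"], index=False)
    ds.reactions[REACTION_COLUMNS].to_csv(paths["reactions"], index=False)
    write_dictionary(ds.dictionary, paths["dictionary"])
    if ground_truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        paths["ground_truth"].write_text(ground_truth.to_json())
    return paths


def read_dataset(data_dir) -> ICSRDataset:
    """Load a directory written by :func:`write_dataset`."""
    d = Path(data_dir)
    dictionary = load_dictionary(d / "dictionary.csv")
    return read_icsr_dataset(
        d / "reports.csv", d / "drugs.csv", d / "reactions.csv", dictionary
    )
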