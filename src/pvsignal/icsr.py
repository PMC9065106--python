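"""Individual case safety reports (ICSRs) and 2x2 contingency counting.

An ICSR is one spontaneous report linking one or more drugs (with a reporter
role: suspected, concomitant or interacting, and an optional daily dose) to
one or more coded reactions (PT-level MedDRA codes).  Disproportionality
statistics are built from report-level 2x2 tables: for a drug set D and an
event term t at hierarchy level L,

    n_obs    reports with a drug in D (matching role) AND >=1 reaction under t
    n_drug   reports with a drug in D
    n_effect reports with >=1 reaction under t, regardless of drug
    n_total  all reports in the database

Counting is per report, never per reaction row: a report mentioning three
sibling PTs under one HLT counts once for that HLT.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .meddra import MedDRADictionary, TermLevel

__all__ = [
    "DrugRole",
    "DrugMention",
    "ReactionMention",
    "ICSR",
    "ICSRDataset",
    "ContingencyTable",
    "read_icsr_dataset",
    "reports_with_drug",
    "reports_with_event",
    "contingency",
    "DatasetIntegrityError",
]

logger = logging.getLogger(__name__)


class DatasetIntegrityError(ValueError):
    """Raised when ICSR tables violate a dataset invariant."""


class DrugRole(str, enum.Enum):
    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


def normalize_drug_name(name: str) -> str:
    """Case-insensitive exact matching: lower-cased, surrounding space stripped."""
    return str(name).strip().lower()


@dataclass(frozen=True)
class DrugMention:
    drug_name: str
    role: str = DrugRole.SUSPECTED.value
    daily_dose_mg: float | None = None
    indication: str | None = None

    def __post_init__(self):
        if self.daily_dose_mg is not None:
            d = float(self.daily_dose_mg)
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"daily_dose_mg must be finite and >= 0, got {d}")


@dataclass(frozen=True)
class ReactionMention:
    pt_code: str
    serious: bool = False
    fatal: bool = False


@dataclass(frozen=True)
class ICSR:
    report_id: str
    drugs: tuple[DrugMention, ...]
    reactions: tuple[ReactionMention, ...]
    age_years: float | None = None
    sex: str | None = None
    reporter: str | None = None
    country: str | None = None


# canonical column sets of the three tables
REPORT_COLUMNS = ["report_id", "age_years", "sex", "reporter", "country"]
DRUG_COLUMNS = ["report_id", "drug_name", "role", "daily_dose_mg", "indication"]
REACTION_COLUMNS = ["report_id", "pt_code", "serious", "fatal"]


class ICSRDataset:
    """Report store backed by three tidy tables plus the active dictionary.

    ``reports``/``drugs``/``reactions`` are pandas DataFrames with the
    canonical columns above; ``drug_name`` is stored normalised.  All
    ``pt_code`` values must resolve to PT-level terms in ``dictionary``.
    """

    def __init__(
        self,
        reports: pd.DataFrame,
        drugs: pd.DataFrame,
        reactions: pd.DataFrame,
        dictionary: MedDRADictionary,
        n_rejected_no_reaction: int = 0,
    ) -> None:
        reports = reports.reset_index(drop=True)
        self.reports = reports[REPORT_COLUMNS].copy()
        self.drugs = drugs[DRUG_COLUMNS].copy()
        self.reactions = reactions[REACTION_COLUMNS].copy()
        self.drugs["drug_name"] = self.drugs["drug_name"].map(normalize_drug_name)
        self.dictionary = dictionary
        self.n_rejected_no_reaction = int(n_rejected_no_reaction)
        self._validate()
        self._event_ids_cache: dict[tuple, frozenset] = {}

    def _validate(self) -> None:
        rid = self.reports["report_id"]
        if rid.duplicated().any():
            dups = sorted(rid[rid.duplicated()].unique()[:5])
            raise DatasetIntegrityError(f"duplicate report_id(s): {dups}")
        known = set(rid)
        for name, frame in (("drugs", self.drugs), ("reactions", self.reactions)):
            bad = set(frame["report_id"]) - known
            if bad:
                raise DatasetIntegrityError(
                    f"{name} table references unknown report_id(s): "
                    f"{sorted(bad)[:5]}"
                )
        with_reaction = set(self.reactions["report_id"])
        missing = known - with_reaction
        if missing:
            raise DatasetIntegrityError(
                f"{len(missing)} report(s) have no reaction rows, e.g. "
                f"{sorted(missing)[:5]}"
            )
        pt_codes = self.reactions["pt_code"].unique()
        unknown = [
            c
            for c in pt_codes
            if c not in self.dictionary
            or self.dictionary.level_of(c) != TermLevel.PT
        ]
        if unknown:
            raise DatasetIntegrityError(
                f"reaction pt_code(s) not resolving to PT terms: {sorted(unknown)[:10]}"
            )

    @property
    def n_total(self) -> int:
        return len(self.reports)

    @property
    def report_ids(self) -> pd.Series:
        return self.reports["report_id"]

    @classmethod
    def from_records(cls, records, dictionary: MedDRADictionary) -> "ICSRDataset":
        """Build a dataset from an iterable of :class:`ICSR` records."""
        rep_rows, drug_rows, rxn_rows = [], [], []
        n_rejected = 0
        for r in records:
            if not r.reactions:
                n_rejected += 1
                continue
            rep_rows.append(
                (r.report_id, r.age_years, r.sex, r.reporter, r.country)
            )
            for d in r.drugs:
                drug_rows.append(
                    (r.report_id, d.drug_name, str(d.role), d.daily_dose_mg, d.indication)
                )
            for x in r.reactions:
                rxn_rows.append((r.report_id, x.pt_code, x.serious, x.fatal))
        if n_rejected:
            logger.warning("rejected %d report(s) lacking reactions", n_rejected)
        return cls(
            pd.DataFrame(rep_rows, columns=REPORT_COLUMNS),
            pd.DataFrame(drug_rows, columns=DRUG_COLUMNS),
            pd.DataFrame(rxn_rows, columns=REACTION_COLUMNS),
            dictionary,
            n_rejected_no_reaction=n_rejected,
        )

    # -- core report-set queries -------------------------------------------

    def reports_with_drug(self, drug_names, roles=None) -> set[str]:
        """Report ids with >=1 drug mention matching name and role.

        Default ``roles={'suspected'}`` matches the exposure definition used
        throughout: only reports where the drug was designated a suspect.
        """
        names = {normalize_drug_name(n) for n in drug_names}
        if not names:
            raise ValueError("drug_names must be non-empty")
        if roles is None:
            roles = {DrugRole.SUSPECTED.value}
        roles = {str(r) for r in roles}
        mask = self.drugs["drug_name"].isin(names) & self.drugs["role"].isin(roles)
        return set(self.drugs.loc[mask, "report_id"])

    def _pts_under(self, term_code: str, level: TermLevel) -> set[str]:
        term_level = self.dictionary.level_of(term_code)  # KeyError if unknown
        if term_level != level:
            raise ValueError(
                f"term {term_code!r} is at level {term_level.name}, "
                f"not {TermLevel(level).name}"
            )
        return self.dictionary.descendants_at_level(term_code, TermLevel.PT)

    def reports_with_event(self, term_code: str, level: TermLevel) -> set[str]:
        """Report ids with >=1 reaction whose PT falls under ``term_code``.

        Deduplicated at report level: several sibling PTs in one report
        count that report once.
        """
        key = (term_code, int(level))
        cached = self._event_ids_cache.get(key)
        if cached is not None:
            return set(cached)
        pts = self._pts_under(term_code, level)
        mask = self.reactions["pt_code"].isin(pts)
        ids = frozenset(self.reactions.loc[mask, "report_id"])
        self._event_ids_cache[key] = ids
        return set(ids)

    def contingency(
        self, drug_names, term_code, level: TermLevel, roles=None
    ) -> "ContingencyTable":
        """Report-level 2x2 table for (drug set, event term).

        Margins (n_effect, n_total) are counted over the whole database,
        index-drug reports included, matching the N_total semantics of the
        IC formula; the ``background='other_drugs'`` comparator variant is
        applied downstream at the expected-count step.
        """
        drug_ids = self.reports_with_drug(drug_names, roles=roles)
        event_ids = self.reports_with_event(term_code, level)
        return ContingencyTable(
            n_obs=len(drug_ids & event_ids),
            n_drug=len(drug_ids),
            n_effect=len(event_ids),
            n_total=self.n_total,
        )


@dataclass(frozen=True)
class ContingencyTable:
    """The four report counts behind every IC and ROR."""

    n_obs: int
    n_drug: int
    n_effect: int
    n_total: int

    def __post_init__(self):
        if not (0 <= self.n_obs <= min(self.n_drug, self.n_effect) <= self.n_total):
            raise ValueError(
                f"invalid contingency counts: n_obs={self.n_obs}, "
                f"n_drug={self.n_drug}, n_effect={self.n_effect}, "
                f"n_total={self.n_total}"
            )
        if self.n_total - self.n_drug - self.n_effect + self.n_obs < 0:
            raise ValueError(
                "margins exceed total: "
                f"n_drug={self.n_drug} + n_effect={self.n_effect} - "
                f"n_obs={self.n_obs} > n_total={self.n_total}"
            )

    @property
    def a(self) -> int:
        return self.n_obs

    @property
    def b(self) -> int:
        return self.n_drug - self.n_obs

    @property
    def c(self) -> int:
        return self.n_effect - self.n_obs

    @property
    def d(self) -> int:
        return self.n_total - self.n_drug - self.n_effect + self.n_obs


def _read_csv(path, columns, optional=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns and c not in optional]
    if missing:
        raise DatasetIntegrityError(
            f"{path} is missing column(s): {', '.join(missing)}"
        )
    return df


def read_icsr_dataset(
    reports_path, drugs_path, reactions_path, dictionary: MedDRADictionary
) -> ICSRDataset:
    """Read the three ICSR CSV tables and return a validated dataset.

    Reactions may be coded in a ``llt_code`` column instead of ``pt_code``;
    LLT codes are mapped up to their unique PT parent on load.  Reports
    lacking any reaction row are rejected with a logged count.
    """
    reports = _read_csv(reports_path, REPORT_COLUMNS)
    drugs = _read_csv(drugs_path, DRUG_COLUMNS)
    reactions = pd.read_csv(reactions_path)
    if "pt_code" not in reactions.columns and "llt_code" in reactions.columns:
        llt = reactions["llt_code"].astype(str)
        unknown = [
            c
            for c in llt.unique()
            if c not in dictionary or dictionary.level_of(c) != TermLevel.LLT
        ]
        if unknown:
            raise DatasetIntegrityError(
                f"llt_code(s) not resolving to LLT terms: {sorted(unknown)[:10]}"
            )
        # each LLT has exactly one PT parent, so this mapping is lossless
        mapping = {
            c: next(iter(dictionary.terms[c].parent_codes)) for c in llt.unique()
        }
        reactions = reactions.assign(pt_code=llt.map(mapping))
    missing = [c for c in REACTION_COLUMNS if c not in reactions.columns]
    if missing:
        raise DatasetIntegrityError(
            f"{reactions_path} is missing column(s): {', '.join(missing)}"
        )
    reports["report_id"] = reports["report_id"].astype(str)
    drugs["report_id"] = drugs["report_id"].astype(str)
    reactions["report_id"] = reactions["report_id"].astype(str)

    with_reaction = set(reactions["report_id"])
    keep = reports["report_id"].isin(with_reaction)
    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.warning("rejected %d report(s) lacking reactions", n_rejected)
        dropped = set(reports.loc[~keep, "report_id"])
        reports = reports.loc[keep]
        drugs = drugs.loc[~drugs["report_id"].isin(dropped)]
    return ICSRDataset(
        reports, drugs, reactions, dictionary, n_rejected_no_reaction=n_rejected
    )


# module-level wrappers mirroring the dataset methods

def reports_with_drug(ds: ICSRDataset, drug_names, roles=None) -> set[str]:
    return ds.reports_with_drug(drug_names, roles=roles)


def reports_with_event(ds: ICSRDataset, term_code, level: TermLevel) -> set[str]:
    return ds.reports_with_event(term_code, level)


def contingency(
    ds: ICSRDataset, drug_names, term_code, level: TermLevel, roles=None
) -> ContingencyTable:
    return ds.contingency(drug_names, term_code, level, roles=roles)
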