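"""Shared fixtures: tiny handcrafted dictionaries and datasets."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.meddra import MedDRADictionary, Term, TermLevel
from pvsignal.icsr import (
    DrugMention,
    ICSR,
    ICSRDataset,
    ReactionMention,
)


@pytest.fixture
def chain_dict_csv(tmp_path):
    """Minimal 5-row dictionary: one term per level chained LLT->...->SOC."""
    p = tmp_path / "dictionary.csv"
    p.write_text(
        "code,name,level,parent_codes,primary_soc\n"
        "soc1,Some SOC,SOC,,\n"
        "hg1,Some HLGT,HLGT,soc1,\n"
        "ht1,Some HLT,HLT,hg1,\n"
        "pt1,Some PT,PT,ht1,soc1\n"
        "llt1,Some LLT,LLT,pt1,\n"
    )
    return p


@pytest.fixture
def two_soc_dict():
    """Hand-built dictionary with a multi-axial PT spanning both SOCs.

    pt_x sits under ht_a1 (SOC A, primary) and ht_b1 (SOC B); pt_a2 and
    pt_b2 are single-axial siblings.
    """
    terms = [
        Term("soc_a", "SOC A", TermLevel.SOC),
        Term("soc_b", "SOC B", TermLevel.SOC),
        Term("hg_a", "HLGT A", TermLevel.HLGT, frozenset({"soc_a"})),
        Term("hg_b", "HLGT B", TermLevel.HLGT, frozenset({"soc_b"})),
        Term("ht_a1", "HLT A1", TermLevel.HLT, frozenset({"hg_a"})),
        Term("ht_b1", "HLT B1", TermLevel.HLT, frozenset({"hg_b"})),
        Term("pt_x", "PT X", TermLevel.PT, frozenset({"ht_a1", "ht_b1"}),
             primary_soc="soc_a"),
        Term("pt_a2", "PT A2", TermLevel.PT, frozenset({"ht_a1"}),
             primary_soc="soc_a"),
        Term("pt_b2", "PT B2", TermLevel.PT, frozenset({"ht_b1"}),
             primary_soc="soc_b"),
        Term("llt_x", "LLT X", TermLevel.LLT, frozenset({"pt_x"})),
    ]
    return MedDRADictionary(terms)


def make_report(rid, drugs, pts, **kw):
    return ICSR(
        report_id=rid,
        drugs=tuple(
            DrugMention(d) if isinstance(d, str) else d for d in drugs
        ),
        reactions=tuple(
            ReactionMention(p) if isinstance(p, str) else p for p in pts
        ),
        **kw,
    )


@pytest.fixture
def toy_dataset(two_soc_dict):
    """10 reports: 4 with drug A (suspected), 5 with event pt_a2, 2 with both."""
    records = [
        make_report("r01", ["druga"], ["pt_a2"]),
        make_report("r02", ["druga"], ["pt_a2", "pt_x"]),
        make_report("r03", ["druga"], ["pt_b2"]),
        make_report("r04", ["druga"], ["pt_x"]),
        make_report("r05", ["other"], ["pt_a2"]),
        make_report("r06", ["other"], ["pt_a2"]),
        make_report("r07", ["other"], ["pt_a2"]),
        make_report("r08", ["other"], ["pt_b2"]),
        make_report("r09", [DrugMention("druga", role="concomitant")], ["pt_b2"]),
        make_report("r10", ["other"], ["pt_x", "pt_b2"]),
    ]
    return ICSRDataset.from_records(records, two_soc_dict)


# ---- independent brute-force oracles (kept free of package internals) ----


def bfs_ancestors(parent_map, code, target_level, level_map):
    """Breadth-first search over raw parent links."""
    result = set()
    frontier = [code]
    seen = set()
    while frontier:
        c = frontier.pop()
        if c in seen:
            continue
        seen.add(c)
        if level_map[c] == target_level:
            result.add(c)
            continue
        frontier.extend(parent_map[c])
    return result


def brute_force_contingency(records, drug_names, pts_under_term, roles):
    """Double loop over report records; returns (n_obs, n_drug, n_effect, n_total)."""
    names = {d.lower() for d in drug_names}
    n_obs = n_drug = n_effect = 0
    for r in records:
        has_drug = any(
            m.drug_name.lower() in names and str(m.role) in roles for m in r.drugs
        )
        has_event = any(x.pt_code in pts_under_term for x in r.reactions)
        n_drug += has_drug
        n_effect += has_event
        n_obs += has_drug and has_event
    return n_obs, n_drug, n_effect, len(records)


def random_dictionary(rng, n_soc=3, n_hlgt=2, n_hlt=2, n_pt=2, p_multi=0.2):
    """Random (possibly multi-axial) dictionary built from raw Terms."""
    terms = []
    hlts = []
    pts = []
    for s in range(n_soc):
        soc = f"s{s}"
        terms.append(Term(soc, soc, TermLevel.SOC))
        for g in range(n_hlgt):
            hg = f"s{s}g{g}"
            terms.append(Term(hg, hg, TermLevel.HLGT, frozenset({soc})))
            for t in range(n_hlt):
                ht = f"s{s}g{g}t{t}"
                terms.append(Term(ht, ht, TermLevel.HLT, frozenset({hg})))
                hlts.append((ht, soc))
                for p in range(n_pt):
                    pts.append((f"{ht}p{p}", ht, soc))
    for code, ht, soc in pts:
        parents = {ht}
        if rng.random() < p_multi:
            foreign = [h for h, s_ in hlts if s_ != soc]
            parents.add(foreign[rng.integers(len(foreign))])
        terms.append(Term(code, code, TermLevel.PT, frozenset(parents), primary_soc=soc))
    return MedDRADictionary(terms)


def random_records(rng, dictionary, n_reports, drug_pool=("druga", "drugb", "drugc")):
    pt_codes = dictionary.level_index[TermLevel.PT]
    roles = ("suspected", "concomitant", "interacting")
    records = []
    for i in range(n_reports):
        n_drugs = 1 + rng.integers(0, 2)
        drugs = [
            DrugMention(
                drug_pool[rng.integers(len(drug_pool))],
                role=roles[rng.integers(len(roles))],
                daily_dose_mg=float(rng.integers(1, 20)) if rng.random() < 0.7 else None,
            )
            for _ in range(n_drugs)
        ]
        n_rxn = 1 + rng.integers(0, 3)
        pts = [pt_codes[rng.integers(len(pt_codes))] for _ in range(n_rxn)]
        records.append(make_report(f"r{i:04d}", drugs, pts))
    return records
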