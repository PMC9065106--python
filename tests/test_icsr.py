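"""Report store, event/drug queries and contingency tables."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.icsr import (
    ContingencyTable,
    DatasetIntegrityError,
    ICSRDataset,
    contingency,
    read_icsr_dataset,
    reports_with_drug,
    reports_with_event,
)
from pvsignal.meddra import TermLevel

from conftest import brute_force_contingency, make_report, random_dictionary, random_records


class TestContingencyTable:
    def test_derived_cells(self):
        t = ContingencyTable(n_obs=2, n_drug=4, n_effect=5, n_total=10)
        assert (t.a, t.b, t.c, t.d) == (2, 2, 3, 3)

    @pytest.mark.parametrize(
        "counts",
        [(5, 4, 10, 20), (2, 4, 1, 20), (2, 30, 5, 20), (3, 15, 10, 20)],
    )
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            ContingencyTable(*counts)


class TestQueries:
    def test_reports_with_drug(self, toy_dataset):
        assert reports_with_drug(toy_dataset, {"druga"}) == {
            "r01", "r02", "r03", "r04",
        }

    def test_role_filter_excludes_concomitant(self, toy_dataset):
        # r09 lists druga as concomitant only
        assert "r09" not in reports_with_drug(toy_dataset, {"druga"})
        assert "r09" in reports_with_drug(
            toy_dataset, {"druga"}, roles={"suspected", "concomitant"}
        )

    def test_case_insensitive_match(self, toy_dataset):
        assert reports_with_drug(toy_dataset, {"DrugA "}) == reports_with_drug(
            toy_dataset, {"druga"}
        )

    def test_event_at_pt_level_is_identity(self, toy_dataset):
        assert reports_with_event(toy_dataset, "pt_a2", TermLevel.PT) == {
            "r01", "r02", "r05", "r06", "r07",
        }

    def test_report_level_dedup_under_hlt(self, two_soc_dict):
        ds = ICSRDataset.from_records(
            [make_report("r1", ["d"], ["pt_x", "pt_a2"]),
             make_report("r2", ["d"], ["pt_b2"])],
            two_soc_dict,
        )
        # both PTs of r1 sit under ht_a1: r1 counts once
        assert reports_with_event(ds, "ht_a1", TermLevel.HLT) == {"r1"}

    def test_multiaxial_event_counts_in_both_socs(self, toy_dataset):
        soc_b = reports_with_event(toy_dataset, "soc_b", TermLevel.SOC)
        assert {"r04", "r10", "r02"} <= soc_b  # pt_x reaches soc_b too

    def test_unknown_term_raises(self, toy_dataset):
        with pytest.raises(KeyError):
            reports_with_event(toy_dataset, "ghost", TermLevel.HLT)


class TestContingency:
    def test_toy_counts(self, toy_dataset):
        t = contingency(toy_dataset, {"druga"}, "pt_a2", TermLevel.PT)
        assert (t.n_obs, t.n_drug, t.n_effect, t.n_total) == (2, 4, 5, 10)

    def test_absent_drug_zero_margin(self, toy_dataset):
        t = contingency(toy_dataset, {"nosuchdrug"}, "pt_a2", TermLevel.PT)
        assert (t.n_obs, t.n_drug, t.n_effect, t.n_total) == (0, 0, 5, 10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = random_dictionary(rng)
        records = random_records(rng, d, n_reports=120)
        ds = ICSRDataset.from_records(records, d)
        for term, level in [
            (d.level_index[TermLevel.HLT][0], TermLevel.HLT),
            (d.level_index[TermLevel.HLGT][1], TermLevel.HLGT),
            (d.level_index[TermLevel.SOC][2], TermLevel.SOC),
        ]:
            pts = {
                pt
                for pt in d.level_index[TermLevel.PT]
                if term in d.ancestors_at_level(pt, level)
            }
            expected = brute_force_contingency(
                records, {"druga"}, pts, {"suspected"}
            )
            t = contingency(ds, {"druga"}, term, level)
            assert (t.n_obs, t.n_drug, t.n_effect, t.n_total) == expected

    def test_hlt_additivity_with_dedup(self, toy_dataset):
        d = toy_dataset.dictionary
        for hlt in d.level_index[TermLevel.HLT]:
            children = d.children(hlt)
            n_hlt = len(reports_with_event(toy_dataset, hlt, TermLevel.HLT))
            per_child = [
                len(reports_with_event(toy_dataset, pt, TermLevel.PT))
                for pt in children
            ]
            if per_child:
                assert max(per_child) <= n_hlt <= sum(per_child)

    def test_invariant_to_duplicated_reaction_rows(self, two_soc_dict):
        base = [make_report("r1", ["d"], ["pt_a2"]),
                make_report("r2", ["x"], ["pt_b2"])]
        dup = [make_report("r1", ["d"], ["pt_a2", "pt_a2"]),
               make_report("r2", ["x"], ["pt_b2"])]
        t1 = contingency(ICSRDataset.from_records(base, two_soc_dict),
                         {"d"}, "pt_a2", TermLevel.PT)
        t2 = contingency(ICSRDataset.from_records(dup, two_soc_dict),
                         {"d"}, "pt_a2", TermLevel.PT)
        assert t1 == t2


class TestIO:
    def _write(self, tmp_path, reports, drugs, reactions):
        paths = []
        for name, txt in (
            ("reports.csv", reports), ("drugs.csv", drugs), ("reactions.csv", reactions)
        ):
            p = tmp_path / name
            p.write_text(txt)
            paths.append(p)
        return paths

    def test_read_valid(self, tmp_path, two_soc_dict):
        rp, dp, xp = self._write(
            tmp_path,
            "report_id,age_years,sex,reporter,country\n"
            "r1,60,female,physician,FR\nr2,70,male,consumer,FR\nr3,50,female,other,DE\n",
            "report_id,drug_name,role,daily_dose_mg,indication\n"
            "r1,DrugA,suspected,4,ra\nr2,druga,suspected,,ra\nr3,other,suspected,2,\n",
            "report_id,pt_code,serious,fatal\n"
            "r1,pt_a2,False,False\nr2,pt_x,True,False\nr3,pt_b2,False,True\n",
        )
        ds = read_icsr_dataset(rp, dp, xp, two_soc_dict)
        assert ds.n_total == 3
        assert reports_with_drug(ds, {"druga"}) == {"r1", "r2"}

    def test_report_without_reaction_rejected_with_count(self, tmp_path, two_soc_dict):
        rp, dp, xp = self._write(
            tmp_path,
            "report_id,age_years,sex,reporter,country\nr1,60,female,physician,FR\nr2,70,male,consumer,FR\n",
            "report_id,drug_name,role,daily_dose_mg,indication\nr1,a,suspected,,\nr2,b,suspected,,\n",
            "report_id,pt_code,serious,fatal\nr1,pt_a2,False,False\n",
        )
        ds = read_icsr_dataset(rp, dp, xp, two_soc_dict)
        assert ds.n_total == 1
        assert ds.n_rejected_no_reaction == 1

    def test_llt_codes_mapped_to_pt(self, tmp_path, two_soc_dict):
        rp, dp, xp = self._write(
            tmp_path,
            "report_id,age_years,sex,reporter,country\nr1,60,female,physician,FR\n",
            "report_id,drug_name,role,daily_dose_mg,indication\nr1,a,suspected,,\n",
            "report_id,llt_code,serious,fatal\nr1,llt_x,False,False\n",
        )
        ds = read_icsr_dataset(rp, dp, xp, two_soc_dict)
        assert list(ds.reactions["pt_code"]) == ["pt_x"]

    def test_unknown_pt_code_is_integrity_error(self, tmp_path, two_soc_dict):
        rp, dp, xp = self._write(
            tmp_path,
            "report_id,age_years,sex,reporter,country\nr1,60,female,physician,FR\n",
            "report_id,drug_name,role,daily_dose_mg,indication\nr1,a,suspected,,\n",
            "report_id,pt_code,serious,fatal\nr1,ghost,False,False\n",
        )
        with pytest.raises(DatasetIntegrityError, match="ghost"):
            read_icsr_dataset(rp, dp, xp, two_soc_dict)

    def test_duplicate_report_id_is_integrity_error(self, tmp_path, two_soc_dict):
        rp, dp, xp = self._write(
            tmp_path,
            "report_id,age_years,sex,reporter,country\nr1,60,female,physician,FR\nr1,61,male,consumer,FR\n",
            "report_id,drug_name,role,daily_dose_mg,indication\nr1,a,suspected,,\n",
            "report_id,pt_code,serious,fatal\nr1,pt_a2,False,False\n",
        )
        with pytest.raises(DatasetIntegrityError, match="duplicate"):
            read_icsr_dataset(rp, dp, xp, two_soc_dict)
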