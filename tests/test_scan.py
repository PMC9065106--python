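"""Staged scan: SOC screen, drill-down gating, comparisons, dose strata."""

import numpy as np
import pytest

from pvsignal.icsr import ContingencyTable, ICSRDataset
from pvsignal.meddra import TermLevel
from pvsignal.scan import (
    ScanConfig,
    compare_drugs,
    dose_stratified_scan,
    drilldown,
    run_scan,
    soc_screen,
)
from pvsignal.stats import evaluate_signal
from pvsignal.synth import (
    DrugProfile,
    GeneratorConfig,
    PlantedSignal,
    default_config,
    generate_dataset,
    generate_dictionary,
)

from conftest import make_report

CLASS = ("ruxolitinib", "tofacitinib", "baricitinib")


def planted_config(seed, drugs=CLASS, term="S05G02T02", rr=4.0,
                   n_background=60_000, n_index=4000):
    sigs = tuple(PlantedSignal(d, term, TermLevel.HLT, rr) for d in drugs)
    return default_config(
        seed=seed, n_background_reports=n_background,
        n_index_reports=n_index, planted_signals=sigs,
    )


@pytest.fixture(scope="module")
def planted_scan():
    ds, truth = generate_dataset(planted_config(seed=21))
    cfg = ScanConfig(
        class_drugs=CLASS,
        selected_terms=(("S05G02T02", TermLevel.HLT),),
        dose_rules={"baricitinib": 2.0, "tofacitinib": 5.0},
    )
    return ds, cfg, run_scan(ds, cfg)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = ScanConfig(
            class_drugs=CLASS,
            levels=("HLGT", "HLT"),
            selected_terms=(("S01G01T01", "HLT"),),
            dose_rules={"baricitinib": 2.0},
        )
        p = tmp_path / "scan.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        cfg2 = ScanConfig.from_yaml(p)
        assert cfg2.to_dict() == cfg.to_dict()
        assert cfg2.levels == (TermLevel.HLGT, TermLevel.HLT)

    def test_invalid_dose_rule(self):
        with pytest.raises(ValueError):
            ScanConfig(class_drugs=CLASS, dose_rules={"baricitinib": -1})

    def test_levels_must_be_general_to_specific(self):
        with pytest.raises(ValueError):
            ScanConfig(class_drugs=CLASS, levels=(TermLevel.HLT, TermLevel.HLGT))


class TestSocScreen:
    def test_single_soc_dictionary_one_row(self):
        cfg = GeneratorConfig(
            seed=0, n_background_reports=2000,
            drug_profiles=(DrugProfile(name="druga", n_reports=200),),
            dictionary_shape=(1, 2, 2, 2),
        )
        ds, _ = generate_dataset(cfg)
        rows = soc_screen(ds, ScanConfig(class_drugs=("druga",)))
        assert len(rows) == 1

    def test_empty_class_rejected(self, planted_scan):
        ds, _, _ = planted_scan
        with pytest.raises(ValueError):
            soc_screen(ds, ScanConfig(class_drugs=()))

    def test_planted_soc_is_top_ranked(self, planted_scan):
        ds, cfg, rep = planted_scan
        assert rep.soc_results[0].term_code == "S05"
        assert rep.soc_results[0].signal.is_signal
        # sorted by ic025 descending
        ics = [r.signal.ic025 for r in rep.soc_results]
        assert ics == sorted(ics, reverse=True)


class TestDrilldown:
    def test_planted_hlt_flagged_for_planted_drug_only(self):
        ds, _ = generate_dataset(
            planted_config(seed=22, drugs=("tofacitinib",), n_background=100_000)
        )
        cfg = ScanConfig(class_drugs=CLASS)
        rows = drilldown(ds, cfg, positive_socs={"S05"})
        by_scope = {
            (r.drug_scope, r.term_code): r.signal for r in rows
        }
        assert by_scope[("tofacitinib", "S05G02T02")].is_signal
        assert not by_scope[("ruxolitinib", "S05G02T02")].is_signal
        assert not by_scope[("baricitinib", "S05G02T02")].is_signal

    def test_no_positive_socs_empty(self, planted_scan):
        ds, cfg, _ = planted_scan
        assert drilldown(ds, cfg, set()) == []

    def test_soc_ancestor_of_every_row_is_positive(self, planted_scan):
        ds, cfg, rep = planted_scan
        positive = set(rep.positive_socs)
        for r in rep.drilldown_results:
            anc = ds.dictionary.ancestors_at_level(
                r.term_code, TermLevel.SOC, soc_axis=cfg.soc_axis
            )
            assert anc & positive

    def test_stage_consistency_with_standalone_stats(self, planted_scan):
        """Drill-down rows recomputed via the stats module are identical."""
        ds, cfg, rep = planted_scan
        for r in rep.drilldown_results[:10]:
            names = CLASS if r.drug_scope == "class" else {r.drug_scope}
            t = ds.contingency(names, r.term_code, r.level, roles=cfg.roles)
            again = evaluate_signal(t, method=cfg.ic_method)
            assert t == r.signal.table
            assert again.ic == pytest.approx(r.signal.ic, abs=1e-12)
            assert again.ic025 == pytest.approx(r.signal.ic025, abs=1e-12)


class TestCompareDrugs:
    def test_ordered_pair_combinatorics_and_reciprocity(self, planted_scan):
        ds, cfg, rep = planted_scan
        assert len(rep.comparisons) == 6  # 3 drugs, ordered pairs, 1 term
        by_pair = {(r.drug_a, r.drug_b): r.ror for r in rep.comparisons}
        for (a, b), r in by_pair.items():
            back = by_pair[(b, a)]
            if not r.continuity_corrected:
                assert r.ror == pytest.approx(1.0 / back.ror)

    def test_requires_selected_terms(self, planted_scan):
        ds, cfg, _ = planted_scan
        with pytest.raises(ValueError):
            compare_drugs(ds, ScanConfig(class_drugs=CLASS))


class TestDoseStratification:
    def make_dose_dataset(self):
        d = generate_dictionary((2, 1, 1, 2))
        records = [
            make_report("r1", [self.dm("baricitinib", 4.0)], ["S01G01T01P01"]),
            make_report("r2", [self.dm("baricitinib", 2.0)], ["S01G01T01P01"]),
            make_report("r3", [self.dm("baricitinib", 2.0)], ["S02G01T01P01"]),
            make_report("r4", [self.dm("baricitinib", None)], ["S02G01T01P01"]),
            make_report("r5", [self.dm("other", 1.0)], ["S02G01T01P02"]),
        ]
        return ICSRDataset.from_records(records, d)

    @staticmethod
    def dm(name, dose):
        from pvsignal.icsr import DrugMention

        return DrugMention(name, daily_dose_mg=dose)

    def test_threshold_strictly_over(self):
        """4 mg/day is high dose; exactly 2 mg/day is low; missing excluded."""
        ds = self.make_dose_dataset()
        cfg = ScanConfig(
            class_drugs=("baricitinib",),
            selected_terms=(("S01G01T01P01", TermLevel.PT),),
            dose_rules={"baricitinib": 2.0},
        )
        out = dose_stratified_scan(ds, cfg, "baricitinib")
        assert len(out) == 1
        r = out[0]
        assert (r.n_high, r.n_low, r.n_missing_dose) == (1, 2, 1)
        assert r.ror.a == 1  # the 4 mg report has the event

    def test_missing_dose_rule_rejected(self):
        ds = self.make_dose_dataset()
        cfg = ScanConfig(class_drugs=("baricitinib",))
        with pytest.raises(ValueError):
            dose_stratified_scan(ds, cfg, "baricitinib")

    def test_empty_stratum_skips_term(self):
        ds = self.make_dose_dataset()
        cfg = ScanConfig(
            class_drugs=("baricitinib",),
            selected_terms=(("S01G01T01P01", TermLevel.PT),),
            dose_rules={"baricitinib": 10.0},  # nothing above 10 mg
        )
        assert dose_stratified_scan(ds, cfg, "baricitinib") == []


class TestRunScan:
    def test_all_stages_populated(self, planted_scan):
        _, _, rep = planted_scan
        assert rep.soc_results and rep.drilldown_results
        assert rep.comparisons and rep.dose_results
        assert not rep.errors
        assert rep.metadata["n_class_reports"] > 0

    def test_rerun_byte_identical(self, tmp_path):
        cfg = planted_config(seed=23, n_background=8000, n_index=600)
        scfg = ScanConfig(
            class_drugs=CLASS,
            selected_terms=(("S05G02T02", TermLevel.HLT),),
            dose_rules={"baricitinib": 2.0},
        )
        for sub in ("a", "b"):
            ds, _ = generate_dataset(cfg)
            run_scan(ds, scfg).write(tmp_path / sub)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
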