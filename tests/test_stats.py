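"""Cohort rules and published statistics: frequencies, aggregation, filters."""

import math
from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampliscreen.simulate import IndividualTruth, SimConfig, simulate_cohort
from ampliscreen.stats import (
    FrequencyEstimate,
    aggregate_by_gene,
    any_carrier_rate,
    build_screening_report,
    carrier_frequency,
    classify_ancestry,
    couple_at_risk_probability,
    estimates_from_rows,
    filter_screening_panel,
    percent_2dp,
    reproduce_paper_report,
    select_unrelated,
    shared_with_population,
    verify_fixtures,
)


class TestAncestry:
    @pytest.mark.parametrize("grandparents, expected", [
        (("syrian",) * 4, "full"),
        (("syrian", "ashkenazi", "ashkenazi", "ashkenazi"), "mixed"),
        (("syrian", "syrian", "syrian", "iranian"), "mixed"),
        (("ashkenazi",) * 4, "ineligible"),
    ])
    def test_classification(self, grandparents, expected):
        assert classify_ancestry(grandparents, "syrian") == expected

    def test_wrong_tuple_length_rejected(self):
        with pytest.raises(ValueError):
            classify_ancestry(("syrian",) * 3, "syrian")


def person(sample_id, family_id):
    return IndividualTruth(sample_id, family_id, ("syrian",) * 4, {}, (10, 10))


class TestSiblingDedup:
    def test_one_per_family(self):
        people = [person(f"F0_S{i}", "F0") for i in range(3)]
        assert len(select_unrelated(people, seed=1)) == 1

    def test_singletons_all_retained(self):
        people = [person(f"F{i}_S0", f"F{i}") for i in range(5)]
        assert select_unrelated(people, seed=1) == people

    def test_deterministic_under_seed(self):
        people = [person(f"F{i // 3}_S{i % 3}", f"F{i // 3}") for i in range(12)]
        assert select_unrelated(people, 7) == select_unrelated(people, 7)

    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=8),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_never_two_from_one_family(self, family_sizes, seed):
        people = [person(f"F{f}_S{s}", f"F{f}")
                  for f, size in enumerate(family_sizes) for s in range(size)]
        chosen = select_unrelated(people, seed)
        families = [p.family_id for p in chosen]
        assert len(families) == len(set(families)) == len(family_sizes)


class TestCarrierFrequency:
    @pytest.mark.parametrize("carriers, n, expected", [
        (13, 331, "3.93"),
        (0, 3401, "0.00"),
        (120, 3147, "3.81"),
        (1, 1, "100.00"),
    ])
    def test_percent_round_half_up(self, carriers, n, expected):
        est = carrier_frequency(carriers, n)
        assert str(est.percent) == expected

    def test_degenerate_full_carriage_ci(self):
        est = carrier_frequency(1, 1)
        assert est.ci95[1] == 1.0

    def test_wilson_interval_contains_fraction(self):
        est = carrier_frequency(56, 3401)
        assert est.ci95[0] < est.fraction < est.ci95[1]

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            carrier_frequency(0, 0)

    def test_all_fixture_percents_recompute(self, table1, table3):
        for row in [*table1, *table3]:
            if not row.is_missing:
                assert percent_2dp(row.carriers, row.n) == row.percent_printed, row


class TestGeneAggregation:
    def test_two_variant_gene_sums_fractions(self):
        ests = [FrequencyEstimate("ARSA:c.449C>T", "syrian_mixed", 1, 3401),
                FrequencyEstimate("ARSA:c.854+3A>G", "syrian_mixed", 1, 3401)]
        assert aggregate_by_gene(ests) == {"ARSA": pytest.approx(2 / 3401)}

    def test_single_variant_gene(self):
        ests = [FrequencyEstimate("GNE:c.2228T>C", "syrian_mixed", 24, 3401)]
        assert aggregate_by_gene(ests) == {"GNE": pytest.approx(24 / 3401)}

    def test_zero_carrier_gene(self):
        ests = [FrequencyEstimate("GPT2:c.159C>G", "syrian_mixed", 0, 3401)]
        assert aggregate_by_gene(ests) == {"GPT2": 0.0}


class TestCoupleRisk:
    def test_single_gene(self):
        assert couple_at_risk_probability({"G": 0.1}) == pytest.approx(0.01)

    def test_empty(self):
        assert couple_at_risk_probability({}) == 0.0

    def test_invariant_to_order_and_row_splitting(self):
        whole = couple_at_risk_probability({"A": 0.04, "B": 0.01})
        ests = [FrequencyEstimate("A:v1", "syrian_full", 2, 100),
                FrequencyEstimate("A:v2", "syrian_full", 2, 100),
                FrequencyEstimate("B:v1", "syrian_full", 1, 100)]
        split = couple_at_risk_probability(aggregate_by_gene(ests))
        assert split == pytest.approx(whole)

    def test_against_two_draw_monte_carlo(self):
        # two random partners; at risk when some gene is carried by both
        fractions = {"A": 0.02, "B": 0.03, "C": 0.005}
        analytic = couple_at_risk_probability(fractions)
        rng = np.random.default_rng(20210720)
        n = 2_000_000
        f = np.array(list(fractions.values()))
        both = (rng.random((n, f.size)) < f) & (rng.random((n, f.size)) < f)
        mc = both.any(axis=1).mean()
        # the sum-of-squares formula is the union probability up to the
        # negligible multi-gene overlap term
        assert abs(mc - analytic) < 4 * math.sqrt(analytic / n) + 2 * (0.02 * 0.03) ** 2

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            couple_at_risk_probability({"G": 1.2})


class TestAnyCarrierRate:
    def test_nobody(self):
        assert any_carrier_rate([{"v": 0}, {"v": 0}]) == 0.0

    def test_everybody(self):
        assert any_carrier_rate([{"a": 1}, {"b": 2}]) == 1.0

    def test_matches_independence_prediction(self):
        freqs = {"V1": 0.02, "V2": 0.01, "V3": 0.04}
        cfg = SimConfig(seed=13, n_families=8000, allele_freqs=freqs)
        people = simulate_cohort(cfg)
        rate = any_carrier_rate(p.panel_genotypes for p in people)
        expected = 1 - math.prod(1 - f for f in freqs.values())
        assert abs(rate - expected) <= 3 * math.sqrt(expected * (1 - expected) / 8000)


class TestPanelFilters:
    def test_published_screening_filter(self, table1, phenotypes):
        ests = estimates_from_rows(table1, "syrian_full")
        n_var, n_pheno, subset = filter_screening_panel(ests, 0.6, phenotypes)
        assert (n_var, n_pheno) == (20, 17)
        assert all(e.percent > Decimal("0.6") for e in subset)

    def test_threshold_extremes(self, table1, phenotypes):
        ests = estimates_from_rows(table1, "syrian_full")
        assert filter_screening_panel(ests, 100, phenotypes)[0] == 0
        assert filter_screening_panel(ests, 0, phenotypes)[0] == 33

    def test_comparison_population_sharing(self, table1, phenotypes):
        assert shared_with_population(table1, "ashkenazi", phenotypes) == (16, 13)

    def test_sharing_raw_count_mode_keeps_sub_resolution_variants(self, table1, phenotypes):
        # three singleton carriers round to 0.00% and are excluded by default
        n_raw, _ = shared_with_population(table1, "ashkenazi", phenotypes, raw_counts=True)
        assert n_raw == 19

    def test_all_zero_population(self, phenotypes):
        from ampliscreen.panel import CohortTableRow
        rows = [CohortTableRow("GNE:c.2228T>C", "ashkenazi", 0, 1000)]
        assert shared_with_population(rows, "ashkenazi", phenotypes) == (0, 0)


class TestReports:
    def test_mixed_cohort_report(self, table3, phenotypes, genes):
        ests = estimates_from_rows(table3, "syrian_mixed")
        report = build_screening_report(ests, "syrian_mixed", phenotypes, gene_map=genes)
        assert str(report.couple_risk_percent) == "0.06"
        assert report.couple_risk == pytest.approx(5.531e-4, rel=1e-3)
        summary = report.summary()
        assert "syrian_mixed" in summary and "0.06%" in summary

    def test_reproduce_paper_report_passes(self):
        report = reproduce_paper_report()
        assert report["all_checks_pass"] is True

    def test_tampered_fixture_detected(self, monkeypatch):
        import ampliscreen.stats as stats_mod
        monkeypatch.setitem(stats_mod.FIXTURE_SHA256, "table1.tsv", "0" * 64)
        with pytest.raises(ValueError, match="checksum"):
            verify_fixtures()
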