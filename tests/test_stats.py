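"""Statistical core: Fisher test, BH-FDR, ImportantVar, run_vea, ranking."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vea import (
    ConfigError,
    ContingencyTable2x2,
    ImportantVarPolicy,
    PathwayDB,
    SimulationConfig,
    VeaError,
    bh_fdr,
    build_group_profile,
    classify_important,
    fisher_exact_2x2,
    rank_results,
    restrict_to_universe,
    run_vea,
)
from vea.simulate import simulate_background, simulate_cohort, simulate_pathway_db
from vea.types import PathwayEnrichmentResult

from . import oracles
from .conftest import av


class TestFisher:
    def test_balanced_table(self):
        p, odds = fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_small_table_against_enumeration(self):
        # margins (4,4)/(4,4); expected values frozen from the exact
        # Fraction enumeration oracle
        p, odds = fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(oracles.fisher_two_sided_p(3, 1, 1, 3), rel=1e-12)
        assert p == pytest.approx(0.48571428571428565, rel=1e-9)
        assert odds == pytest.approx(9.0)

    def test_zero_cell_uses_haldane_anscombe_for_or_only(self):
        table = ContingencyTable2x2(0, 20, 30, 950)
        p, odds = fisher_exact_2x2(table)
        assert odds == pytest.approx((0.5 * 950.5) / (20.5 * 30.5))
        assert p == pytest.approx(oracles.fisher_two_sided_p(0, 20, 30, 950), rel=1e-7)

    def test_degenerate_margin_gives_p_one(self):
        p, _ = fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 5))
        assert p == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(VeaError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(400):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            p, odds = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            expected_p = oracles.fisher_two_sided_p(a, b, c, d)
            assert p == pytest.approx(expected_p, rel=1e-7, abs=1e-300)
            assert odds == oracles.sample_odds_ratio(a, b, c, d)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.05]) == [0.05]

    def test_stepup_hand_example(self):
        # hand application of the step-up definition
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_capped_at_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(VeaError):
            bh_fdr([0.5, 1.2])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_definition_oracle_and_is_monotone(self, ps):
        adjusted = bh_fdr(ps)
        expected = oracles.bh_stepup(ps)
        assert adjusted == pytest.approx(expected, rel=1e-12, abs=1e-12)
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] <= ps[j]:
                    assert adjusted[i] <= adjusted[j] + 1e-12

    def test_ties_share_one_adjusted_value(self):
        adjusted = bh_fdr([0.02, 0.02, 0.5])
        assert adjusted[0] == adjusted[1]


class TestClassifyImportant:
    def test_stopgain_without_scores_is_important(self):
        assert classify_important(av(func="stopgain"))

    def test_synonymous_all_tolerated_is_not(self):
        v = av(func="synonymous_SNV",
               calls={"SIFT": "tolerated", "FATHMM": "tolerated"})
        assert not classify_important(v)

    def test_high_cadd_synonymous_is_important(self):
        v = av(func="synonymous_SNV", scores={"CADD": 35.0})
        assert classify_important(v)

    def test_missing_evidence_never_damaging(self):
        v = av(func="synonymous_SNV", calls={"SIFT": "missing"}, scores={"CADD": None})
        assert not classify_important(v)

    def test_consensus_policy_requires_k_predictors(self):
        policy = ImportantVarPolicy(min_damaging=2, functional_classes=frozenset())
        one = av(func="synonymous_SNV", calls={"SIFT": "damaging"})
        two = av(func="synonymous_SNV",
                 calls={"SIFT": "damaging", "FATHMM": "damaging"})
        assert not classify_important(one, policy)
        assert classify_important(two, policy)

    def test_monotone_in_added_evidence(self):
        base = av(func="synonymous_SNV", calls={"SIFT": "damaging"})
        more = av(func="synonymous_SNV",
                  calls={"SIFT": "damaging", "FATHMM": "damaging"},
                  scores={"CADD": 30.0})
        for policy in (ImportantVarPolicy(), ImportantVarPolicy(min_damaging=2)):
            if classify_important(base, policy):
                assert classify_important(more, policy)


class TestRunVea:
    @staticmethod
    def _tiny_run(tiny_db, tiny_background):
        members = [
            [
                av(pos=1, genes=("NOD2",), func="stopgain"),
                av(pos=2, genes=("IL1B",)),
                av(pos=3, genes=("TNF",), func="synonymous_SNV"),
            ]
        ] * 2
        profile = restrict_to_universe(build_group_profile("g", members), tiny_db)
        return run_vea(profile, tiny_background, tiny_db)

    def test_table_construction(self, tiny_db, tiny_background):
        results = {r.pathway_id: r for r in self._tiny_run(tiny_db, tiny_background)}
        # pathway 1 = {NOD2, IL1B}: 2 of 3 case variants, bg 15 of 30
        t = results["R-HSA-0001"].table
        assert (t.case_in, t.case_out, t.bg_in, t.bg_out) == (2, 1, 15, 15)
        # margins constant across pathways
        totals = {(r.table.case_in + r.table.case_out,
                   r.table.bg_in + r.table.bg_out)
                  for r in results.values()}
        assert totals == {(3, 30)}

    def test_untouched_pathway_degenerate_contract(self, tiny_db, tiny_background):
        results = {r.pathway_id: r for r in self._tiny_run(tiny_db, tiny_background)}
        r3 = results["R-HSA-0003"]  # MEFV: no case variants
        assert r3.table.case_in == 0 and not r3.enriched
        assert r3.n_important_var == 0

    def test_important_var_counts_and_bound(self, tiny_db, tiny_background):
        for r in self._tiny_run(tiny_db, tiny_background):
            assert r.n_important_var <= r.table.case_in
            assert sum(r.important_var_genes.values()) >= r.n_important_var

    def test_empty_pathway_db_rejected(self, tiny_background):
        members = [[av()]]
        profile = build_group_profile("g", members)
        with pytest.raises((ConfigError, VeaError)):
            run_vea(profile, tiny_background, PathwayDB(pathways={}))

    def test_zero_background_rejected(self, tiny_db):
        from vea import BackgroundCounts

        profile = build_group_profile("g", [[av(genes=("NOD2",))]])
        bg = BackgroundCounts(per_gene={"NOD2": 0})
        with pytest.raises(ConfigError):
            run_vea(profile, bg, tiny_db)

    def test_planted_pathway_has_smallest_fdr(self):
        cfg = SimulationConfig(
            seed=11, group_sizes={"G1": 3}, n_genes=300, n_pathways=40,
            pathway_size_range=(5, 15), planted={"R-SIM-0005": 5.0},
        )
        db = simulate_pathway_db(cfg)
        bg = restrict_to_universe(simulate_background(cfg), db)
        cohort = simulate_cohort(cfg, db)
        profile = restrict_to_universe(build_group_profile("G1", cohort["G1"]), db)
        results = run_vea(profile, bg, db)
        best = min(results, key=lambda r: (r.fdr, r.p_value))
        assert best.pathway_id == "R-SIM-0005"


class TestRanking:
    @staticmethod
    def _result(pid, n_imp=0, odds=1.0, epr=None):
        return PathwayEnrichmentResult(
            pathway_id=pid, name=pid, table=ContingencyTable2x2(1, 1, 1, 1),
            odds_ratio=odds, p_value=0.5, fdr=0.5, n_important_var=n_imp, epr=epr,
        )

    def test_important_var_descending_with_id_tiebreak(self):
        rows = [self._result("B", 11), self._result("A", 11), self._result("C", 78)]
        ranked = rank_results(rows, mode="important_var")
        assert [r.pathway_id for r in ranked] == ["C", "A", "B"]

    def test_or_mode_filters_threshold_and_important(self):
        rows = [
            self._result("A", n_imp=1, odds=5.03),
            self._result("B", n_imp=0, odds=9.0),
            self._result("C", n_imp=3, odds=1.2),
        ]
        ranked = rank_results(rows, mode="odds_ratio")
        assert [r.pathway_id for r in ranked] == ["A"]

    def test_epr_mode_requires_epr(self):
        with pytest.raises(ConfigError):
            rank_results([self._result("A")], mode="epr")
        ranked = rank_results(
            [self._result("A", epr=0.3), self._result("B", epr=0.9)], mode="epr"
        )
        assert [r.pathway_id for r in ranked] == ["B", "A"]

    def test_empty_input(self):
        assert rank_results([], mode="odds_ratio") == []
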