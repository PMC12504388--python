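import numpy as np
import pytest
from scipy.special import expit

from conjointcheck.bcc import (
    MCMCConfig,
    SummaryTable,
    ThreeMatrix,
    _constrained_posterior_draws,
    bayes_check_three_matrix,
    build_summary_table,
    ordinal_axiom_check,
    run_bcc,
    sample_three_matrices,
    satisfies_axioms,
)
from conjointcheck.datagen import (
    ResponseMatrix,
    draw_item_params,
    draw_person_params,
    simulate_responses,
)

# the worked 3-matrix of observed proportions from a hypothetical 20-item
# test: rows are sum-score groups 6/9/14, columns three items in easiness order
WORKED_PROPS = np.array([[0.22, 0.61, 0.70], [0.36, 0.72, 0.76], [0.45, 0.69, 0.81]])


def worked_three_matrix(n=100):
    return ThreeMatrix(
        row_scores=np.array([6, 9, 14]),
        col_items=np.array([0, 1, 2]),
        counts=np.round(WORKED_PROPS * n).astype(int),
        trials=np.full(3, n),
    )


class TestBuildSummaryTable:
    def test_hand_tally(self):
        # 6 persons x 4 items; person with a perfect score is dropped
        X = np.array(
            [
                [1, 1, 1, 1],  # score 4 -> dropped
                [1, 1, 0, 0],  # 2
                [1, 0, 0, 0],  # 1
                [0, 1, 0, 0],  # 1
                [1, 1, 1, 0],  # 3
                [1, 1, 0, 1],  # 3
            ]
        )
        table = build_summary_table(ResponseMatrix(X))
        assert list(table.scores) == [1, 2, 3]
        assert list(table.row_counts) == [2, 1, 2]
        # marginal p values: item1 5/6, item2 5/6, item3 2/6, item4 2/6
        # ascending easiness with ties broken by original index
        assert list(table.item_order) == [2, 3, 0, 1]
        # score-1 row: persons {1000, 0100}: items (3,4,1,2) -> 0,0,1,1 correct
        assert list(table.cell_counts[0]) == [0, 0, 1, 1]
        assert np.allclose(table.cell_props[1], [0, 0, 1, 1])  # the single 1100 person
        assert np.allclose(table.cell_props[2], [0.5, 0.5, 1, 1])

    def test_row_sums_equal_score_times_count(self, small_rasch_data):
        table = build_summary_table(small_rasch_data)
        assert np.array_equal(
            table.cell_counts.sum(axis=1), table.scores * table.row_counts
        )

    def test_requires_three_score_groups(self):
        X = np.tile([1, 0, 1, 0], (5, 1))  # every person scores 2
        with pytest.raises(ValueError, match="3 distinct interior"):
            build_summary_table(ResponseMatrix(X))

    def test_requires_three_items(self):
        with pytest.raises(ValueError, match="3 items"):
            build_summary_table(ResponseMatrix(np.array([[0, 1], [1, 0], [1, 1]])))

    def test_model_implied_monotonicity(self, rasch_data_1000x20):
        # within each column, proportions rise with score up to sampling noise
        data, _, _ = rasch_data_1000x20
        table = build_summary_table(data)
        se = np.sqrt(
            table.cell_props * (1 - table.cell_props) / table.row_counts[:, None]
        )
        drops = np.diff(table.cell_props, axis=0)
        tol = 3 * np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
        assert np.all(drops >= -np.maximum(tol, 0.05))


def _toy_table():
    return SummaryTable(
        scores=np.array([2, 5, 8]),
        row_counts=np.array([10, 20, 10]),
        item_order=np.arange(3),
        cell_counts=np.array([[1, 2, 3], [8, 10, 12], [6, 7, 9]]),
        cell_props=np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.6, 0.7, 0.9]]),
    )


class TestSampleThreeMatrices:
    def test_single_possible_choice(self):
        tms = sample_three_matrices(_toy_table(), 10, seed=1)
        assert len(tms) == 10
        for tm in tms:
            assert np.array_equal(tm.row_scores, [2, 5, 8])
            assert np.array_equal(tm.col_items, [0, 1, 2])

    def test_rows_and_cols_strictly_increasing(self, small_rasch_data):
        table = build_summary_table(small_rasch_data)
        for tm in sample_three_matrices(table, 50, seed=3):
            assert np.all(np.diff(tm.row_scores) > 0)
            assert np.all(np.diff(tm.col_items) > 0)
            assert np.allclose(tm.props, tm.counts / tm.trials[:, None])

    def test_seed_determinism(self, small_rasch_data):
        table = build_summary_table(small_rasch_data)
        a = sample_three_matrices(table, 100, seed=9)
        b = sample_three_matrices(table, 100, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.counts, tb.counts)
            assert np.array_equal(ta.row_scores, tb.row_scores)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            sample_three_matrices(_toy_table(), 0)

    def test_adjacent_enumeration(self, small_rasch_data):
        from conjointcheck.bcc import adjacent_three_matrices

        table = build_summary_table(small_rasch_data)
        tms = adjacent_three_matrices(table)
        assert len(tms) == (table.n_rows - 2) * (table.n_cols - 2)
        for tm in tms[:10]:
            assert np.all(np.diff(tm.row_scores) > 0)
            assert np.all(np.diff(tm.col_items) == 1)


class TestOrdinalAxiomCheck:
    def test_worked_example_flags_single_violation_only(self):
        # the 0.72 > 0.69 reversal in the middle column is the only failure
        violations = ordinal_axiom_check(worked_three_matrix())
        assert len(violations) == 1
        v = violations[0]
        assert v.axiom == "single"
        assert v.cells == ((1, 1), (2, 1))
        assert "0.720" in v.description and "0.690" in v.description

    def test_worked_example_no_classical_double_violation(self):
        violations = ordinal_axiom_check(worked_three_matrix())
        assert not [v for v in violations if v.axiom == "double"]

    def test_additive_structure_clean(self):
        p = 0.1 * (np.arange(3)[:, None] + np.arange(3)[None, :] + 1)
        tm = ThreeMatrix(
            row_scores=np.array([1, 2, 3]),
            col_items=np.array([0, 1, 2]),
            counts=np.round(p * 100).astype(int),
            trials=np.full(3, 100),
        )
        assert ordinal_axiom_check(tm) == []

    def test_double_cancellation_violation_detected(self):
        # antecedents p(1,2)>=p(2,1) and p(2,3)>=p(3,2) hold, but the
        # implied corner inequality p(1,3)>=p(3,1) fails
        p = np.array([[0.20, 0.50, 0.45], [0.40, 0.50, 0.70], [0.55, 0.60, 0.80]])
        tm = ThreeMatrix(
            row_scores=np.array([1, 2, 3]),
            col_items=np.array([0, 1, 2]),
            counts=np.round(p * 100).astype(int),
            trials=np.full(3, 100),
        )
        doubles = [v for v in ordinal_axiom_check(tm) if v.axiom == "double"]
        assert len(doubles) == 1


class TestSatisfiesAxioms:
    def test_constant_matrix_always_feasible(self):
        for v in (0.0, 0.3, 1.0):
            assert satisfies_axioms(np.full((3, 3), v))

    def test_additive_matrix_feasible(self):
        r = np.array([-0.5, 0.0, 0.7])
        c = np.array([0.6, 0.0, -0.4])
        assert satisfies_axioms(expit(r[:, None] - c[None, :]))

    def test_monotonicity_violation_infeasible(self):
        p = np.full((3, 3), 0.5)
        p[0, 0] = 0.9
        assert not satisfies_axioms(p)


class TestBayesCheckThreeMatrix:
    def test_additive_large_n_rarely_flagged(self):
        r = np.array([-0.5, 0.0, 0.5])
        c = np.array([0.4, 0.0, -0.4])
        p = expit(r[:, None] - c[None, :])
        n = 10_000
        tm = ThreeMatrix(
            row_scores=np.array([3, 6, 9]),
            col_items=np.array([0, 1, 2]),
            counts=np.round(p * n).astype(int),
            trials=np.full(3, n),
        )
        checks = bayes_check_three_matrix(tm, MCMCConfig(burn_in=500, kept_draws=2000, seed=4))
        assert sum(c.violated for c in checks) <= 1

    def test_incoherent_center_cell_flagged(self):
        # 0.9 in the center cannot sit inside any monotone-compatible interval
        p = np.array([[0.2, 0.3, 0.4], [0.3, 0.9, 0.5], [0.4, 0.5, 0.6]])
        tm = ThreeMatrix(
            row_scores=np.array([3, 6, 9]),
            col_items=np.array([0, 1, 2]),
            counts=np.round(p * 500).astype(int),
            trials=np.full(3, 500),
        )
        checks = bayes_check_three_matrix(tm, MCMCConfig(burn_in=500, kept_draws=2000, seed=4))
        center = next(c for c in checks if c.row == 1 and c.col == 1)
        assert center.violated
        assert center.empirical_p > center.ci_hi

    def test_interval_contains_nominal_mass_of_draws(self):
        tm = worked_three_matrix()
        cfg = MCMCConfig(burn_in=200, kept_draws=1000, credible_level=0.95, seed=6)
        kept = _constrained_posterior_draws(
            tm.counts[None].astype(float),
            tm.trials[None].astype(float),
            cfg,
            np.random.default_rng(6),
        )
        lo, hi = np.quantile(kept, [0.025, 0.975], axis=0)
        inside = (kept >= lo) & (kept <= hi)
        assert np.all(inside.mean(axis=0) >= 0.95)

    def test_draws_satisfy_constraints(self):
        tm = worked_three_matrix()
        cfg = MCMCConfig(burn_in=200, kept_draws=500, seed=2)
        kept = _constrained_posterior_draws(
            tm.counts[None].astype(float),
            tm.trials[None].astype(float),
            cfg,
            np.random.default_rng(2),
        )
        flat = kept.reshape(-1, 3, 3).astype(float)
        assert satisfies_axioms(flat).all()

    def test_matches_rejection_sampling_oracle(self):
        # tiny counts: compare posterior means against accept-reject from
        # the unconstrained Beta posteriors
        counts = np.array([[[0.0, 1.0, 1.0], [1.0, 1.0, 2.0], [1.0, 2.0, 3.0]]])
        trials = np.full((1, 3), 3.0)
        cfg = MCMCConfig(burn_in=1000, kept_draws=20_000, seed=3)
        kept = _constrained_posterior_draws(counts, trials, cfg, np.random.default_rng(3))
        mh_mean = kept.mean(axis=0, dtype=np.float64)[0]
        rng = np.random.default_rng(8)
        draws = rng.beta(counts[0] + 1, trials[0][:, None] - counts[0] + 1, size=(200_000, 3, 3))
        acc = draws[satisfies_axioms(draws)]
        assert acc.shape[0] > 1000
        se = acc.std(axis=0) / np.sqrt(acc.shape[0])
        assert np.all(np.abs(mh_mean - acc.mean(axis=0)) < 3 * se + 0.01)


class TestRunBcc:
    def test_deterministic_given_seed(self, small_rasch_data, fast_cfg):
        a = run_bcc(small_rasch_data, m=50, cfg=fast_cfg)
        b = run_bcc(small_rasch_data, m=50, cfg=fast_cfg)
        assert a.weighted_prop == b.weighted_prop
        assert a.unweighted_prop == b.unweighted_prop

    def test_equal_row_counts_make_weighting_irrelevant(self, fast_cfg):
        # every score group the same size -> weighted == unweighted
        rng = np.random.default_rng(12)
        blocks = []
        for s in (2, 4, 6):
            block = np.zeros((30, 8), dtype=int)
            for i in range(30):
                block[i, rng.choice(8, size=s, replace=False)] = 1
            blocks.append(block)
        data = ResponseMatrix(np.vstack(blocks))
        summary = run_bcc(data, m=40, cfg=fast_cfg)
        assert np.isclose(summary.weighted_prop, summary.unweighted_prop)

    def test_proportions_within_unit_interval(self, small_rasch_data, fast_cfg):
        s = run_bcc(small_rasch_data, m=60, cfg=fast_cfg, keep_cells=True)
        assert 0 <= s.weighted_prop <= 1
        assert 0 <= s.unweighted_prop <= 1
        assert len(s.cells) == 60 * 9
        for cell in s.cells[:50]:
            assert cell.ci_lo <= cell.ci_hi
            assert cell.violated == (
                cell.empirical_p < cell.ci_lo or cell.empirical_p > cell.ci_hi
            )

    def test_weighted_prop_matches_cell_aggregation(self, small_rasch_data, fast_cfg):
        s = run_bcc(small_rasch_data, m=40, cfg=fast_cfg, keep_cells=True)
        w = np.array([c.weight for c in s.cells], dtype=float)
        v = np.array([c.violated for c in s.cells], dtype=float)
        assert np.isclose(s.weighted_prop, (w * v).sum() / w.sum())
        assert np.isclose(s.unweighted_prop, v.mean())

    def test_adjacent_mode_enumerates_windows(self, small_rasch_data, fast_cfg):
        from conjointcheck.bcc import build_summary_table as bst

        table = bst(small_rasch_data)
        s = run_bcc(small_rasch_data, cfg=fast_cfg, mode="adjacent")
        assert s.n_matrices == (table.n_rows - 2) * (table.n_cols - 2)
        assert 0 <= s.weighted_prop <= 1

    def test_violations_vanish_with_sample_size(self, fast_cfg):
        # additive truth + huge N: flagged fraction near zero
        persons = draw_person_params(20_000, seed=81)
        items = draw_item_params(10, 0.0, 1.0, disc="rasch", seed=82)
        data = simulate_responses(persons, items, seed=83)
        s = run_bcc(data, m=80, cfg=fast_cfg)
        assert s.weighted_prop < 0.05
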