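"""Spearman kernels and experiment screening."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from regulonkit.io import ExpressionMatrix
from regulonkit.screen import (
    ConstantInputError,
    GuideConfig,
    RegulatorStat,
    ScreenRecord,
    rank_coexpression,
    screen_experiment,
    select_experiments,
    spearman_p,
    spearman_rho,
)


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 9], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            # hand value: 1 - 6*4/(5*24) = 0.8, untied
            ([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], 0.8),
        ],
    )
    def test_examples(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_flagged(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_strictly_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x, y = rng.normal(size=n), rng.normal(size=n)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 2) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(np.tanh(x), y**3) == pytest.approx(base, abs=1e-12)


class TestSpearmanP:
    def test_rho_zero_gives_p_one(self):
        assert spearman_p(0.0, 6) == 1.0
        assert spearman_p(0.0, 50) == pytest.approx(1.0)

    def test_exact_p_n5_by_permutation_count(self):
        """n=5, rho=0.8: p = (# of the 120 permutations with |rho| >= 0.8)/120."""
        hits = 0
        xs = np.arange(5)
        for perm in itertools.permutations(range(5)):
            if abs(np.corrcoef(xs, perm)[0, 1]) >= 0.8 - 1e-12:
                hits += 1
        assert spearman_p(0.8, 5) == pytest.approx(hits / 120, abs=1e-15)

    def test_approximation_matches_t_cdf(self):
        rho, n = 0.7, 30
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        expected = 2 * stats.t.sf(t, df=n - 2)
        assert spearman_p(rho, n) == pytest.approx(expected, abs=1e-10)

    def test_exact_null_distribution_sums_to_one(self):
        from regulonkit.screen import _exact_null_distribution

        for n in (4, 5, 6, 7):
            _, counts = _exact_null_distribution(n)
            assert sum(counts) == math.factorial(n)

    def test_perfect_rho_on_approx_branch_returns_zero(self):
        assert spearman_p(1.0, 20) == 0.0


def _matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"p{i}_at" for i in range(values.shape[0])]
    return ExpressionMatrix("e1", ids, [f"a{j}" for j in range(values.shape[1])], values)


class TestScreenExperiment:
    def config(self):
        return GuideConfig(
            target="t_at",
            regulators=[("A", "ra_at"), ("B", "rb_at")],
        )

    def test_one_strong_regulator_selects(self, rng):
        # regulator A tracks the target closely, B does not
        n = 30
        t = rng.normal(size=n)
        values = [t, t + rng.normal(0, 0.3, n), rng.normal(size=n)]
        m = _matrix(values, ids=["t_at", "ra_at", "rb_at"])
        rec = screen_experiment(m, self.config())
        assert rec.selected
        assert rec.stats["A"].rho > rec.stats["B"].rho

    def test_weak_correlations_do_not_select(self, rng):
        n = 40
        values = rng.normal(size=(3, n))
        m = _matrix(values, ids=["t_at", "ra_at", "rb_at"])
        rec = screen_experiment(m, self.config())
        assert not rec.selected

    def test_constant_regulator_reported_missing(self, rng):
        n = 20
        t = rng.normal(size=n)
        values = [t, np.ones(n), t + rng.normal(0, 0.1, n)]
        m = _matrix(values, ids=["t_at", "ra_at", "rb_at"])
        rec = screen_experiment(m, self.config())
        assert rec.stats["A"] is None
        assert rec.selected  # decided on regulator B alone

    def test_absent_target_skips_experiment(self, rng):
        m = _matrix(rng.normal(size=(2, 10)), ids=["ra_at", "rb_at"])
        assert screen_experiment(m, self.config()) is None

    def test_null_calibration(self):
        """For i.i.d. noise the fraction of experiments with p <= 0.05 sits
        near the nominal level (binomial tolerance band over 2000 runs)."""
        rng = np.random.default_rng(5)
        n, hits = 30, 0
        for _ in range(2000):
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho = spearman_rho(x, y)
            hits += spearman_p(rho, n) <= 0.05
        assert 0.03 <= hits / 2000 <= 0.07


def _record(eid, rho, p, selected, induction=None):
    return ScreenRecord(
        experiment_id=eid,
        n_arrays=10,
        stats={"A": RegulatorStat(rho=rho, p=p)},
        selected=selected,
        induction={"A": induction},
    )


class TestSelectExperiments:
    def test_selected_flags_drive_mode_one(self):
        recs = [_record("e1", 0.9, 0.01, True), _record("e2", 0.3, 0.4, False),
                _record("e3", 0.8, 0.02, True)]
        assert select_experiments(recs) == ["e1", "e3"]

    def test_thresholds_are_inclusive(self, rng):
        """rho exactly 0.7 with p exactly 0.05 still selects."""
        m = _matrix(rng.normal(size=(2, 10)), ids=["t_at", "ra_at"])
        config = GuideConfig(target="t_at", regulators=[("A", "ra_at")])
        rec = screen_experiment(m, config)
        rec.stats["A"] = RegulatorStat(rho=0.7, p=0.05)
        rec.selected = rec.stats["A"].rho >= config.rho_min and rec.stats["A"].p <= config.p_max
        assert rec.selected

    def test_induced_uncorrelated_mode(self):
        recs = [
            _record("e1", 0.31, 0.5, False, induction=2.0),   # induced, uncorrelated -> in
            _record("e2", 0.8, 0.001, True, induction=2.0),   # correlated -> out
            _record("e3", 0.1, 0.9, False, induction=0.2),    # not induced -> out
        ]
        got = select_experiments(recs, "induced_uncorrelated", regulator="A")
        assert got == ["e1"]

    def test_mode_two_without_labels_errors(self):
        recs = [_record("e1", 0.3, 0.5, False, induction=None)]
        with pytest.raises(ValueError, match="induction"):
            select_experiments(recs, "induced_uncorrelated", regulator="A")

    def test_record_order_permutation_only_permutes_output(self):
        recs = [_record("e1", 0.9, 0.01, True), _record("e2", 0.8, 0.02, True)]
        assert select_experiments(recs) == ["e1", "e2"]
        assert select_experiments(recs[::-1]) == ["e2", "e1"]


class TestRankCoexpression:
    def test_rank_matches_brute_force_sort(self, rng):
        from regulonkit.normalize import MergedMatrix

        n_probes, n_arrays = 10, 40
        values = rng.normal(size=(n_probes, n_arrays))
        ids = [f"p{i}_at" for i in range(n_probes)]
        merged = MergedMatrix(
            probeset_ids=ids,
            array_ids=[f"a{j}" for j in range(n_arrays)],
            values=values,
            provenance={f"a{j}": "e1" for j in range(n_arrays)},
        )
        target = "p0_at"
        rhos = {
            ids[i]: spearman_rho(values[0], values[i])
            for i in range(1, n_probes)
        }
        expected_order = sorted(rhos, key=lambda p: (-rhos[p], p))
        for query in ids[1:]:
            rank, rho = rank_coexpression(merged, target, query)
            assert rank == expected_order.index(query) + 1
            assert rho == pytest.approx(rhos[query], abs=1e-12)
        # the most correlated probeset ranks first
        assert rank_coexpression(merged, target, expected_order[0])[0] == 1

    def test_constant_query_is_an_error(self, rng):
        from regulonkit.normalize import MergedMatrix

        values = rng.normal(size=(3, 10))
        values[2] = 1.0
        merged = MergedMatrix(
            probeset_ids=["a_at", "b_at", "c_at"],
            array_ids=[f"a{j}" for j in range(10)],
            values=values,
            provenance={f"a{j}": "e1" for j in range(10)},
        )
        with pytest.raises(ConstantInputError):
            rank_coexpression(merged, "a_at", "c_at")
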