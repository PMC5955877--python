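import numpy as np
import pytest

from conftest import random_quantity_matrix
from erenorm.data_model import QuantityMatrix
from erenorm.genorm import (
    GeNormError,
    StabilityConfig,
    analyze_stability,
    classify_stability,
    m_value,
    m_values,
    normalization_factor,
    optimal_target_count,
    pairwise_variation,
    rank_stepwise,
    v_curve,
)
from oracles import oracle_m, oracle_rank_stepwise, oracle_v_series


def qm_from_dict(quantities: dict[str, list[float]]) -> QuantityMatrix:
    """Column-normalize so per-target max is 1; log-ratio sds are unchanged."""
    targets = list(quantities)
    arr = np.array([quantities[t] for t in targets]).T
    arr = arr / arr.max(axis=0, keepdims=True)
    return QuantityMatrix([f"s{i}" for i in range(arr.shape[0])], targets, arr)


class TestPairwiseVariation:
    def test_proportional_targets_have_zero_v(self):
        q = qm_from_dict({"a": [1.0, 0.5, 0.25], "b": [1.0, 0.5, 0.25]})
        assert pairwise_variation(q, "a", "b") == 0.0

    def test_direct_stdev_of_log_ratios(self):
        # log2 ratios are (0, -1, -2): sample sd = 1
        q = qm_from_dict({"a": [1.0, 0.5, 0.25], "b": [1.0, 1.0, 1.0]})
        assert pairwise_variation(q, "a", "b") == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        q = random_quantity_matrix(rng, 8, 5)
        for j, k in [("t00", "t03"), ("t01", "t04")]:
            assert pairwise_variation(q, j, k) == pytest.approx(
                pairwise_variation(q, k, j), abs=1e-15
            )

    def test_needs_two_samples_and_distinct_targets(self):
        q = qm_from_dict({"a": [1.0, 0.5], "b": [1.0, 1.0]})
        with pytest.raises(GeNormError):
            pairwise_variation(q, "a", "a")


class TestMValue:
    def test_mean_of_pairwise_v(self):
        # a and b proportional (V=0); c at V=1 against both => M_a = 0.5
        q = qm_from_dict(
            {"a": [1.0, 0.5, 0.25], "b": [1.0, 0.5, 0.25], "c": [0.25, 0.25, 0.25]}
        )
        assert m_value(q, "a") == pytest.approx(0.5, abs=1e-12)
        assert m_value(q, "b") == pytest.approx(0.5, abs=1e-12)

    def test_all_proportional_all_zero(self):
        q = qm_from_dict(
            {"a": [1.0, 0.5], "b": [0.5, 0.25], "c": [1.0, 0.5]}
        )
        assert all(m == pytest.approx(0.0, abs=1e-15) for m in m_values(q).values())

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(50):
            q = random_quantity_matrix(rng, 10, 6)
            as_dict = {t: q.quantities[:, j].tolist() for j, t in enumerate(q.target_ids)}
            for t in q.target_ids:
                assert m_value(q, t) == pytest.approx(oracle_m(as_dict, t), abs=1e-12)

    def test_single_target_rejected(self):
        with pytest.raises(GeNormError):
            m_value(qm_from_dict({"a": [1.0, 0.5]}), "a")


class TestStepwiseRanking:
    def test_noisy_target_eliminated_first(self, rng):
        stable = 2.0 ** -rng.uniform(0, 3, size=12)
        q_dict = {t: (stable / stable.max()).tolist() for t in ("a", "b", "c")}
        noisy = stable * 2.0 ** rng.normal(0, 1.5, size=12)
        q_dict["z"] = (noisy / noisy.max()).tolist()
        elimination, ranked = rank_stepwise(qm_from_dict(q_dict))
        assert elimination[0][0] == "z"
        assert ranked[-1] == "z"

    def test_ranked_reverses_elimination(self, rng):
        q = random_quantity_matrix(rng, 8, 5)
        elimination, ranked = rank_stepwise(q)
        assert ranked == [t for t, _ in reversed(elimination)]

    def test_matches_oracle_on_fixed_matrix(self):
        rng = np.random.default_rng(42)
        q = random_quantity_matrix(rng, 8, 5)
        as_dict = {t: q.quantities[:, j].tolist() for j, t in enumerate(q.target_ids)}
        o_elim, o_ranked = oracle_rank_stepwise(as_dict)
        elimination, ranked = rank_stepwise(q)
        assert ranked == o_ranked
        assert [t for t, _ in elimination] == [t for t, _ in o_elim]
        for (_, m), (_, om) in zip(elimination, o_elim):
            assert m == pytest.approx(om, abs=1e-12)

    def test_final_pair_tied_and_lexicographic(self):
        q = qm_from_dict(
            {"b": [1.0, 0.5, 0.25], "a": [1.0, 0.5, 0.25], "c": [1.0, 0.9, 0.1]}
        )
        elimination, ranked = rank_stepwise(q)
        assert ranked[:2] == ["a", "b"]
        assert elimination[-1][1] == elimination[-2][1]


class TestNormalizationFactor:
    def test_single_target_is_identity(self, rng):
        q = random_quantity_matrix(rng, 6, 3)
        np.testing.assert_allclose(
            normalization_factor(q, ["t01"]), q.quantities[:, 1], rtol=1e-12
        )

    def test_geometric_mean_of_two(self):
        q = qm_from_dict({"a": [1.0, 0.25], "b": [1.0, 1.0]})
        np.testing.assert_allclose(normalization_factor(q, ["a", "b"]), [1.0, 0.5])

    def test_order_invariant(self, rng):
        q = random_quantity_matrix(rng, 6, 4)
        np.testing.assert_allclose(
            normalization_factor(q, ["t00", "t02", "t03"]),
            normalization_factor(q, ["t03", "t00", "t02"]),
            rtol=1e-12,
        )


class TestVCurve:
    def test_target_proportional_to_nf2_gives_zero_v23(self, rng):
        q_raw = random_quantity_matrix(rng, 10, 2)
        nf2 = normalization_factor(q_raw, q_raw.target_ids)
        arr = np.column_stack([q_raw.quantities, nf2 / nf2.max()])
        q = QuantityMatrix(q_raw.sample_ids, [*q_raw.target_ids, "t99"], arr)
        v = v_curve(q, ["t00", "t01", "t99"])
        assert v[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_and_has_t_minus_2_entries(self, rng):
        q = random_quantity_matrix(rng, 8, 6)
        _, ranked = rank_stepwise(q)
        v = v_curve(q, ranked)
        assert len(v) == 4
        as_dict = {t: q.quantities[:, j].tolist() for j, t in enumerate(q.target_ids)}
        oracle = oracle_v_series(as_dict, ranked)
        for n in v:
            assert v[n] == pytest.approx(oracle[n], abs=1e-12)


class TestOptimalCount:
    def test_first_v_below_cutoff(self):
        assert optimal_target_count({2: 0.10, 3: 0.05}) == (2, None)
        assert optimal_target_count({2: 0.20, 3: 0.12}) == (3, None)

    def test_fallback_to_all_targets_flagged(self):
        n, flag = optimal_target_count({2: 0.2, 3: 0.18, 4: 0.16})
        assert n == 5 and flag == "no V below cutoff"


class TestClassification:
    @pytest.mark.parametrize(
        "m,label",
        [(0.15, "very_high"), (0.45, "high"), (0.5, "unstable"), (0.2, "high"), (1.2, "unstable")],
    )
    def test_thresholds(self, m, label):
        assert classify_stability(m) == label

    def test_negative_m_rejected(self):
        with pytest.raises(GeNormError):
            classify_stability(-0.1)

    def test_config_ordering_enforced(self):
        with pytest.raises(GeNormError):
            StabilityConfig(m_high=0.2, m_very_high=0.5)


class TestGlobalShiftInvariance:
    def test_per_sample_cq_shift_changes_nothing(self, rng):
        """Adding a per-sample constant to every target's Cq (the shared
        mRNA-fraction shift that normalization is built on) leaves M values,
        ranking, and the V series untouched."""
        cq = rng.uniform(18, 30, size=(9, 5))
        shift = rng.normal(0, 2, size=(9, 1))
        def to_q(c):
            return QuantityMatrix(
                [f"s{i}" for i in range(9)],
                [f"t{j:02d}" for j in range(5)],
                2.0 ** (c.min(axis=0)[None, :] - c),
            )
        r1 = analyze_stability(to_q(cq))
        r2 = analyze_stability(to_q(cq + shift))
        assert r1.ranked_targets == r2.ranked_targets
        for t in r1.m_values:
            assert r1.m_values[t] == pytest.approx(r2.m_values[t], abs=1e-9)
        for n in r1.v_series:
            assert r1.v_series[n] == pytest.approx(r2.v_series[n], abs=1e-9)


class TestNoiseMonotonicity:
    def test_more_independent_noise_never_lowers_mean_m(self):
        """Raising one target's independent noise sd raises its first-pass M
        in expectation (mean over 50 seeds)."""
        from erenorm.simulate import ExperimentDesign, TargetSpec, generate_cq
        from erenorm.data_model import to_relative_quantities

        def mean_m(tau: float) -> float:
            out = []
            for seed in range(50):
                design = ExperimentDesign(
                    n_samples=10,
                    targets=(
                        TargetSpec("probe", 24.0, instability_sd=tau),
                        TargetSpec("r1", 22.0),
                        TargetSpec("r2", 23.0),
                        TargetSpec("r3", 21.0),
                    ),
                    global_shift_sd=1.0,
                    noise_sd=0.1,
                    seed=seed,
                )
                matrix, _ = generate_cq(design)
                out.append(m_values(to_relative_quantities(matrix))["probe"])
            return float(np.mean(out))

        assert mean_m(0.2) < mean_m(0.6) < mean_m(1.2)
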