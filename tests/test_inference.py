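"""Second-order statistics, permutation inference and FDR."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import SEED, spearman_oracle, tau_a_oracle
from gramrsa.design import ModelRDM, build_model, complexity_type_model
from gramrsa.inference import (
    InferenceError,
    bh_fdr,
    compare_models,
    permutation_test,
    rdm_correlation,
    storey_qvalues,
)
from gramrsa.patterns import RDM, PatternMatrix, activation_rdm


def _rdm_from(matrix, labels=None):
    matrix = np.asarray(matrix, float)
    if labels is None:
        labels = tuple(f"c{k}" for k in range(matrix.shape[0]))
    return RDM(matrix, labels)


def _full_model_from_rdm(dissim, name="toy"):
    """Fully constrained model with the given (0-1 ranged) dissimilarities."""
    n = dissim.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return ModelRDM(name, dissim, mask)


def _random_model(rng, n):
    """Random partially constrained model with tied values on a 0.25 grid."""
    while True:
        vals = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(n, n))
        vals = np.triu(vals, 1)
        vals = vals + vals.T
        mask = np.triu(rng.random((n, n)) < 0.75, 1)
        mask = mask | mask.T
        if mask[np.triu_indices(n, 1)].sum() < 3:
            continue
        sel = vals[np.triu_indices(n, 1)][mask[np.triu_indices(n, 1)]]
        if np.unique(sel).size < 2:
            continue
        return ModelRDM("random", vals, mask)


class TestRDMCorrelation:
    def test_identity_is_one(self, cs):
        ct = complexity_type_model(cs)
        data = _rdm_from(np.nan_to_num(ct.dissim), cs.labels)
        for method in ("spearman", "pearson"):
            assert rdm_correlation(data, ct, method) == pytest.approx(1.0)
        # tau-a of a two-valued vector against itself: ties keep tau < 1
        tau = rdm_correlation(data, ct, "kendall_tau_a")
        assert 0 < tau < 1

    def test_antipodal_is_minus_one(self, cs):
        ct = complexity_type_model(cs)
        data = _rdm_from(2.0 - np.nan_to_num(ct.dissim) - 2.0 * np.eye(12),
                         cs.labels)
        assert rdm_correlation(data, ct, "spearman") == pytest.approx(-1.0)

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 7))
            vox = int(rng.integers(3, 21))
            values = np.round(rng.normal(size=(vox, n)), 1)
            if np.any(values.var(axis=0) == 0):
                continue
            data = activation_rdm(
                PatternMatrix(values, tuple(f"c{k}" for k in range(n)))
            )
            model = _random_model(rng, n)
            i, j = model.constrained_upper_indices()
            x = list(data.dissim[i, j])
            y = list(model.dissim[i, j])
            if len(set(y)) < 2:
                continue
            assert rdm_correlation(data, model, "spearman") == pytest.approx(
                spearman_oracle(x, y), abs=1e-10
            )
            assert rdm_correlation(
                data, model, "kendall_tau_a"
            ) == pytest.approx(tau_a_oracle(x, y), abs=1e-10)

    def test_too_few_cells_rejected(self):
        dissim = np.array(
            [[np.nan, 1.0, np.nan], [1.0, np.nan, 0.0], [np.nan, 0.0, np.nan]]
        )
        mask = ~np.isnan(dissim)
        model = ModelRDM("tiny", dissim, mask)
        data = _rdm_from(np.array([[0, 0.5, 1], [0.5, 0, 0.7], [1, 0.7, 0]]))
        with pytest.raises(InferenceError):
            rdm_correlation(data, model)

    def test_unknown_method_rejected(self, cs, rng):
        ct = complexity_type_model(cs)
        data = _rdm_from(np.nan_to_num(ct.dissim), cs.labels)
        with pytest.raises(InferenceError):
            rdm_correlation(data, ct, "biweight")


class TestPermutationTest:
    def test_exact_match_minimal_p(self, cs):
        ct = complexity_type_model(cs)
        data = _rdm_from(np.nan_to_num(ct.dissim), cs.labels)
        res = permutation_test(data, ct, method="spearman", n_perm=999,
                               seed=SEED)
        # no permutation exceeds the perfect statistic; ties counted >=
        assert np.all(res.null <= res.statistic + 1e-12)
        assert res.p_value >= 1.0 / 1000.0
        assert res.p_value < 0.01

    def test_determinism(self, cs, rng):
        ct = complexity_type_model(cs)
        p = PatternMatrix(rng.normal(size=(40, 12)), cs.labels)
        data = activation_rdm(p)
        a = permutation_test(data, ct, n_perm=200, seed=123)
        b = permutation_test(data, ct, n_perm=200, seed=123)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null, b.null)

    def test_p_floor(self, cs, rng):
        ct = complexity_type_model(cs)
        data = activation_rdm(PatternMatrix(rng.normal(size=(40, 12)),
                                            cs.labels))
        res = permutation_test(data, ct, n_perm=100, seed=1)
        assert res.p_value >= 1.0 / 101.0
        assert res.p_value <= 1.0

    def test_n_perm_minimum(self, cs, rng):
        ct = complexity_type_model(cs)
        data = activation_rdm(PatternMatrix(rng.normal(size=(40, 12)),
                                            cs.labels))
        with pytest.raises(InferenceError):
            permutation_test(data, ct, n_perm=50)


class TestCompareModels:
    def test_identical_models_give_p_one(self, cs, rng):
        ct = complexity_type_model(cs)
        rdms = [
            activation_rdm(PatternMatrix(rng.normal(size=(30, 12)),
                                         cs.labels))
            for _ in range(4)
        ]
        res = compare_models(rdms, ct, ct)
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_enumeration_s4(self, cs, rng, models):
        rdms = [
            activation_rdm(PatternMatrix(rng.normal(size=(30, 12)),
                                         cs.labels))
            for _ in range(4)
        ]
        res = compare_models(rdms, models["complexity_type"],
                             models["general_complexity"])
        assert res.exhaustive
        # p is a multiple of 1/16 for 4 subjects
        assert (res.p_value * 16) == pytest.approx(round(res.p_value * 16))
        # oracle: enumerate the 16 sign patterns directly
        d = res.per_subject
        obs = abs(d.mean())
        count = 0
        for bits in range(16):
            signs = [1 if bits & (1 << k) else -1 for k in range(4)]
            count += abs(np.mean([s * x for s, x in zip(signs, d)])) >= (
                obs - 1e-12
            )
        assert res.p_value == pytest.approx(count / 16)

    def test_single_subject_rejected(self, cs, rng, models):
        rdm = activation_rdm(
            PatternMatrix(rng.normal(size=(30, 12)), cs.labels)
        )
        with pytest.raises(InferenceError):
            compare_models([rdm], models["complexity_type"],
                           models["general_complexity"])

    def test_planted_geometry_detected(self, cs, models):
        from gramrsa.synth import simulate_roi_patterns

        pats = simulate_roi_patterns(
            models["complexity_type"], n_voxels=150, n_subjects=8,
            snr=5.0, seed=SEED, condition_set=cs,
        )
        rdms = [activation_rdm(p) for p in pats]
        res = compare_models(rdms, models["complexity_type"],
                             models["general_complexity"])
        assert res.mean_difference > 0
        assert res.p_value < 0.05


class TestStoreyQ:
    def test_block_of_small_p(self):
        q, pi0 = storey_qvalues([0.001] * 22)
        assert pi0 <= 1.0
        assert np.all(q <= 0.022)

    def test_uniform_large_sample(self, rng):
        p = rng.uniform(size=10_000)
        p = np.clip(p, 1e-12, 1.0)
        q, pi0 = storey_qvalues(p)
        assert 0.9 <= pi0 <= 1.1

    def test_single_p_one(self):
        q, pi0 = storey_qvalues([1.0])
        assert q[0] == 1.0
        assert pi0 == 1.0

    def test_monotone_in_p(self, rng):
        p = np.clip(rng.uniform(size=200), 1e-12, 1.0)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_equals_pi0_times_bh(self, rng):
        # dual route: the step-up machinery should match statsmodels' BH
        # adjusted p-values scaled by the pi0 estimate
        p = np.clip(rng.uniform(size=50) ** 2, 1e-12, 1.0)
        q, pi0 = storey_qvalues(p)
        _, bh_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, np.clip(pi0 * bh_adj, 0, 1), atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(InferenceError):
            storey_qvalues([])
        with pytest.raises(InferenceError):
            storey_qvalues([0.0, 0.5])
        with pytest.raises(InferenceError):
            storey_qvalues([0.5, 1.2])


class TestBHFDR:
    def test_step_up_by_hand(self):
        rejected = bh_fdr([0.001, 0.2, 0.9], alpha=0.05)
        assert list(rejected) == [0]

    def test_all_ones(self):
        assert len(bh_fdr([1.0, 1.0, 1.0], alpha=0.05)) == 0

    def test_order_invariance(self, rng):
        p = np.clip(rng.uniform(size=30) ** 3, 1e-12, 1.0)
        perm = rng.permutation(30)
        base = set(bh_fdr(p, 0.05))
        shuffled = {int(perm[k]) for k in bh_fdr(p[perm], 0.05)}
        assert base == shuffled
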