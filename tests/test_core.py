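import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import adnorm as ad
from adnorm.core import (
    background_set,
    constant_vs_k_curve,
    difference_profile,
    median_normalize,
    normalization_constant,
    normalize_experiment,
)

GENES3 = pd.Index(["g1", "g2", "g3"], name="gene")


def series(vals, index=GENES3):
    return pd.Series(np.asarray(vals, dtype=float), index=index)


class TestDifferenceProfile:
    def test_direct_arithmetic_and_descending_order(self):
        p = difference_profile(series([0, 0, 0]), series([-1, 2, 0]), "r")
        assert p.diffs.tolist() == [1.0, -2.0, 0.0]
        assert p.sorted_diffs.tolist() == [1.0, 0.0, -2.0]
        assert list(p.gene_ids[p.order]) == ["g1", "g3", "g2"]

    def test_identical_vectors_give_identity_order(self):
        ref = series([0.3, -0.2, 1.1])
        p = difference_profile(ref, ref, "r")
        assert np.all(p.diffs == 0)
        assert p.order.tolist() == [0, 1, 2]  # stable ties

    def test_pure_shift_gives_constant_diffs(self):
        ref = series([0.5, 1.5, -0.5])
        p = difference_profile(ref, ref - 2, "r")
        assert np.allclose(p.diffs, 2.0)

    def test_mismatched_gene_sets_error(self):
        other = pd.Index(["g1", "g2", "gX"])
        with pytest.raises(ValueError, match="same genes"):
            difference_profile(series([0, 0, 0]), series([0, 0, 0], other), "r")


class TestBackgroundSet:
    def test_top_k_by_descending_difference(self):
        p = difference_profile(series([0, 0, 0]), series([-1, 2, 0]), "r")
        assert set(background_set(p, 2)) == {"g1", "g3"}

    def test_k_equal_n_returns_all_genes(self):
        p = difference_profile(series([0, 0, 0]), series([1, 2, 3]), "r")
        assert set(background_set(p, 3)) == set(GENES3)

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range_error(self, k):
        p = difference_profile(series([0, 0, 0]), series([1, 2, 3]), "r")
        with pytest.raises(ValueError, match="out of range"):
            background_set(p, k)


class TestNormalizationConstant:
    def test_set_median_direct(self):
        genes = pd.Index(["a", "b"])
        c = normalization_constant(
            series([0, 0], genes), series([-1, 0], genes), ["a", "b"],
            "set-median",
        )
        assert c == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "estimator", ["set-median", "set-mean", "orderstat-mean"]
    )
    def test_pure_shift_recovered_by_every_estimator(self, estimator):
        rng = np.random.default_rng(0)
        genes = pd.Index([f"g{i}" for i in range(101)])
        ref = series(rng.normal(size=101), genes)
        rep = ref - 2.0
        c = normalization_constant(ref, rep, genes[:40], estimator)
        assert c == pytest.approx(2.0)

    def test_empty_background_set_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            normalization_constant(series([0, 0, 0]), series([1, 2, 3]), [])

    def test_unknown_estimator_error(self):
        with pytest.raises(ValueError, match="estimator"):
            normalization_constant(
                series([0, 0, 0]), series([1, 2, 3]), ["g1"], "mean-of-means"
            )

    def test_orderstat_mean_equals_brute_force_topk_mean(self):
        """Independent oracle: mean of the top-k of the fully sorted
        difference vector, computed without the profile machinery."""
        rng = np.random.default_rng(42)
        genes = pd.Index([f"g{i}" for i in range(500)])
        ref = series(rng.normal(size=500), genes)
        rep = series(rng.normal(size=500), genes)
        k = 120
        brute = np.sort((ref - rep).to_numpy())[::-1][:k].mean()
        p = difference_profile(ref, rep, "r")
        c = normalization_constant(
            ref, rep, background_set(p, k), "orderstat-mean"
        )
        assert c == pytest.approx(brute, abs=1e-12)

    def test_all_genes_set_median_is_classical_median_normalization(self):
        rng = np.random.default_rng(7)
        genes = pd.Index([f"g{i}" for i in range(301)])
        ref = series(rng.normal(size=301), genes)
        rep = series(rng.normal(1.3, 1, size=301), genes)
        c = normalization_constant(ref, rep, genes, "set-median")
        assert c == pytest.approx(
            float(ref.median() - rep.median()), abs=1e-12
        )

    @given(st.floats(-5, 5, allow_nan=False))
    def test_shift_equivariance(self, a):
        rng = np.random.default_rng(3)
        genes = pd.Index([f"g{i}" for i in range(50)])
        ref = series(rng.normal(size=50), genes)
        rep = series(rng.normal(size=50), genes)
        s = genes[:20]
        base = normalization_constant(ref, rep, s, "set-median")
        shifted = normalization_constant(ref, rep + a, s, "set-median")
        assert shifted == pytest.approx(base - a, abs=1e-9)


class TestConstantVsKCurve:
    def test_pure_shift_curve_is_flat(self):
        rng = np.random.default_rng(0)
        genes = pd.Index([f"g{i}" for i in range(200)])
        ref = series(rng.normal(size=200), genes)
        curve = constant_vs_k_curve(ref, ref - 1.5, [10, 50, 100, 200])
        assert all(c == pytest.approx(1.5) for _, c in curve)

    def test_full_k_boundary_equals_global_median_normalization(self):
        rng = np.random.default_rng(5)
        genes = pd.Index([f"g{i}" for i in range(150)])
        ref = series(rng.normal(size=150), genes)
        rep = series(rng.normal(size=150), genes)
        [(k, c)] = constant_vs_k_curve(ref, rep, [150], "set-median")
        assert k == 150
        assert c == pytest.approx(float(ref.median() - rep.median()))

    def test_curve_drifts_down_once_targets_are_swallowed(self):
        """With targets present, deeper k pulls the constant down on
        average (the background set starts to include enriched genes)."""
        rng = np.random.default_rng(8)
        diffs_head, diffs_tail = [], []
        for s in range(30):
            r = np.random.default_rng(s)
            n, n_t = 2000, 600
            ref = series(r.normal(size=n), pd.Index([f"g{i}" for i in range(n)]))
            rep = ref.copy()
            rep.iloc[:] = r.normal(size=n)
            rep.iloc[:n_t] += 3.0  # targets are IP-enriched
            curve = dict(constant_vs_k_curve(ref, rep, [400, 1900]))
            diffs_head.append(curve[400])
            diffs_tail.append(curve[1900])
        assert np.mean(diffs_tail) < np.mean(diffs_head)


class TestMedianNormalize:
    def test_columns_have_zero_median(self, small_experiment):
        out = median_normalize(small_experiment.matrix)
        assert np.allclose(out.values.median(axis=0).to_numpy(), 0.0)


class TestNormalizeExperiment:
    def test_exact_recovery_under_pure_shift_pooled(self):
        """IP replicates equal to mock_bar minus a constant are restored to
        mock_bar exactly, and the constants equal the shifts."""
        rng = np.random.default_rng(0)
        n = 1500
        genes = pd.Index([f"g{i}" for i in range(n)], name="gene")
        mock = rng.normal(size=(n, 3))
        mock -= np.median(mock, axis=0)  # pre-centered so mock_bar is exact
        mock_bar = mock.mean(axis=1)
        shifts = {"ip1": 0.8, "ip2": -1.2}
        values = pd.DataFrame(
            {
                "ip1": mock_bar - shifts["ip1"],
                "ip2": mock_bar - shifts["ip2"],
                "mock1": mock[:, 0],
                "mock2": mock[:, 1],
                "mock3": mock[:, 2],
            },
            index=genes,
        )
        matrix = ad.EnrichmentMatrix(
            values=values,
            conditions=pd.Series(
                {"ip1": "IP", "ip2": "IP", "mock1": "Mock",
                 "mock2": "Mock", "mock3": "Mock"}
            ),
        )
        cfg = ad.Config(reference="pooled", k=400)
        res = normalize_experiment(matrix, cfg)
        for rep, a in shifts.items():
            assert res.constants[rep] == pytest.approx(a, abs=1e-9)
            assert np.allclose(
                res.normalized.values[rep].to_numpy(), mock_bar, atol=1e-9
            )

    def test_exact_recovery_with_identical_mocks_matched(self):
        """With identical Mock columns the leave-one-out references all equal
        mock_bar, so the matched policy recovers pure shifts exactly too."""
        rng = np.random.default_rng(1)
        n = 1200
        genes = pd.Index([f"g{i}" for i in range(n)], name="gene")
        mock_col = rng.normal(size=n)
        mock_col -= np.median(mock_col)
        values = pd.DataFrame(
            {
                "ip1": mock_col - 0.6,
                "mock1": mock_col,
                "mock2": mock_col,
            },
            index=genes,
        )
        matrix = ad.EnrichmentMatrix(
            values=values,
            conditions=pd.Series(
                {"ip1": "IP", "mock1": "Mock", "mock2": "Mock"}
            ),
        )
        res = normalize_experiment(matrix, ad.Config(k=300))
        assert res.constants["ip1"] == pytest.approx(0.6, abs=1e-9)

    def test_fewer_than_two_mocks_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="2 Mock replicates"):
            normalize_experiment(tiny_matrix, ad.Config(k=2))

    @pytest.mark.parametrize("reference", ["matched", "pooled"])
    def test_result_bookkeeping(self, small_experiment, reference):
        cfg = ad.Config(reference=reference, k=200)
        res = normalize_experiment(small_experiment.matrix, cfg)
        n_mock = len(small_experiment.matrix.mock_ids)
        for rep in small_experiment.matrix.ip_ids:
            expected_fits = 1 if reference == "pooled" else n_mock
            assert len(res.fits[rep]) == expected_fits
            for fit in res.fits[rep]:
                assert len(fit.background_genes) == fit.k == 200
        for m in small_experiment.matrix.mock_ids:
            assert len(res.fits[m]) == 1
        summary = res.summary()
        assert set(summary["replicate"]) == set(
            small_experiment.matrix.replicate_ids
        )

    def test_normalized_values_are_additive_shifts(self, small_experiment):
        """IP columns move by exactly their constant; Mock columns are the
        centered Mocks plus their constant."""
        res = normalize_experiment(small_experiment.matrix, ad.Config(k=200))
        raw = small_experiment.matrix
        for rep in raw.ip_ids:
            assert np.allclose(
                res.normalized.values[rep].to_numpy(),
                raw.values[rep].to_numpy() + res.constants[rep],
                atol=1e-12,
            )
        for m in raw.mock_ids:
            assert np.allclose(
                res.normalized.values[m].to_numpy(),
                res.mock_model.centered_mocks[m].to_numpy()
                + res.constants[m],
                atol=1e-12,
            )


class TestPropertyOneInvariance:
    """The normalization is invariant to per-replicate constant shifts."""

    @pytest.mark.parametrize("reference", ["matched", "pooled"])
    def test_shifting_one_ip_replicate_changes_nothing(
        self, small_experiment, reference
    ):
        cfg = ad.Config(reference=reference)
        base = normalize_experiment(small_experiment.matrix, cfg)
        shifted_values = small_experiment.matrix.values.copy()
        shifted_values["ip1"] = shifted_values["ip1"] + 3.7
        shifted = normalize_experiment(
            small_experiment.matrix.with_values(shifted_values), cfg
        )
        assert np.allclose(
            base.normalized.values.to_numpy(),
            shifted.normalized.values.to_numpy(),
            atol=1e-9,
        )

    def test_common_shift_of_all_mocks_changes_nothing(self, small_experiment):
        cfg = ad.Config()
        base = normalize_experiment(small_experiment.matrix, cfg)
        shifted_values = small_experiment.matrix.values.copy()
        for m in small_experiment.matrix.mock_ids:
            shifted_values[m] = shifted_values[m] - 5.25
        shifted = normalize_experiment(
            small_experiment.matrix.with_values(shifted_values), cfg
        )
        assert np.allclose(
            base.normalized.values.to_numpy(),
            shifted.normalized.values.to_numpy(),
            atol=1e-9,
        )
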