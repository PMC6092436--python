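"""RDA/CCA, VIF filtering, forward selection, permutation ANOVA, VPA, DCA."""

import numpy as np
import pandas as pd
import pytest

from abundrare import (
    DataError, RelAbundanceMatrix, cca, dca_gradient_length, ezekiel_adj_r2,
    forward_select, permutation_anova, rda, variation_partition, vif_filter,
)


def gradient_community(n=30, n_sp=40, tol=0.5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    grad = np.linspace(0, 1, n)
    opt = np.linspace(-0.2, 1.2, n_sp)
    y = np.exp(-(grad[:, None] - opt[None, :]) ** 2 / (2 * tol**2)) + 1e-12
    if noise:
        y *= rng.lognormal(0, noise, y.shape)
    y = y / y.sum(axis=1, keepdims=True)
    return RelAbundanceMatrix([f"o{i}" for i in range(n_sp)],
                              [f"s{j}" for j in range(n)], y.T)


class TestRDA:
    def test_exact_linear_map_explains_everything(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        y = x @ rng.normal(size=(3, 10))
        res = rda(y, x)
        assert res.constrained_fraction == pytest.approx(1.0)

    def test_unrelated_predictor_explains_little(self):
        n = 40
        rng = np.random.default_rng(1)
        y = np.outer(np.sin(np.arange(n)), np.ones(5))
        res = rda(y, rng.normal(size=(n, 2)))
        assert res.constrained_fraction < 0.2
        assert res.adj_r2 <= res.constrained_fraction

    def test_overdetermined_errors(self):
        rng = np.random.default_rng(2)
        with pytest.raises(DataError):
            rda(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))

    def test_ezekiel_formula(self):
        assert ezekiel_adj_r2(0.5, 22, 5) == pytest.approx(0.34375)

    def test_reparameterisation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(25, 4))
        y = x @ rng.normal(size=(4, 8)) + rng.normal(size=(25, 8))
        mix = rng.normal(size=(4, 4)) + np.eye(4) * 2
        r1 = rda(y, x).constrained_fraction
        r2 = rda(y, x @ mix).constrained_fraction
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_matches_vegan_rda(self, tmp_path):
        """Cross-check R2 and adjusted R2 against vegan on a tiny fixture."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 2))
        y = x @ rng.normal(size=(2, 6)) + rng.normal(size=(12, 6))
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        script = tmp_path / "check.R"
        script.write_text(
            'y <- as.matrix(read.csv("%s", header=FALSE))\n'
            'x <- as.data.frame(read.csv("%s", header=FALSE))\n'
            "m <- vegan::rda(y ~ ., data=x)\n"
            "cat(summary(m)$constr.chi / summary(m)$tot.chi, "
            "vegan::RsquareAdj(m)$adj.r.squared)\n"
            % (tmp_path / "y.csv", tmp_path / "x.csv")
        )
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=120)
        if out.returncode != 0:
            pytest.skip(f"vegan unavailable: {out.stderr[:200]}")
        r2_ref, adj_ref = map(float, out.stdout.split())
        res = rda(y, x)
        assert res.constrained_fraction == pytest.approx(r2_ref, abs=1e-6)
        assert res.adj_r2 == pytest.approx(adj_ref, abs=1e-6)


class TestCCA:
    def test_binary_separator_explains_most_inertia(self):
        rng = np.random.default_rng(4)
        y = np.zeros((10, 16))
        y[:5, :8] = rng.integers(5, 50, size=8)  # one profile per group
        y[5:, 8:] = rng.integers(5, 50, size=8)
        x = np.array([[1]] * 5 + [[0]] * 5, dtype=float)
        res = cca(y, x, n_perm=29, seed=0)
        assert res.constrained_fraction > 0.9

    def test_identical_columns_degenerate(self):
        y = np.ones((6, 4))
        with pytest.raises(DataError):
            cca(y, np.random.default_rng(0).normal(size=(6, 1)))

    def test_shuffled_predictor_drops_to_null(self):
        rng = np.random.default_rng(5)
        grad = np.linspace(0, 1, 20)
        y = gradient_community(20, 15, tol=0.3).ra.T * 1000
        res_true = cca(y, grad[:, None], n_perm=29, seed=0)
        shuffled = [cca(y, grad[rng.permutation(20), None], n_perm=0 + 29, seed=1).constrained_fraction
                    for _ in range(20)]
        assert res_true.constrained_fraction > np.percentile(shuffled, 95)


class TestVIF:
    def test_orthogonal_columns_untouched(self):
        n = 64
        t = np.arange(n)
        x = pd.DataFrame({
            "a": np.cos(2 * np.pi * t / n),
            "b": np.sin(2 * np.pi * t / n),
            "c": np.cos(4 * np.pi * t / n),
        })
        kept, dropped = vif_filter(x)
        assert list(kept.columns) == ["a", "b", "c"]
        assert dropped == {}

    def test_duplicate_column_dropped_later_first(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=30)
        x = pd.DataFrame({"a": a, "b": rng.normal(size=30), "a2": a})
        kept, dropped = vif_filter(x)
        assert "a2" in dropped
        assert list(kept.columns) == ["a", "b"]

    def test_near_collinear_triple(self):
        rng = np.random.default_rng(7)
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        x3 = x1 + x2 + rng.normal(0, 0.01, 30)
        kept, dropped = vif_filter(pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}))
        assert len(dropped) == 1
        from abundrare.ordination import _vifs

        assert max(_vifs(kept.to_numpy())) <= 20


class TestForwardSelect:
    def test_recovers_true_driver(self):
        hits = 0
        rng = np.random.default_rng(8)
        for _ in range(20):
            x1 = rng.normal(size=30)
            noise = rng.normal(size=(30, 2))
            y = np.outer(x1, rng.normal(size=8) + 1) + rng.normal(size=(30, 8)) * 0.5
            x = pd.DataFrame({"x1": x1, "n1": noise[:, 0], "n2": noise[:, 1]})
            res = forward_select(y, x, n_perm=99, seed=int(rng.integers(2**31)))
            hits += bool(res.selected) and res.selected[0] == "x1"
        assert hits >= 19

    def test_empty_selection_on_pure_noise_is_not_error(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(15, 10))
        x = pd.DataFrame({"a": rng.normal(size=15)})
        res = forward_select(y, x, n_perm=99, seed=0)
        assert isinstance(res.selected, list)

    def test_duplicated_candidate_violates_contract(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=20)
        x = pd.DataFrame({"a": a, "b": a})
        with pytest.raises(DataError, match="collinear"):
            forward_select(rng.normal(size=(20, 5)), x)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(size=25)
        y = np.outer(x1, np.ones(6)) + rng.normal(size=(25, 6)) * 0.3
        x = pd.DataFrame({"x1": x1, "n1": rng.normal(size=25), "n2": rng.normal(size=25)})
        r1 = forward_select(y, x, n_perm=99, seed=3)
        r2 = forward_select(y, x[["n2", "x1", "n1"]], n_perm=99, seed=3)
        assert set(r1.selected) == set(r2.selected)


class TestPermutationAnova:
    def test_strong_effect_saturates_p(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 1))
        y = x @ np.ones((1, 6)) + rng.normal(size=(20, 6)) * 0.01
        _, p = permutation_anova(y, x, n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_p_granularity(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(12, 5))
        x = rng.normal(size=(12, 1))
        _, p = permutation_anova(y, x, n_perm=9, seed=0)
        assert (p * 10) == pytest.approx(round(p * 10))

    def test_partial_test_of_pure_fraction(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=(30, 1))
        x = rng.normal(size=(30, 1))
        y = x @ np.ones((1, 5)) * 2 + z @ np.ones((1, 5)) + rng.normal(size=(30, 5))
        _, p = permutation_anova(y, x, n_perm=99, seed=0, conditioning=z)
        assert p < 0.05


class TestVariationPartition:
    def test_fraction_identity_arithmetic(self):
        # with pure fractions 3.5% and 3.4% and shared 2.0%, residual is 91.1%
        pure_s, pure_e, shared = 0.035, 0.034, 0.020
        residual = 1.0 - pure_s - pure_e - shared
        assert residual == pytest.approx(0.911)

    def test_fitted_fractions_sum_to_one(self):
        rng = np.random.default_rng(15)
        xe = rng.normal(size=(25, 2))
        xs = rng.normal(size=(25, 2))
        y = xe @ rng.normal(size=(2, 10)) + xs @ rng.normal(size=(2, 10)) + rng.normal(size=(25, 10))
        res = variation_partition(y, xe, xs, n_perm=49, seed=0)
        total = res.pure_env + res.pure_spatial + res.shared + res.residual
        assert total == pytest.approx(1.0, abs=1e-9)
        assert res.residual == pytest.approx(1 - (res.E + res.S - res.shared), abs=1e-9)

    def test_null_spatial_component(self):
        rng = np.random.default_rng(16)
        xe = rng.normal(size=(40, 2))
        xs = rng.normal(size=(40, 2))  # unrelated to y
        y = xe @ rng.normal(size=(2, 12)) * 2 + rng.normal(size=(40, 12)) * 0.3
        res = variation_partition(y, xe, xs, n_perm=49, seed=1)
        assert abs(res.pure_spatial) < 0.05
        assert abs(res.shared) < 0.05
        assert res.pure_env > 0.5

    def test_empty_set_rejected(self):
        rng = np.random.default_rng(17)
        with pytest.raises(DataError):
            variation_partition(rng.normal(size=(10, 4)),
                                np.zeros((10, 0)), rng.normal(size=(10, 1)))


class TestDCA:
    def test_short_gradient_recommends_rda(self):
        ra = gradient_community(tol=2.0)
        res = dca_gradient_length(ra)
        assert res.axis_lengths.max() < 3
        assert res.recommendation == "rda"

    def test_long_gradient_recommends_cca(self):
        ra = gradient_community(tol=0.05)
        res = dca_gradient_length(ra)
        assert res.axis_lengths.max() > 4
        assert res.recommendation == "cca"

    def test_duplicated_samples_near_zero_length(self):
        y = np.tile(np.array([[3.0, 2.0, 1.0, 4.0]]), (6, 1))
        ra = RelAbundanceMatrix([f"o{i}" for i in range(4)],
                                [f"s{j}" for j in range(6)],
                                (y / y.sum(axis=1, keepdims=True)).T)
        res = dca_gradient_length(ra)
        assert res.axis_lengths.max() < 0.5

    def test_degenerate_table_errors(self):
        y = np.zeros((5, 3))
        y[:, 0] = 1.0
        ra = RelAbundanceMatrix(["a", "b", "c"], [f"s{j}" for j in range(5)], y.T)
        with pytest.raises(DataError):
            dca_gradient_length(ra)
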