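import numpy as np
import pandas as pd
import pytest

from metstab.ammi import (
    CellMeanMatrix,
    ammi_anova,
    asv,
    cell_means,
    fit_ammi,
    stability_ranking,
)
from metstab.errors import ContractError
from metstab.synthetic import SimulationSpec, generate_met
from metstab.trial_io import records_to_frame


def _cells(matrix, replication=1):
    matrix = np.asarray(matrix, float)
    n, m = matrix.shape
    return CellMeanMatrix(tuple(f"g{i}" for i in range(n)),
                          tuple(f"h{j}" for j in range(m)),
                          matrix, replication)


def _random_cells(rng, n=10, m=6, replication=2):
    return _cells(rng.normal(10, 3, (n, m)), replication)


def brute_force_partition(matrix, r):
    """Double-loop SS partition oracle from the definition of each term."""
    y = np.asarray(matrix, float)
    n, m = y.shape
    mu = y.mean()
    g = y.mean(axis=1) - mu
    e = y.mean(axis=0) - mu
    ss_g = ss_e = ss_gei = 0.0
    for i in range(n):
        for j in range(m):
            z = y[i, j] - mu - g[i] - e[j]
            ss_gei += r * z * z
    for i in range(n):
        ss_g += r * m * g[i] ** 2
    for j in range(m):
        ss_e += r * n * e[j] ** 2
    return ss_g, ss_e, ss_gei


class TestFitAmmi:
    def test_purely_additive_table_has_no_interaction(self):
        g = np.array([1.0, -2.0, 0.5, 0.5])
        e = np.array([0.3, -0.3, 1.0, -1.0])
        cells = _cells(10 + g[:, None] + e[None, :])
        fit = fit_ammi(cells, n_axes=2)
        assert np.abs(fit.lambdas).max() < 1e-10
        np.testing.assert_allclose(fit.g, g, atol=1e-12)
        np.testing.assert_allclose(fit.e, e, atol=1e-12)

    def test_main_effects_sum_to_zero(self, rng):
        fit = fit_ammi(_random_cells(rng), n_axes=2)
        assert abs(fit.g.sum()) < 1e-10
        assert abs(fit.e.sum()) < 1e-10

    def test_full_rank_reconstruction_is_exact(self, rng):
        cells = _random_cells(rng, n=7, m=5)
        fit = fit_ammi(cells, n_axes=4)
        np.testing.assert_allclose(fit.reconstruction(), cells.means, atol=1e-8)
        assert np.abs(fit.residual).max() < 1e-8

    def test_planted_rank_one_interaction_recovered(self, rng):
        n, m = 9, 6
        u = rng.normal(size=n); u -= u.mean(); u /= np.linalg.norm(u)
        v = rng.normal(size=m); v -= v.mean(); v /= np.linalg.norm(v)
        lam = 4.2
        cells = _cells(10 + lam * np.outer(u, v))
        fit = fit_ammi(cells, n_axes=2)
        assert fit.lambdas[0] == pytest.approx(lam, rel=1e-10)
        assert fit.lambdas[1] == pytest.approx(0.0, abs=1e-10)
        sign = np.sign(fit.genotype_scores[:, 0] @ u)
        np.testing.assert_allclose(sign * fit.genotype_scores[:, 0], u, atol=1e-10)
        np.testing.assert_allclose(sign * fit.env_scores[:, 0], v, atol=1e-10)

    def test_missing_cells_rejected(self):
        with pytest.raises(ContractError, match="missing"):
            _cells([[1, 2, np.nan], [4, 5, 6], [7, 8, 9]])

    def test_interaction_svd_identity(self, rng):
        cells = _random_cells(rng)
        fit = fit_ammi(cells, n_axes=2)
        assert (fit.lambdas ** 2).sum() == pytest.approx(
            (fit.interaction ** 2).sum(), rel=1e-10)


class TestAmmiAnova:
    def test_additive_table_has_zero_gei(self):
        cells = _cells(5 + np.outer([1.0, -1.0, 0.0], np.ones(3))
                       + np.outer(np.ones(3), [2.0, -1.0, -1.0]))
        table = ammi_anova(cells)
        assert table.loc["G x E", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_partition_matches_brute_force(self, rng):
        cells = _random_cells(rng, n=6, m=5, replication=3)
        table = ammi_anova(cells)
        ss_g, ss_e, ss_gei = brute_force_partition(cells.means, 3)
        assert table.loc["genotype", "sum_sq"] == pytest.approx(ss_g, rel=1e-8)
        assert table.loc["environment", "sum_sq"] == pytest.approx(ss_e, rel=1e-8)
        assert table.loc["G x E", "sum_sq"] == pytest.approx(ss_gei, rel=1e-8)

    def test_gei_equals_sum_of_all_ipc_ss(self, rng):
        cells = _random_cells(rng, n=8, m=5)
        full = fit_ammi(cells, n_axes=4)
        table = ammi_anova(cells, full)
        ipc_ss = table.loc[[f"IPC{k}" for k in range(1, 5)], "sum_sq"].sum()
        assert ipc_ss == pytest.approx(table.loc["G x E", "sum_sq"], rel=1e-8)

    def test_ipc_degrees_of_freedom(self, rng):
        cells = _random_cells(rng, n=10, m=6)
        table = ammi_anova(cells, fit_ammi(cells, 2))
        assert table.loc["IPC1", "df"] == 10 + 6 - 1 - 2
        assert table.loc["IPC2", "df"] == 10 + 6 - 1 - 4

    def test_f_tests_against_supplied_error(self, rng):
        cells = _random_cells(rng)
        table = ammi_anova(cells, fit_ammi(cells, 2), ms_error=1.0, df_error=50)
        assert (table["F"].dropna() > 0).all()
        assert table["p"].dropna().between(0, 1).all()


class TestAsv:
    def test_zero_scores_give_zero(self):
        assert asv(0.0, 0.0, 1.0, 1.0) == 0.0

    def test_three_four_five(self):
        assert asv(3.0, 4.0, 2.0, 2.0) == pytest.approx(5.0)

    def test_degenerate_second_axis_rejected(self):
        with pytest.raises(ContractError):
            asv(1.0, 1.0, 1.0, 0.0)

    def test_monotone_in_absolute_scores(self):
        base = asv(1.0, 1.0, 3.0, 1.5)
        assert asv(2.0, 1.0, 3.0, 1.5) > base
        assert asv(1.0, -2.0, 3.0, 1.5) > base
        assert asv(-1.0, 1.0, 3.0, 1.5) == pytest.approx(base)

    def test_pipeline_asv_equals_direct_formula(self, rng):
        cells = _random_cells(rng, n=20, m=6)
        fit = fit_ammi(cells, 2)
        stab = stability_ranking(fit, cells)
        scores = fit.scaled_genotype_scores()
        r = cells.replication
        w = (r * fit.lambdas[0] ** 2) / (r * fit.lambdas[1] ** 2)
        expected = np.sqrt((w * scores[:, 0]) ** 2 + scores[:, 1] ** 2)
        np.testing.assert_allclose(stab["ASV"].to_numpy(), expected, rtol=1e-12)


class TestStabilityRanking:
    def test_best_genotype_attains_minimum_ysi(self):
        # one genotype with the highest mean and no interaction at all
        rng = np.random.default_rng(1)
        n, m = 8, 5
        u = rng.normal(size=n); u[1:] -= u[1:].mean(); u[0] = 0.0
        base = 10 + np.zeros((n, m))
        base[0] += 5.0
        v = rng.normal(size=m); v -= v.mean()
        cells = _cells(base + 2.0 * np.outer(u, v))
        fit = fit_ammi(cells, 2)
        stab = stability_ranking(fit, cells)
        assert stab.loc["g0", "YSI"] == stab["YSI"].min()

    def test_extreme_ysi_bounds(self, rng):
        cells = _random_cells(rng, n=12, m=6)
        stab = stability_ranking(fit_ammi(cells, 2), cells)
        assert stab["YSI"].min() >= 2
        assert stab["YSI"].max() <= 2 * len(stab)
        assert sorted(stab["RY"]) == list(range(1, 13))

    def test_ysi_order_matches_rank_sum_oracle(self, rng):
        from scipy.stats import rankdata

        cells = _random_cells(rng, n=15, m=6)
        fit = fit_ammi(cells, 2)
        stab = stability_ranking(fit, cells)
        oracle = (rankdata(-cells.means.mean(axis=1))
                  + rankdata(stab["ASV"].to_numpy()))
        assert np.argsort(stab["YSI"].to_numpy(), kind="stable").tolist() == \
            np.argsort(oracle, kind="stable").tolist()


class TestInvariances:
    def test_sign_flip_leaves_everything_invariant(self, rng):
        cells = _random_cells(rng)
        fit = fit_ammi(cells, 2)
        flipped = fit.__class__(
            mu=fit.mu, g=fit.g, e=fit.e, lambdas=fit.lambdas,
            genotype_scores=-fit.genotype_scores, env_scores=-fit.env_scores,
            n_axes=fit.n_axes, residual=fit.residual, interaction=fit.interaction)
        np.testing.assert_allclose(flipped.reconstruction(), fit.reconstruction())
        s1 = stability_ranking(fit, cells)
        s2 = stability_ranking(flipped, cells)
        np.testing.assert_allclose(s1["ASV"], s2["ASV"])
        np.testing.assert_allclose(s1["YSI"], s2["YSI"])

    def test_scale_equivariance(self, rng):
        cells = _random_cells(rng)
        scaled = CellMeanMatrix(cells.genotypes, cells.environments,
                                3.0 * cells.means, cells.replication)
        f1, f2 = fit_ammi(cells, 2), fit_ammi(scaled, 2)
        np.testing.assert_allclose(f2.lambdas, 3.0 * f1.lambdas,
                                   rtol=1e-10, atol=1e-10)
        s1 = stability_ranking(f1, cells)
        s2 = stability_ranking(f2, scaled)
        np.testing.assert_allclose(s1["RY"], s2["RY"])
        np.testing.assert_allclose(s1["RASV"], s2["RASV"])
        np.testing.assert_allclose(s1["YSI"], s2["YSI"])


def test_cell_means_from_records_average_replicates(small_trial):
    spec, records, truth = small_trial
    cm = cell_means(records_to_frame(records), "TDW", "wet")
    assert cm.replication == spec.n_replicates
    assert cm.means.shape == (spec.n_genotypes, spec.n_harvests)
    expected = (truth.grand_mean + truth.genotype_effects[:, None]
                + truth.harvest_effects[None, :] + truth.interaction)
    # replicate averaging shrinks residual noise by sqrt(r)
    assert np.abs(cm.means - expected).max() < 4 * np.sqrt(spec.sigma2_e / spec.n_replicates) * 1.5
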