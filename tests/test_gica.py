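"""Group-ICA chain: MDL order selection, PCA reductions, Infomax, stability
screen, GICA3 backreconstruction, and map/time-course scaling."""

import numpy as np
import pytest

from rsnlong import EstimationError, InvalidArgumentError
from rsnlong.gica import (
    DataMatrix,
    backreconstruct_gica3,
    concat_reduce,
    estimate_order_mdl,
    explained_variance_fraction,
    infomax_ica,
    map_to_volume,
    reduce_pca,
    run_gica,
    scale_percent_signal,
    stability_screen,
    volume_to_data_matrix,
    zscore_map,
)
from tests.conftest import matched_abs_corr


def make_matrix(values):
    v = np.asarray(values, float)
    mask = np.ones((v.shape[0], 1, 1), dtype=bool)
    return DataMatrix(values=v, mask=mask)


class TestMDL:
    def test_recovers_constructed_rank(self, rng):
        # rank-3 signal + noise at SNR ~20
        sources = rng.normal(size=(3, 2000))
        mix = rng.normal(size=(3, 50))
        data = sources.T @ mix
        data += rng.normal(0, data.std() / 20, size=data.shape)
        assert estimate_order_mdl(make_matrix(data)) == 3

    def test_matches_bruteforce_cost_argmin(self, rng):
        # independent evaluation of the Wax-Kailath cost over all orders
        data = rng.normal(size=(800, 20))
        data[:, :4] += rng.normal(size=(800, 4)) * 3
        x = data - data.mean(axis=1, keepdims=True)
        lam = np.linalg.eigvalsh(x.T @ x / 800)[::-1]
        lam = np.clip(lam, 1e-12 * lam[0], None)
        p, n = 20, 20
        costs = []
        for k in range(1, p):
            tail = lam[k:]
            ll = n * (p - k) * np.log(tail.mean() / np.exp(np.mean(np.log(tail))))
            costs.append(ll + 0.5 * k * (2 * p - k + 1) * np.log(n))
        assert estimate_order_mdl(make_matrix(data)) == int(np.argmin(costs)) + 1

    def test_white_noise_gives_low_order(self, rng):
        data = rng.normal(size=(3000, 40))
        assert estimate_order_mdl(make_matrix(data)) <= 2

    def test_constant_data_fails(self):
        with pytest.raises(EstimationError):
            estimate_order_mdl(make_matrix(np.ones((100, 10))))


class TestPCA:
    def test_full_rank_reconstruction_is_exact(self, rng):
        data = make_matrix(rng.normal(size=(50, 10)))
        red = reduce_pca(data, 10)
        assert explained_variance_fraction(data, red) == pytest.approx(1.0, abs=1e-12)

    def test_rank3_data_fully_explained_by_k3(self, rng):
        data = make_matrix(rng.normal(size=(200, 3)) @ rng.normal(size=(3, 30)))
        red = reduce_pca(data, 3)
        assert explained_variance_fraction(data, red) == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_non_increasing(self, rng):
        red = reduce_pca(make_matrix(rng.normal(size=(100, 20))), 10)
        assert np.all(np.diff(red.eigenvalues) <= 1e-12)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            reduce_pca(make_matrix(rng.normal(size=(50, 10))), 11)

    def test_session_k_doubles_component_number(self, toy_data_matrices):
        res = run_gica(toy_data_matrices, n_components=3, session_k="auto", seed=0)
        assert res.session_k == 6

    def test_concat_dimension_bound(self, rng):
        reds = [reduce_pca(make_matrix(rng.normal(size=(50, 10))), 4) for _ in range(2)]
        with pytest.raises(InvalidArgumentError):
            concat_reduce(reds, 9)


class TestInfomax:
    def test_recovers_supergaussian_sources(self, rng):
        # 3 sparse (super-Gaussian) sources, random mixing
        s = rng.laplace(size=(3, 3000)) ** 3
        a = rng.normal(size=(3, 3))
        x = (a @ s).T  # "voxels" x k
        from rsnlong.gica import GroupReduction

        red = GroupReduction(reduced=x, eigenvalues=np.ones(3), k=3)
        ica = infomax_ica(red, 3, seed=0)
        assert matched_abs_corr(s, ica.aggregate_maps).min() > 0.95

    def test_identity_mixing_returns_inputs(self, rng):
        s = rng.laplace(size=(3, 2000))
        from rsnlong.gica import GroupReduction

        red = GroupReduction(reduced=s.T.copy(), eigenvalues=np.ones(3), k=3)
        ica = infomax_ica(red, 3, seed=1)
        assert matched_abs_corr(s, ica.aggregate_maps).min() > 0.99

    def test_seed_invariance_on_clean_data(self, rng):
        s = rng.laplace(size=(3, 3000))
        a = rng.normal(size=(3, 3))
        from rsnlong.gica import GroupReduction

        red = GroupReduction(reduced=(a @ s).T, eigenvalues=np.ones(3), k=3)
        m1 = infomax_ica(red, 3, seed=10).aggregate_maps
        m2 = infomax_ica(red, 3, seed=99).aggregate_maps
        assert matched_abs_corr(m1, m2).min() > 0.99

    def test_component_count_must_match_reduction(self, rng):
        from rsnlong.gica import GroupReduction

        red = GroupReduction(reduced=rng.normal(size=(100, 4)), eigenvalues=np.ones(4), k=4)
        with pytest.raises(InvalidArgumentError):
            infomax_ica(red, 3)


class TestStability:
    def test_identifiable_sources_are_stable(self, toy_data_matrices):
        reds = [reduce_pca(m, 6) for m in toy_data_matrices]
        group = concat_reduce(reds, 3)
        idx = stability_screen(group, 3, n_runs=3, seed=0)
        assert np.all(idx > 0.9)

    def test_identical_seeds_give_full_stability(self, toy_data_matrices):
        reds = [reduce_pca(m, 6) for m in toy_data_matrices]
        group = concat_reduce(reds, 3)
        idx = stability_screen(group, 3, n_runs=2, seeds=[5, 5])
        assert np.all(idx > 0.95)

    def test_pure_noise_has_unstable_component(self, rng):
        noise = make_matrix(rng.normal(size=(1500, 30)))
        red = reduce_pca(noise, 5)
        group = concat_reduce([red], 5)
        idx = stability_screen(group, 5, n_runs=4, seed=0)
        assert idx.min() < 0.8

    def test_single_run_rejected(self, toy_data_matrices):
        reds = [reduce_pca(m, 6) for m in toy_data_matrices]
        group = concat_reduce(reds, 3)
        with pytest.raises(InvalidArgumentError):
            stability_screen(group, 3, n_runs=1)


class TestGICA3:
    def test_aggregate_identity_noiseless(self, toy_study):
        mats = [volume_to_data_matrix(v, toy_study.mask) for v in toy_study.sessions]
        res = run_gica(mats, n_components=3, session_k=6, seed=0)
        mean_maps = np.mean(res.backrecon.session_maps, axis=0)
        assert np.abs(mean_maps - res.ica.aggregate_maps).max() < 1e-6

    def test_aggregate_identity_with_noise(self, toy_data_matrices):
        res = run_gica(toy_data_matrices, n_components=3, session_k=6, seed=0)
        mean_maps = np.mean(res.backrecon.session_maps, axis=0)
        assert np.abs(mean_maps - res.ica.aggregate_maps).max() < 1e-3

    def test_single_session_map_equals_aggregate(self, toy_study):
        mats = [volume_to_data_matrix(toy_study.sessions[0], toy_study.mask)]
        res = run_gica(mats, n_components=3, session_k=6, seed=0)
        np.testing.assert_allclose(
            res.backrecon.session_maps[0], res.ica.aggregate_maps, atol=1e-8
        )

    def test_timecourses_match_generating_truth(self, toy_study):
        mats = [volume_to_data_matrix(v, toy_study.mask) for v in toy_study.sessions]
        res = run_gica(mats, n_components=3, session_k=6, seed=0)
        for true_tc, rec in zip(
            toy_study.true_timecourses, res.backrecon.session_timecourses
        ):
            assert matched_abs_corr(true_tc, rec.T).min() > 0.95

    def test_voxel_permutation_equivariance(self, toy_study, rng):
        # permuting input voxels permutes output maps the same way
        mats = [volume_to_data_matrix(v, toy_study.mask) for v in toy_study.sessions]
        res = run_gica(mats, n_components=3, session_k=6, seed=0)
        perm = rng.permutation(mats[0].n_voxels)
        mats_p = [DataMatrix(m.values[perm], m.mask) for m in mats]
        res_p = run_gica(mats_p, n_components=3, session_k=6, seed=0)
        assert matched_abs_corr(
            res.ica.aggregate_maps[:, perm], res_p.ica.aggregate_maps
        ).min() > 0.999


class TestScaling:
    def test_zscore_map_definition(self):
        m = zscore_map([1.0, 2.0, 3.0])
        assert m.values.mean() == pytest.approx(0.0, abs=1e-15)
        assert m.values.std() == pytest.approx(1.0, abs=1e-15)

    def test_zscore_idempotent_on_standardized_map(self, rng):
        v = rng.normal(size=200)
        v = (v - v.mean()) / v.std()
        np.testing.assert_allclose(zscore_map(v).values, v, atol=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(InvalidArgumentError):
            zscore_map(np.full(10, 2.0))

    def test_percent_signal_change_algebra(self, rng):
        # amplitude-a signal on baseline b: RMS of scaled series = 100*RMS/b
        a, b = 3.0, 500.0
        tc = a * np.sin(np.linspace(0, 8 * np.pi, 200))
        scaled = scale_percent_signal(tc, np.full(50, b))
        from rsnlong.outcomes import rms_percent_bold

        assert rms_percent_bold(scaled) == pytest.approx(
            100 * np.sqrt(np.mean(tc**2)) / b, abs=1e-12
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidArgumentError):
            scale_percent_signal(np.ones(10), np.zeros(5))


class TestVoxelOrdering:
    def test_volume_roundtrip_is_x_fastest(self, rng):
        mask = rng.uniform(size=(4, 3, 2)) > 0.3
        vol = rng.normal(size=(4, 3, 2, 5))
        dm = volume_to_data_matrix(vol, mask)
        back = map_to_volume(dm.values[:, 0], mask)
        np.testing.assert_allclose(back[mask], vol[..., 0][mask])
        # x index varies fastest in the flattening
        expected = vol[..., 0].reshape(-1, order="F")[mask.reshape(-1, order="F")]
        np.testing.assert_allclose(dm.values[:, 0], expected)
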