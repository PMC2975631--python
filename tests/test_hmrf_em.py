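import numpy as np
import pytest

from neoseg import (CSF, GM, WM, ClassParams, LabelMap, MRFConfig,
                    MultiChannelVolume, em_fit, estimate_bias, icm_sweep)
from neoseg.hmrf_em import negative_log_likelihood
from neoseg.parzen import classify_initial
from neoseg.preprocess import BrainMask
from neoseg.metrics import confusion, similarity_index
from neoseg.synthetic import PhantomSpec, default_specs, generate_phantom, sample_training_set

from conftest import brain_mask_of


def _simple_params(means, cov_scale=25.0, codes=(CSF, GM, WM)):
    return {c: ClassParams(mean=np.asarray(m, dtype=float),
                           cov=cov_scale * np.eye(2),
                           proportion=1.0 / len(codes))
            for c, m in zip(codes, means)}


def _clean_setup(clean_phantom, feature_map_for):
    spec, vol, truth = clean_phantom
    bm = brain_mask_of(spec, truth)
    init = classify_initial(vol, bm, feature_map_for)
    return spec, vol, truth, bm, init


@pytest.fixture(scope="module")
def clean_feature_map():
    specs = default_specs(2, seed=200, noise_sd=4.0, bias_amplitude=0.0,
                          pv_width_vox=0.0, n_wmsa=0)
    from neoseg import build_feature_map
    return build_feature_map(sample_training_set(specs, 300, seed=201))


@pytest.fixture(scope="module")
def clean_em(clean_phantom, clean_feature_map):
    spec, vol, truth = clean_phantom
    bm = brain_mask_of(spec, truth)
    init = classify_initial(vol, bm, clean_feature_map)
    params, bias, labels = em_fit(vol, bm, init, MRFConfig(beta=1.0))
    return spec, vol, truth, bm, init, params, bias, labels


def test_beta_zero_equals_ml_classification(clean_phantom, clean_feature_map):
    """With no spatial coupling and no bias, the labels are the voxelwise
    maximum-likelihood classification under the fitted Gaussians."""
    spec, vol, truth = clean_phantom
    bm = brain_mask_of(spec, truth)
    init = classify_initial(vol, bm, clean_feature_map)
    params, _, labels = em_fit(vol, bm, init, MRFConfig(beta=0.0))
    codes = [CSF, GM, WM]
    feats = np.stack([vol.pd, vol.t2], axis=-1)[bm.mask]
    nll = negative_log_likelihood(feats, [params[c] for c in codes])
    ml = np.array(codes)[nll.argmin(axis=0)]
    assert (labels.labels[bm.mask] == ml).all()


def test_em_recovers_generating_means(clean_em):
    """Class means separated >= 6 noise SD: fitted means within 2% and
    labels match truth on >= 99% of in-mask voxels."""
    spec, vol, truth, bm, init, params, bias, labels = clean_em
    for code, name in ((CSF, "csf"), (GM, "gm"), (WM, "wm")):
        gen = np.asarray(spec.class_means[name])
        rel = np.abs(params[code].mean - gen) / gen
        assert rel.max() < 0.02
    agree = (labels.labels[bm.mask] == truth.tissue.labels[bm.mask]).mean()
    assert agree >= 0.99
    for code in (CSF, GM, WM):
        assert similarity_index(confusion(truth.tissue, labels, code)) >= 0.99


def test_salt_voxel_removed_by_one_sweep():
    """A lone WM voxel in a homogeneous GM plate flips to GM in one ICM sweep
    when beta >= 2 and the two classes have identical emissions."""
    shape = (7, 7, 1)
    vol = MultiChannelVolume(pd=np.full(shape, 100.0), t2=np.full(shape, 100.0),
                             spacing=(1, 1, 1))
    labels = np.full(shape, GM, dtype=np.int16)
    labels[3, 3, 0] = WM
    lm = LabelMap(labels=labels, spacing=(1, 1, 1))
    params = _simple_params([(0, 0), (100, 100), (100, 100)])  # GM == WM emission
    out = icm_sweep(lm, vol, params, beta=2.0, n_sweeps=1)
    assert (out.labels == GM).all()


def test_icm_fixed_point_is_idempotent(clean_em):
    spec, vol, truth, bm, init, params, bias, labels = clean_em
    once = icm_sweep(labels, vol, params, beta=1.0, mask=bm.mask, n_sweeps=1)
    twice = icm_sweep(once, vol, params, beta=1.0, mask=bm.mask, n_sweeps=1)
    np.testing.assert_array_equal(twice.labels, once.labels)


def test_beta_zero_sweep_ignores_neighbors():
    rng = np.random.default_rng(0)
    shape = (6, 6, 2)
    feats = rng.normal(0, 1, (*shape, 2)) + 100
    vol = MultiChannelVolume(pd=feats[..., 0], t2=feats[..., 1], spacing=(1, 1, 1))
    params = _simple_params([(99, 99), (100, 100), (101, 101)], cov_scale=1.0)
    start = LabelMap(labels=np.full(shape, CSF, dtype=np.int16), spacing=(1, 1, 1))
    out = icm_sweep(start, vol, params, beta=0.0,
                    mask=np.ones(shape, dtype=bool), n_sweeps=1)
    codes = [CSF, GM, WM]
    nll = negative_log_likelihood(feats.reshape(-1, 2), [params[c] for c in codes])
    expect = np.array(codes)[nll.argmin(axis=0)].reshape(shape)
    np.testing.assert_array_equal(out.labels, expect)


def _python_raster_icm(labels, mask, nll, beta):
    """Independent sequential raster-order oracle (pure python)."""
    out = labels.copy()
    nx, ny, nz = labels.shape
    K = nll.shape[0]
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                if not mask[x, y, z]:
                    continue
                best, best_e = -1, np.inf
                for k in range(K):
                    e = nll[k, x, y, z]
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            if dx == dy == 0:
                                continue
                            xx, yy = x + dx, y + dy
                            if 0 <= xx < nx and 0 <= yy < ny and mask[xx, yy, z]:
                                if out[xx, yy, z] != k:
                                    e += beta
                    if e < best_e:
                        best, best_e = k, e
                out[x, y, z] = best
    return out


def test_icm_sweep_matches_bruteforce_energy_minimization():
    rng = np.random.default_rng(1)
    shape = (5, 5, 1)
    feats = rng.normal(100, 30, (*shape, 2))
    vol = MultiChannelVolume(pd=feats[..., 0], t2=feats[..., 1], spacing=(1, 1, 1))
    params = _simple_params([(60, 60), (100, 100), (140, 140)], cov_scale=400.0)
    codes = [CSF, GM, WM]
    start_idx = rng.integers(0, 3, shape)
    start = LabelMap(labels=np.array(codes, dtype=np.int16)[start_idx],
                     spacing=(1, 1, 1))
    mask = np.ones(shape, dtype=bool)
    out = icm_sweep(start, vol, params, beta=1.0, mask=mask, n_sweeps=1)

    nll = negative_log_likelihood(feats.reshape(-1, 2),
                                  [params[c] for c in codes]).reshape(3, *shape)
    oracle_idx = _python_raster_icm(start_idx.copy(), mask, nll, 1.0)
    np.testing.assert_array_equal(out.labels,
                                  np.array(codes, dtype=np.int16)[oracle_idx])


def _total_energy(labels, mask, nll, beta, codes):
    idx = np.zeros(labels.shape, dtype=int)
    for i, c in enumerate(codes):
        idx[labels == c] = i
    e = 0.0
    nx, ny, nz = labels.shape
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                if not mask[x, y, z]:
                    continue
                e += nll[idx[x, y, z], x, y, z]
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        if dx == dy == 0:
                            continue
                        xx, yy = x + dx, y + dy
                        if 0 <= xx < nx and 0 <= yy < ny and mask[xx, yy, z]:
                            if idx[xx, yy, z] != idx[x, y, z]:
                                e += 0.5 * beta  # each pair counted twice
    return e


def test_icm_energy_nonincreasing():
    rng = np.random.default_rng(2)
    shape = (8, 8, 1)
    feats = rng.normal(100, 30, (*shape, 2))
    vol = MultiChannelVolume(pd=feats[..., 0], t2=feats[..., 1], spacing=(1, 1, 1))
    params = _simple_params([(60, 60), (100, 100), (140, 140)], cov_scale=400.0)
    codes = [CSF, GM, WM]
    mask = np.ones(shape, dtype=bool)
    labels = LabelMap(labels=np.array(codes, dtype=np.int16)[rng.integers(0, 3, shape)],
                      spacing=(1, 1, 1))
    nll = negative_log_likelihood(feats.reshape(-1, 2),
                                  [params[c] for c in codes]).reshape(3, *shape)
    energies = [_total_energy(labels.labels, mask, nll, 1.0, codes)]
    for _ in range(4):
        labels = icm_sweep(labels, vol, params, beta=1.0, mask=mask, n_sweeps=1)
        energies.append(_total_energy(labels.labels, mask, nll, 1.0, codes))
    assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


def test_beta_zero_matches_independent_gmm(clean_phantom, clean_feature_map):
    """On a separable phantom, beta = 0 EM converges to the same class means
    as an independent Gaussian-mixture implementation (1e-3 relative)."""
    from sklearn.mixture import GaussianMixture
    spec, vol, truth = clean_phantom
    bm = brain_mask_of(spec, truth)
    init = classify_initial(vol, bm, clean_feature_map)
    params, _, _ = em_fit(vol, bm, init, MRFConfig(beta=0.0))
    feats = np.stack([vol.pd, vol.t2], axis=-1)[bm.mask]
    means_init = np.array([feats[init.labels[bm.mask] == c].mean(axis=0)
                           for c in (CSF, GM, WM)])
    gmm = GaussianMixture(n_components=3, covariance_type="full",
                          means_init=means_init, max_iter=100, tol=1e-6,
                          reg_covar=1e-6, random_state=0).fit(feats)
    ours = np.array([params[c].mean for c in (CSF, GM, WM)])
    rel = np.abs(ours - gmm.means_) / np.abs(gmm.means_)
    assert rel.max() < 1e-3


def test_bias_gain_near_one_without_bias(clean_em):
    spec, vol, truth, bm, init, params, bias, labels = clean_em
    bf = estimate_bias(vol, bm.mask, labels, params, smoothing_mm=25.0)
    for g in (bf.gain_pd, bf.gain_t2):
        assert np.abs(g[bm.mask] - 1).max() < 0.01
        assert abs(g[bm.mask].mean() - 1) < 1e-6  # gauge fixing


def test_bias_ramp_recovered():
    from scipy.stats import pearsonr
    spec = PhantomSpec(seed=9, bias_kind="ramp", bias_amplitude=0.1,
                       noise_sd=4.0, pv_width_vox=0.0, n_wmsa=0)
    vol, truth = generate_phantom(spec)
    bm = BrainMask(truth.brain_mask, spec.spacing)
    specs = default_specs(2, seed=3, bias_amplitude=0.0, noise_sd=4.0,
                          pv_width_vox=0.0, n_wmsa=0)
    from neoseg import build_feature_map
    fmap = build_feature_map(sample_training_set(specs, 200, seed=4))
    init = classify_initial(vol, bm, fmap)
    params, _, labels = em_fit(vol, bm, init, MRFConfig(beta=1.0))
    bf = estimate_bias(vol, bm.mask, labels, params, smoothing_mm=25.0)
    r = pearsonr(bf.gain_t2[bm.mask], truth.bias[bm.mask]).statistic
    assert r >= 0.95


def test_bias_rejects_nonpositive_intensities(clean_em):
    spec, vol, truth, bm, init, params, bias, labels = clean_em
    from neoseg.hmrf_em import BiasError
    bad = MultiChannelVolume(pd=vol.pd - vol.pd[bm.mask].max(), t2=vol.t2,
                             spacing=vol.spacing)
    with pytest.raises(BiasError):
        estimate_bias(bad, bm.mask, labels, params)


def test_em_requires_three_classes(clean_phantom):
    spec, vol, truth = clean_phantom
    bm = brain_mask_of(spec, truth)
    only_gm = LabelMap(labels=np.where(bm.mask, GM, 0).astype(np.int16),
                       spacing=spec.spacing)
    with pytest.raises(ValueError):
        em_fit(vol, bm, only_gm, MRFConfig())
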