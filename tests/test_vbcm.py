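"""Smoothing, lesion delineation and voxelwise regression with cluster FWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aphasiamap.vbcm import (
    Volume,
    cluster_fwe,
    fit_vbcm,
    gaussian_smooth,
    identify_lesion,
    load_volume,
    overlap_map,
    save_volume,
)


def vol(data, vs=2.0, **kw):
    return Volume(np.asarray(data, dtype=float), (vs, vs, vs), **kw)


class TestSmoothing:
    def test_impulse_mass_preserved(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        sm = gaussian_smooth(vol(data), fwhm_mm=4.0)
        assert sm.data.sum() == pytest.approx(1.0, abs=1e-6)
        assert sm.data[7, 7, 7] == sm.data.max()

    def test_constant_volume_unchanged_in_interior(self):
        sm = gaussian_smooth(vol(np.full((21, 21, 21), 5.0)), fwhm_mm=4.0)
        # constant padding erodes edges; the deep interior must stay constant
        assert np.allclose(sm.data[8:13, 8:13, 8:13], 5.0, atol=1e-6)

    def test_matches_dense_convolution_oracle(self):
        """Separable filtering equals brute-force dense 3-D convolution."""
        rng = np.random.default_rng(0)
        data = rng.random((11, 11, 11))
        fwhm, vs = 8.0, 2.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vs
        sm = gaussian_smooth(vol(data, vs=vs), fwhm_mm=fwhm)

        # dense oracle: explicit kernel, zero padding
        half = 8
        ax = np.arange(-half, half + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        K = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        K /= K.sum()
        out = np.zeros_like(data)
        pad = np.pad(data, half)
        for i in range(11):
            for j in range(11):
                for k in range(11):
                    out[i, j, k] = (pad[i:i + 2 * half + 1,
                                        j:j + 2 * half + 1,
                                        k:k + 2 * half + 1] * K).sum()
        np.testing.assert_allclose(sm.data, out, atol=1e-4)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(vol(np.zeros((5, 5, 5))), fwhm_mm=0)


class TestLesionIdentification:
    def _controls(self, rng, n=6, shape=(20, 20, 20), noise=2.0):
        return [vol(100 + rng.standard_normal(shape) * noise, group="control")
                for _ in range(n)]

    def test_patient_at_control_mean_no_lesion(self):
        rng = np.random.default_rng(1)
        controls = self._controls(rng)
        mu = np.mean([c.data for c in controls], axis=0)
        res = identify_lesion(vol(mu), controls)
        assert res.n_voxels == 0
        assert res.volume_mm3 == 0.0

    def test_planted_sphere_recovered_with_high_dice(self):
        rng = np.random.default_rng(2)
        shape = (24, 24, 24)
        controls = [vol(100 + rng.standard_normal(shape) * 2.0) for _ in range(16)]
        x, y, z = np.indices(shape)
        sphere = (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= 25
        patient = 100 + rng.standard_normal(shape) * 2.0
        patient[sphere] -= 40.0  # 40% signal drop
        res = identify_lesion(vol(patient), controls)
        inter = (res.lesion.data.astype(bool) & sphere).sum()
        dice = 2 * inter / (res.lesion.data.sum() + sphere.sum())
        assert dice >= 0.8

    def test_threshold_above_range_gives_empty_map(self):
        rng = np.random.default_rng(3)
        controls = self._controls(rng)
        patient = vol(rng.standard_normal((20, 20, 20)) * 50)
        res = identify_lesion(patient, controls, u_threshold=1.01)
        assert res.n_voxels == 0

    def test_zero_variance_voxels_excluded(self):
        controls = [vol(np.ones((5, 5, 5))) for _ in range(3)]
        patient = vol(np.zeros((5, 5, 5)))
        res = identify_lesion(patient, controls)
        assert res.n_excluded_voxels == 125
        assert res.n_voxels == 0


class TestOverlap:
    def test_identical_maps_stack(self):
        m = np.zeros((6, 6, 6))
        m[2:4, 2:4, 2:4] = 1
        res = overlap_map([vol(m)] * 3)
        assert res.max_count == 3
        assert res.counts.data[res.max_coordinate] == 3

    def test_disjoint_maps_max_one(self):
        a = np.zeros((6, 6, 6)); a[0, 0, 0] = 1
        b = np.zeros((6, 6, 6)); b[5, 5, 5] = 1
        assert overlap_map([vol(a), vol(b)]).max_count == 1

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            overlap_map([vol(np.full((3, 3, 3), 0.5))])


def make_cohort(n=40, shape=(12, 12, 12), seed=0, effect=None, region=None):
    """Small synthetic regression cohort; optional planted association."""
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    age = 60 + 8 * rng.standard_normal(n)
    edu = 13 + 2 * rng.standard_normal(n)
    vols = []
    for i in range(n):
        data = 100 + rng.standard_normal(shape) * 2.0
        if effect is not None:
            data[region] += effect * score[i]
        vols.append(vol(data, subject_id=f"P{i}"))
    covars = pd.DataFrame({"score": score, "age": age, "education": edu,
                           "lesion_volume": rng.random(n) * 100})
    return vols, covars


class TestGLM:
    def test_degrees_of_freedom_arithmetic(self):
        vols, covars = make_cohort(n=53)
        maps = fit_vbcm(vols, covars, ["score"], mode="separate")
        assert maps["score"].df == 53 - 5  # intercept + score + age + edu + lesion vol

    def test_exact_linear_fit_flagged_infinite(self):
        n = 20
        rng = np.random.default_rng(4)
        score = rng.standard_normal(n)
        vols = [vol(np.full((4, 4, 4), 10.0 + 3.0 * s)) for s in score]
        covars = pd.DataFrame({"score": score,
                               "age": np.zeros(n) + 60, "education": np.zeros(n) + 12})
        covars["age"] += rng.standard_normal(n) * 1e-3
        covars["education"] += rng.standard_normal(n) * 1e-3
        maps = fit_vbcm(vols, covars, ["score"], include_lesion_volume=False)
        assert np.isinf(maps["score"].t.data).all()

    def test_t_invariant_to_affine_covariate_rescaling(self):
        vols, covars = make_cohort(n=30, seed=5, effect=1.0,
                                   region=(slice(3, 6), slice(3, 6), slice(3, 6)))
        t1 = fit_vbcm(vols, covars, ["score"])["score"].t.data
        covars2 = covars.copy()
        covars2["score"] = covars2["score"] * 17.0 - 3.0
        covars2["age"] = covars2["age"] / 10.0 + 2.0
        t2 = fit_vbcm(vols, covars2, ["score"])["score"].t.data
        np.testing.assert_allclose(t1, t2, atol=1e-6)

    def test_simultaneous_disjoint_signals_peak_in_own_region(self):
        n, shape = 50, (14, 14, 14)
        rng = np.random.default_rng(6)
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        ra = (slice(2, 5), slice(2, 5), slice(2, 5))
        rb = (slice(9, 12), slice(9, 12), slice(9, 12))
        vols = []
        for i in range(n):
            d = 100 + rng.standard_normal(shape) * 1.0
            d[ra] += 4.0 * s1[i]
            d[rb] += 4.0 * s2[i]
            vols.append(vol(d))
        covars = pd.DataFrame({"sa": s1, "sb": s2,
                               "age": 60 + 8 * rng.standard_normal(n),
                               "education": 13 + 2 * rng.standard_normal(n)})
        maps = fit_vbcm(vols, covars, ["sa", "sb"], mode="simultaneous",
                        include_lesion_volume=False)
        mask_a, mask_b = np.zeros(shape, bool), np.zeros(shape, bool)
        mask_a[ra] = True
        mask_b[rb] = True
        for name, own in (("sa", mask_a), ("sb", mask_b)):
            t = np.nan_to_num(maps[name].t.data, nan=-np.inf)
            assert own[np.unravel_index(np.argmax(t), shape)]

    def test_collinear_design_rejected(self):
        vols, covars = make_cohort(n=20)
        covars["dup"] = covars["score"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_vbcm(vols, covars, ["score", "dup"], mode="simultaneous")


class TestClusterFWE:
    def _planted(self, n=45, shape=(14, 14, 14), seed=7, effect=3.0):
        rng = np.random.default_rng(seed)
        score = rng.standard_normal(n)
        region = (slice(4, 10), slice(4, 10), slice(4, 10))
        vols = []
        for i in range(n):
            d = 100 + rng.standard_normal(shape) * 1.5
            d[region] += effect * score[i]
            vols.append(vol(d))
        covars = pd.DataFrame({"score": score,
                               "age": 60 + 8 * rng.standard_normal(n),
                               "education": 13 + 2 * rng.standard_normal(n)})
        return vols, covars, region

    def test_planted_cluster_survives_with_dice(self):
        vols, covars, region = self._planted()
        sm = fit_vbcm(vols, covars, ["score"], include_lesion_volume=False)["score"]
        ct = cluster_fwe(sm, n_perm=199, seed=1)
        sig = ct.significant_mask(0.05)
        planted = np.zeros(sm.t.data.shape, bool)
        planted[region] = True
        dice = 2 * (sig & planted).sum() / max(sig.sum() + planted.sum(), 1)
        assert dice >= 0.5
        peak = ct.significant(0.05).iloc[0]
        assert planted[int(peak.peak_i), int(peak.peak_j), int(peak.peak_k)]

    def test_alpha_one_reports_every_cluster(self):
        vols, covars, _ = self._planted()
        sm = fit_vbcm(vols, covars, ["score"], include_lesion_volume=False)["score"]
        ct = cluster_fwe(sm, n_perm=99, seed=2)
        assert len(ct.significant(1.0)) == len(ct.table)

    def test_corrected_p_monotone_in_cluster_size(self):
        vols, covars, _ = self._planted(effect=1.2, seed=9)
        sm = fit_vbcm(vols, covars, ["score"], include_lesion_volume=False)["score"]
        ct = cluster_fwe(sm, n_perm=99, seed=3)
        tbl = ct.table.sort_values("n_voxels", ascending=False)
        assert (tbl["p_fwe"].diff().dropna() >= 0).all()

    def test_corrected_p_within_bounds(self):
        vols, covars, _ = self._planted(seed=11)
        sm = fit_vbcm(vols, covars, ["score"], include_lesion_volume=False)["score"]
        ct = cluster_fwe(sm, n_perm=99, seed=4)
        if len(ct.table):
            assert (ct.table["p_fwe"] >= 1 / 100).all()
            assert (ct.table["p_fwe"] <= 1.0).all()

    def test_too_few_permutations_rejected(self):
        vols, covars, _ = self._planted()
        sm = fit_vbcm(vols, covars, ["score"], include_lesion_volume=False)["score"]
        with pytest.raises(ValueError):
            cluster_fwe(sm, n_perm=50)


def test_nifti_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    v = vol(rng.random((6, 7, 8)), vs=4.0, subject_id="P1")
    path = tmp_path / "vol.nii.gz"
    save_volume(v, path)
    back = load_volume(path, subject_id="P1")
    np.testing.assert_allclose(back.data, v.data, atol=1e-6)
    assert back.voxel_size == v.voxel_size
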