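"""Stokes computation, noise estimation, DOPU, and post-filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pdoct import presets
from pdoct.polarimetry import (
    DopuVolume,
    NoiseEstimate,
    StokesVolume,
    dopu,
    estimate_noise,
    postfilter,
    stokes_from_jones,
)
from pdoct.recon import ComplexVolume, reconstruct
from pdoct.simulator import NoiseSpec, synthesize_volume


def _vol(e_h, e_v, spacing=2.8):
    return ComplexVolume(np.asarray(e_h), np.asarray(e_v), spacing)


class TestStokes:
    @pytest.mark.parametrize(
        "eh, ev, expected",
        [
            (1.0, 0.0, (1.0, 1.0, 0.0, 0.0)),  # pure H
            (1 / math.sqrt(2), 1 / math.sqrt(2), (1.0, 0.0, 1.0, 0.0)),  # 45° linear
            (1 / math.sqrt(2), 1j / math.sqrt(2), (1.0, 0.0, 0.0, 1.0)),  # circular
        ],
    )
    def test_closed_form_states(self, eh, ev, expected):
        s = stokes_from_jones(_vol(np.full((1, 1, 1), eh, complex), np.full((1, 1, 1), ev, complex)))
        got = (s.i[0, 0, 0], s.q[0, 0, 0], s.u[0, 0, 0], s.v[0, 0, 0])
        assert got == pytest.approx(expected, abs=1e-12)

    @given(
        arrays(np.float64, (2, 3, 2, 4), elements=st.floats(-2, 2, allow_nan=False)),
    )
    @settings(max_examples=25, deadline=None)
    def test_full_polarization_identity(self, parts):
        """Single-voxel fields are fully polarized: Q²+U²+V² = I²."""
        e_h = parts[0, 0] + 1j * parts[0, 1]
        e_v = parts[1, 0] + 1j * parts[1, 1]
        s = stokes_from_jones(_vol(e_h[..., None], e_v[..., None]))
        assert np.allclose(s.q**2 + s.u**2 + s.v**2, s.i**2, atol=1e-9)

    def test_rejects_nan(self):
        e = np.ones((2, 2, 2), complex)
        bad = e.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            stokes_from_jones(_vol(bad, e))


class TestNoiseEstimate:
    def test_negligible_for_noise_free_volume(self, slab_recon):
        # the signal-free region sees only numerical sidelobe leakage,
        # orders of magnitude below the in-volume signal level
        est = estimate_noise(slab_recon["vol"])
        signal = float(np.mean(slab_recon["vol"].intensity()[slab_recon["in_slab"]]))
        assert est.n_h < 1e-6 * signal and est.n_v < 1e-6 * signal

    def test_matches_independent_monte_carlo(self, desk_src, cal_true):
        """Deep-region noise energy agrees with a separately seeded replication."""
        proto = presets.desk_protocol(alines=48, bscans=8)
        empty = presets.slab_phantom(0.0, density=0.0)
        sigma = 0.8

        def deep_energy(seed):
            raw = synthesize_volume(empty, desk_src, proto, NoiseSpec(sigma, sigma), seed=seed)
            vol = reconstruct(raw, cal_true)
            return estimate_noise(vol)

        a = deep_energy(101)
        b = deep_energy(202)  # independent noise realization = the MC oracle
        assert a.n_h == pytest.approx(b.n_h, rel=0.05)
        assert a.n_v == pytest.approx(b.n_v, rel=0.05)

    def test_quadruples_when_sigma_doubles(self, desk_src, cal_true):
        proto = presets.desk_protocol(alines=32, bscans=4)
        empty = presets.slab_phantom(0.0, density=0.0)
        raw1 = synthesize_volume(empty, desk_src, proto, NoiseSpec(0.5, 0.5), seed=9)
        raw2 = synthesize_volume(empty, desk_src, proto, NoiseSpec(1.0, 1.0), seed=9)
        e1 = estimate_noise(reconstruct(raw1, cal_true))
        e2 = estimate_noise(reconstruct(raw2, cal_true))
        assert e2.n_h / e1.n_h == pytest.approx(4.0, rel=0.10)
        assert e2.n_v / e1.n_v == pytest.approx(4.0, rel=0.10)

    def test_warns_when_region_holds_structure(self, desk_src, cal_true):
        proto = presets.desk_protocol(alines=16, bscans=2)
        deep_slab = presets.slab_phantom(0.0, top_um=640.0, bottom_um=700.0)
        raw = synthesize_volume(deep_slab, desk_src, proto, NoiseSpec(), seed=4)
        vol = reconstruct(raw, cal_true)
        with pytest.warns(UserWarning, match="bright structure"):
            estimate_noise(vol)


class TestDopu:
    def test_uniform_state_gives_unity(self):
        """Identical fully polarized state across the kernel → DOPU = 1."""
        rng = np.random.default_rng(0)
        amp = rng.rayleigh(1.0, size=(16, 12, 4))  # speckle amplitudes, same state
        e_h = amp * (0.6 + 0.3j)
        e_v = amp * (0.2 - 0.7j)
        d = dopu(stokes_from_jones(_vol(e_h, e_v)))
        assert np.all(np.isfinite(d.dopu))
        assert np.allclose(d.dopu, 1.0, atol=1e-9)

    def test_degenerate_kernel_unity_everywhere(self, slab_recon):
        d = dopu(stokes_from_jones(slab_recon["vol"]), kernel=(1, 1))
        vals = d.dopu[slab_recon["in_slab"]]
        vals = vals[np.isfinite(vals)]
        assert np.allclose(vals, 1.0, atol=1e-9)

    def test_matches_random_stokes_resultant_oracle(self, rng):
        """Kernel DOPU of isotropic unit Stokes vectors equals the mean
        resultant length of N=15 random unit 3-vectors (Monte-Carlo oracle)."""
        lateral, axial = 3, 5
        shape = (axial * 20, lateral * 20, 3)  # 1200 disjoint kernels
        qvu = rng.normal(size=shape + (3,))
        qvu /= np.linalg.norm(qvu, axis=-1, keepdims=True)
        stokes = StokesVolume(
            i=np.ones(shape), q=qvu[..., 0], u=qvu[..., 1], v=qvu[..., 2]
        )
        d = dopu(stokes, kernel=(lateral, axial)).dopu
        # disjoint kernel centers
        centers = d[axial // 2 :: axial, lateral // 2 :: lateral, :]
        sample = centers.ravel()

        n_rep = 200_000
        v = rng.normal(size=(n_rep, lateral * axial, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        oracle = np.linalg.norm(v.sum(axis=1), axis=1) / (lateral * axial)

        se = math.sqrt(sample.var() / sample.size + oracle.var() / n_rep)
        assert abs(sample.mean() - oracle.mean()) < 3 * se

    @pytest.mark.parametrize("snr_db", [5, 10, 15])
    def test_noise_correction_closer_to_unity(self, desk_src, cal_true, snr_db):
        """On a preserving slab at low SNR, the noise-corrected DOPU mean is
        strictly closer to 1 than the uncorrected mean (paired realization)."""
        proto = presets.desk_protocol(alines=48, bscans=8)
        phantom = presets.slab_phantom(0.0)
        raw0 = synthesize_volume(phantom, desk_src, proto, NoiseSpec(), seed=31)
        vol0 = reconstruct(raw0, cal_true)
        from pdoct.simulator import truth_masks

        masks = truth_masks(phantom, proto, vol0.depth_axis)
        sel = masks.labels == 1
        assert sel.sum() >= 1000
        i_sig = float(np.mean(vol0.intensity()[sel]))

        empty = presets.slab_phantom(0.0, density=0.0)
        pilot = reconstruct(
            synthesize_volume(empty, desk_src, proto, NoiseSpec(1.0, 1.0), seed=77), cal_true
        )
        n_unit = float(np.mean(pilot.intensity()))
        sigma = math.sqrt(i_sig * 10 ** (-snr_db / 10) / n_unit)

        raw = synthesize_volume(phantom, desk_src, proto, NoiseSpec(sigma, sigma), seed=31)
        vol = reconstruct(raw, cal_true)
        stokes = stokes_from_jones(vol, estimate_noise(vol))
        corrected = dopu(stokes, noise_correct=True, snr_floor_factor=0.0)
        uncorrected = dopu(stokes, noise_correct=False)
        mc = float(np.nanmean(corrected.dopu[sel]))
        mu = float(np.nanmean(uncorrected.dopu[sel]))
        assert abs(mc - 1.0) < abs(mu - 1.0)

    def test_mean_dopu_non_increasing_in_depolarization(self, desk_src, cal_true):
        proto = presets.desk_protocol(alines=48, bscans=8)
        means = []
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            phantom = presets.slab_phantom(p)
            raw = synthesize_volume(phantom, desk_src, proto, NoiseSpec(), seed=11)
            vol = reconstruct(raw, cal_true)
            from pdoct.simulator import truth_masks

            masks = truth_masks(phantom, proto, vol.depth_axis)
            d = dopu(stokes_from_jones(vol))
            means.append(float(np.nanmean(d.dopu[masks.labels == 1])))
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[0] > means[-1] + 0.3  # and the contrast is substantial

    def test_range_invariant(self, slab_dopu):
        finite = slab_dopu.dopu[np.isfinite(slab_dopu.dopu)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0

    def test_rejects_even_kernel(self, slab_recon):
        stokes = stokes_from_jones(slab_recon["vol"])
        with pytest.raises(ValueError, match="odd"):
            dopu(stokes, kernel=(2, 5))

    def test_normalized_estimator_agrees_on_uniform_intensity(self, rng):
        shape = (15, 9, 3)
        qvu = rng.normal(size=shape + (3,))
        qvu /= np.linalg.norm(qvu, axis=-1, keepdims=True)
        stokes = StokesVolume(i=np.ones(shape), q=qvu[..., 0], u=qvu[..., 1], v=qvu[..., 2])
        a = dopu(stokes, estimator="sum-ratio").dopu
        b = dopu(stokes, estimator="normalized").dopu
        assert np.allclose(a, b, atol=1e-9)


class TestPostfilter:
    def test_constant_volume_unchanged(self):
        d = DopuVolume(np.full((12, 8, 4), 0.5), kernel=(3, 5))
        out = postfilter(d, dopu_threshold=0.8)
        assert np.allclose(out.dopu, 0.5)
        assert out.filtered and out.threshold_used == 0.8

    def test_supra_threshold_set_to_preserving_background(self):
        d = DopuVolume(np.full((12, 8, 4), 0.92), kernel=(3, 5))
        out = postfilter(d, dopu_threshold=0.8)
        assert np.allclose(out.dopu, 1.0)

    def test_single_voxel_impulse_removed(self):
        vol = np.ones((16, 10, 5))
        vol[8, 5, 2] = 0.1  # isolated depolarizing speck
        out = postfilter(DopuVolume(vol, kernel=(3, 5)))
        assert np.allclose(out.dopu, 1.0)

    def test_depolarizing_slab_retained(self, desk_src, cal_true):
        """A thick strongly depolarizing slab survives threshold+median."""
        proto = presets.desk_protocol(alines=48, bscans=8)
        phantom = presets.slab_phantom(0.9)
        raw = synthesize_volume(phantom, desk_src, proto, NoiseSpec(), seed=12)
        vol = reconstruct(raw, cal_true)
        from pdoct.simulator import truth_masks

        masks = truth_masks(phantom, proto, vol.depth_axis)
        out = postfilter(dopu(stokes_from_jones(vol)))
        in_slab = out.dopu[masks.labels == 1]
        assert np.mean(in_slab < 0.8) >= 0.90

    def test_nan_ignored_in_windows(self):
        vol = np.full((9, 9, 3), 0.4)
        vol[0, 0, 0] = np.nan
        out = postfilter(DopuVolume(vol, kernel=(3, 5)))
        finite = out.dopu[np.isfinite(out.dopu)]
        assert np.allclose(finite, 0.4)

    def test_rejects_even_median_kernel(self):
        d = DopuVolume(np.ones((4, 4, 4)), kernel=(3, 5))
        with pytest.raises(ValueError, match="odd"):
            postfilter(d, median_kernel=(2, 5, 3))

    def test_rejects_double_filtering(self):
        d = DopuVolume(np.ones((4, 4, 4)), kernel=(3, 5), filtered=True)
        with pytest.raises(ValueError, match="already filtered"):
            postfilter(d)


def test_noise_estimate_rejects_negative():
    with pytest.raises(ValueError):
        NoiseEstimate(-1.0, 0.0)
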