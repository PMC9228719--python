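"""Virtual instrument: profile simulation, peak fitting and the two-injection
inversion back to the diffusion matrix."""

import numpy as np
import pytest

from ternadiff.core_model import Composition, DMatrix, predict_dmatrix
from ternadiff.synthetic_data import SyntheticDesign, generate_trace_set
from ternadiff.taylor_dispersion import (
    AssemblyError,
    DispersionTrace,
    InstrumentGeometry,
    PeakFit,
    assemble_dmatrix,
    dispersion_profile,
    fit_trace,
    read_trace,
    simulate_trace,
    weights_for_injection,
    write_trace,
)

TWO_MODE = PeakFit(v0=0.05, v1=1e-5, vmax=1.2, t_r=7000.0, w1=0.7, d_eig1=1.0, d_eig2=0.4)


def random_physical_dmatrix(rng) -> DMatrix:
    """Random 2x2 diffusion matrix with real, positive, distinct eigenvalues."""
    while True:
        d11, d22 = rng.uniform(0.3, 2.0, 2)
        d12, d21 = rng.uniform(-0.2, 0.2, 2)
        disc = (d11 - d22) ** 2 + 4 * d12 * d21
        if disc < 1e-4:
            continue
        tr = d11 + d22
        lam2 = (tr - np.sqrt(disc)) / 2
        if lam2 > 0.01:
            return DMatrix(d11=d11, d12=d12, d21=d21, d22=d22)


class TestSimulate:
    def test_peak_height_at_retention_time(self):
        trace = simulate_trace(TWO_MODE)
        v_at_tr = dispersion_profile(
            np.array([TWO_MODE.t_r]), TWO_MODE.v0, TWO_MODE.v1, TWO_MODE.vmax,
            TWO_MODE.t_r, TWO_MODE.w1, TWO_MODE.d_eig1, TWO_MODE.d_eig2,
            trace.geometry.tube_radius,
        )[0]
        baseline = TWO_MODE.v0 + TWO_MODE.v1 * TWO_MODE.t_r
        assert v_at_tr - baseline == pytest.approx(TWO_MODE.vmax, abs=1e-12)

    def test_label_exchange_symmetry(self):
        swapped = PeakFit(
            v0=TWO_MODE.v0, v1=TWO_MODE.v1, vmax=TWO_MODE.vmax, t_r=TWO_MODE.t_r,
            w1=1 - TWO_MODE.w1, d_eig1=TWO_MODE.d_eig2, d_eig2=TWO_MODE.d_eig1,
        )
        a = simulate_trace(TWO_MODE, window=(4000, 10000))
        b = simulate_trace(swapped, window=(4000, 10000))
        np.testing.assert_allclose(a.voltages, b.voltages, atol=1e-15)

    def test_second_moment_is_mode_mixture(self):
        """The two-mode profile is linear in its modes, so any integral moment
        is the W1-weighted mixture of single-mode moments (quadrature check)."""
        geom = InstrumentGeometry(sampling_interval=1.0)
        window = (3000, 11000)
        kw = dict(geometry=geom, window=window)
        base = dict(v0=0.0, v1=0.0, vmax=1.0, t_r=7000.0)
        mix = simulate_trace(PeakFit(**base, w1=0.7, d_eig1=1.0, d_eig2=0.4), **kw)
        m1 = simulate_trace(PeakFit(**base, w1=1.0, d_eig1=1.0, d_eig2=0.4), **kw)
        m2 = simulate_trace(PeakFit(**base, w1=0.0, d_eig1=1.0, d_eig2=0.4), **kw)

        def moment2(tr):
            return np.trapezoid((tr.times - 7000.0) ** 2 * tr.voltages, tr.times)

        assert moment2(mix) == pytest.approx(
            0.7 * moment2(m1) + 0.3 * moment2(m2), rel=1e-12
        )

    def test_single_mode_area_scales_as_inverse_sqrt_d(self):
        """At fixed Vmax and tR the single-mode peak area follows 1/sqrt(D)
        (narrower peaks for faster diffusion), verified by quadrature."""
        geom = InstrumentGeometry(sampling_interval=1.0)
        areas = {}
        for d in (0.4, 1.0, 2.0):
            tr = simulate_trace(
                PeakFit(vmax=1.0, t_r=7000.0, w1=1.0, d_eig1=d, d_eig2=d),
                geometry=geom, window=(3000, 11000),
            )
            areas[d] = np.trapezoid(tr.voltages, tr.times)
        products = [a * np.sqrt(d) for d, a in areas.items()]
        assert max(products) / min(products) == pytest.approx(1.0, abs=1e-3)

    def test_seed_determinism(self):
        a = simulate_trace(TWO_MODE, noise_sd=0.01, seed=5)
        b = simulate_trace(TWO_MODE, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.voltages, b.voltages)

    def test_rejects_nonpositive_time_window(self):
        with pytest.raises(ValueError):
            simulate_trace(TWO_MODE, window=(-10.0, 5000.0))


class TestFitTrace:
    def test_noiseless_roundtrip_recovers_parameters(self):
        fit = fit_trace(simulate_trace(TWO_MODE))
        for name in ("vmax", "t_r", "w1", "d_eig1", "d_eig2"):
            assert getattr(fit, name) == pytest.approx(
                getattr(TWO_MODE, name), rel=1e-6
            ), name

    def test_noiseless_roundtrip_with_negative_mode_amplitude(self):
        p = PeakFit(vmax=1.0, t_r=7000.0, w1=-0.07, d_eig1=1.0, d_eig2=0.4)
        fit = fit_trace(simulate_trace(p))
        assert fit.w1 == pytest.approx(-0.07, abs=1e-6)
        assert fit.d_eig1 == pytest.approx(1.0, rel=1e-5)
        assert fit.d_eig2 == pytest.approx(0.4, rel=1e-6)

    def test_degenerate_single_mode(self):
        p = PeakFit(vmax=1.0, t_r=7000.0, w1=1.0, d_eig1=0.8, d_eig2=0.3)
        fit = fit_trace(simulate_trace(p))
        heavy = fit.d_eig1 if fit.w1 > 0.5 else fit.d_eig2
        assert heavy == pytest.approx(0.8, rel=1e-6)

    def test_retention_time_matches_profile_argmax(self):
        trace = simulate_trace(TWO_MODE)
        fit = fit_trace(trace)
        argmax_t = trace.times[int(np.argmax(trace.voltages))]
        assert abs(fit.t_r - argmax_t) <= trace.geometry.sampling_interval

    def test_noisy_recovery_within_five_percent(self):
        errs1, errs2 = [], []
        for seed in range(40):
            trace = simulate_trace(TWO_MODE, noise_sd=0.001 * TWO_MODE.vmax, seed=seed)
            fit = fit_trace(trace)
            errs1.append(abs(fit.d_eig1 / TWO_MODE.d_eig1 - 1))
            errs2.append(abs(fit.d_eig2 / TWO_MODE.d_eig2 - 1))
        assert np.median(errs1) < 0.05
        assert np.median(errs2) < 0.05


class TestWeights:
    def test_decoupled_system_pure_injections(self):
        dm = DMatrix(d11=1.0, d12=0.0, d21=0.0, d22=0.4)
        assert weights_for_injection(dm, (0.002, 0.0)) == pytest.approx(1.0, abs=1e-12)
        assert weights_for_injection(dm, (0.0, 0.002)) == pytest.approx(0.0, abs=1e-12)

    def test_weight_is_scale_invariant_and_linear_in_amplitude(self):
        rng = np.random.default_rng(11)
        rho = 1.3
        s = np.array([1.0, rho])
        for _ in range(100):
            dm = random_physical_dmatrix(rng)
            u1, u2 = (0.002, 0.0), (0.0, 0.002)
            w1 = weights_for_injection(dm, u1, rho)
            w2 = weights_for_injection(dm, u2, rho)
            assert weights_for_injection(dm, (0.004, 0.0), rho) == pytest.approx(
                w1, abs=1e-12
            )
            mixed = weights_for_injection(dm, (0.002, 0.002), rho)
            expected = (w1 * (s @ u1) + w2 * (s @ u2)) / (s @ (0.002, 0.002))
            assert mixed == pytest.approx(expected, abs=1e-12)

    def test_equal_eigenvalues_rejected(self):
        dm = DMatrix(d11=0.5, d12=0.0, d21=0.0, d22=0.5)
        with pytest.raises(ValueError, match="binary"):
            weights_for_injection(dm, (0.002, 0.0))


class TestAssemble:
    def test_forward_inverse_identity_on_random_matrices(self):
        rng = np.random.default_rng(19)
        u1, u2 = (0.002, 0.0), (0.0, 0.002)
        for _ in range(1000):
            dm = random_physical_dmatrix(rng)
            rho = rng.uniform(0.5, 2.0)
            lam = dm.eigenvalues()
            fits = [
                PeakFit(w1=weights_for_injection(dm, u, rho),
                        d_eig1=lam[0], d_eig2=lam[1])
                for u in (u1, u2)
            ]
            rec = assemble_dmatrix(fits, [u1, u2], rho)
            np.testing.assert_allclose(rec.as_array(), dm.as_array(), atol=1e-10)

    def test_general_independent_excesses(self):
        rng = np.random.default_rng(23)
        u1, u2 = (0.002, 0.0005), (0.0004, 0.002)
        for _ in range(200):
            dm = random_physical_dmatrix(rng)
            lam = dm.eigenvalues()
            fits = [
                PeakFit(w1=weights_for_injection(dm, u), d_eig1=lam[0], d_eig2=lam[1])
                for u in (u1, u2)
            ]
            rec = assemble_dmatrix(fits, [u1, u2])
            np.testing.assert_allclose(rec.as_array(), dm.as_array(), atol=1e-8)

    def test_binary_injections_give_diagonal(self):
        fits = [
            PeakFit(w1=1.0, d_eig1=1.0, d_eig2=0.4),
            PeakFit(w1=1.0, d_eig1=1.0, d_eig2=0.4),
        ]
        m = assemble_dmatrix(fits, [(0.002, 0.0), (0.001, 0.0)])
        assert m.d12 == 0.0 and m.d21 == 0.0
        assert m.d11 == pytest.approx(1.0)

    def test_dependent_excesses_rejected(self):
        fits = [PeakFit(w1=0.6, d_eig1=1.0, d_eig2=0.4)] * 2
        with pytest.raises(AssemblyError):
            assemble_dmatrix(fits, [(0.002, 0.001), (0.004, 0.002)])

    def test_inconsistent_eigenvalues_rejected(self):
        fits = [
            PeakFit(w1=0.6, d_eig1=1.0, d_eig2=0.4),
            PeakFit(w1=0.6, d_eig1=1.3, d_eig2=0.4),
        ]
        with pytest.raises(AssemblyError, match="inconsistent"):
            assemble_dmatrix(fits, [(0.002, 0.0), (0.0, 0.002)])

    def test_end_to_end_noiseless_recovers_model_matrix(self, cd_system):
        comp = Composition(0.0035, 0.0035)
        design = SyntheticDesign(
            compositions=[comp], true_system=cd_system, noise_main=0, noise_cross=0,
            seed=3,
        )
        ra, rb = generate_trace_set(design)
        fits = [fit_trace(ra.trace), fit_trace(rb.trace)]
        m = assemble_dmatrix(fits, [ra.injection_excess, rb.injection_excess])
        expected = predict_dmatrix(comp, cd_system)
        np.testing.assert_allclose(m.as_array(), expected.as_array(), atol=1e-4)


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        trace = simulate_trace(TWO_MODE, noise_sd=0.005, seed=9,
                               injection_excess=(0.002, 0.0))
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        np.testing.assert_allclose(back.times, trace.times, rtol=1e-9)
        np.testing.assert_allclose(back.voltages, trace.voltages, rtol=1e-9)
        assert back.injection_excess == trace.injection_excess
        assert back.seed == trace.seed
        assert back.geometry == trace.geometry

    def test_trace_validation(self):
        geom = InstrumentGeometry()
        with pytest.raises(ValueError, match="uniform"):
            DispersionTrace(times=np.array([1.0, 2.0, 4.0]),
                            voltages=np.zeros(3), geometry=geom)
        with pytest.raises(ValueError, match="increasing"):
            DispersionTrace(times=np.array([2.0, 1.0]),
                            voltages=np.zeros(2), geometry=geom)
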