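"""Coupling estimator contracts: closed forms, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from deltabeta.cfc import (
    AACEstimate,
    CouplingEstimate,
    amplitude_correlation,
    debiased_pac,
    dpac_z,
    electrode_composite,
    phase_clustering,
    surrogate_null,
)
from deltabeta.preprocessing import AnalyticSeries


def _series(phase, amplitude, band="x"):
    return AnalyticSeries(
        phase=np.asarray(phase, float),
        amplitude=np.asarray(amplitude, float),
        band=band,
    )


def _dpac_loop(phases, amps):
    """Per-sample loop oracle for dPAC (independent of the vectorized path)."""
    n = len(phases)
    pc = sum(complex(np.cos(p), np.sin(p)) for p in phases) / n
    acc = 0j
    for p, a in zip(phases, amps):
        acc += a * (complex(np.cos(p), np.sin(p)) - pc)
    return abs(acc / n)


class TestPhaseClustering:
    def test_uniform_grid_cancels(self):
        phases = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        assert abs(phase_clustering(phases)) < 1e-12

    def test_total_clustering(self):
        pc = phase_clustering(np.full(10, np.pi / 3))
        assert pc == pytest.approx(np.exp(1j * np.pi / 3))

    def test_two_term_mean(self):
        pc = phase_clustering(np.array([0.0, np.pi / 2]))
        assert pc == pytest.approx((1 + 1j) / 2)
        assert abs(pc) == pytest.approx(np.sqrt(2) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phase_clustering(np.array([]))


class TestDebiasedPac:
    def test_cosine_modulation_closed_form(self):
        """a = 1 + m*cos(phi) on a uniform grid gives dPAC = m/2."""
        m = 0.6
        phases = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        amps = 1.0 + m * np.cos(phases)
        est = debiased_pac(_series(phases, amps), _series(phases, amps))
        assert est.dpac_magnitude == pytest.approx(m / 2, abs=1e-6)
        assert est.dpac_magnitude == pytest.approx(_dpac_loop(phases, amps), abs=1e-12)

    def test_constant_amplitude_no_coupling(self):
        phases = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        est = debiased_pac(_series(phases, np.ones_like(phases)),
                           _series(phases, np.full_like(phases, 2.0)))
        assert est.dpac_magnitude < 1e-12

    def test_debiasing_noop_under_uniform_phases(self):
        rng = np.random.default_rng(5)
        phases = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
        amps = rng.uniform(0.5, 1.5, phases.size)
        est = debiased_pac(_series(phases, amps), _series(phases, amps))
        assert est.dpac_magnitude == pytest.approx(est.pac_magnitude, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            debiased_pac(_series([0.0, 1.0], [1.0, 1.0]), _series([0.0], [1.0]))

    def test_zero_amplitude_degenerate(self):
        phases = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        est = debiased_pac(_series(phases, np.ones_like(phases)),
                           _series(phases, np.zeros_like(phases)))
        assert est.degenerate
        assert est.dpac_magnitude == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        phases=arrays(float, 40, elements=st.floats(-np.pi, np.pi)),
        amps=arrays(float, 40, elements=st.floats(0, 5)),
    )
    def test_loop_oracle_equivalence(self, phases, amps):
        est = debiased_pac(_series(phases, amps), _series(phases, amps))
        assert est.dpac_magnitude == pytest.approx(_dpac_loop(phases, amps), abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.floats(-10, 10), seed=st.integers(0, 100))
    def test_rotation_invariance(self, shift, seed):
        """A common additive phase shift leaves the dPAC magnitude unchanged."""
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-np.pi, np.pi, 200)
        amps = rng.uniform(0.0, 2.0, 200)
        a = debiased_pac(_series(phases, amps), _series(phases, amps))
        b = debiased_pac(_series(phases + shift, amps), _series(phases, amps))
        assert b.dpac_magnitude == pytest.approx(a.dpac_magnitude, rel=1e-9, abs=1e-12)


class TestSurrogateNull:
    @staticmethod
    def _null_epochs(rng, m=6, t=256):
        phases = [
            np.angle(np.exp(1j * (2 * np.pi * rng.uniform(1, 3) * np.arange(t) / t
                                  + rng.uniform(-np.pi, np.pi))))
            for _ in range(m)
        ]
        amps = [np.abs(rng.standard_normal(t)).cumsum() / t + 0.5 for _ in range(m)]
        return phases, amps

    def test_n_perm_values_returned(self):
        rng = np.random.default_rng(0)
        phases, amps = self._null_epochs(rng)
        null = surrogate_null(phases, amps, n_perm=1000, seed=3)
        assert null.n_perm == 1000
        assert null.values.shape == (1000,)
        assert null.std > 0

    def test_identity_pairing_reproduces_observed(self):
        """With 2 epochs the surrogates take exactly the identity/swap values."""
        rng = np.random.default_rng(1)
        phases, amps = self._null_epochs(rng, m=2)
        concat_est = debiased_pac(
            _series(np.concatenate(phases), np.concatenate(amps)),
            _series(np.concatenate(phases), np.concatenate(amps)),
        )
        null = surrogate_null(phases, amps, n_perm=64, seed=0)
        observed = concat_est.dpac_magnitude
        distinct = np.unique(np.round(null.values, 12))
        assert any(abs(v - observed) < 1e-12 for v in distinct)
        assert distinct.size <= 2

    def test_factorized_matches_direct_recomputation(self):
        """The cross-epoch-sum shortcut equals brute-force re-pairing exactly."""
        rng = np.random.default_rng(7)
        phases, amps = self._null_epochs(rng, m=5, t=128)
        null = surrogate_null(phases, amps, n_perm=50, seed=11)
        rng2 = np.random.default_rng(11)
        phase_mat = np.stack(phases)
        amp_mat = np.stack(amps)
        for k in range(50):
            perm = rng2.permutation(5)
            est = debiased_pac(
                _series(phase_mat[perm].ravel(), amp_mat[perm].ravel()),
                _series(phase_mat[perm].ravel(), amp_mat.ravel()),
            )
            assert null.values[k] == pytest.approx(est.dpac_magnitude, abs=1e-12)

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError, match="shuffling undefined"):
            surrogate_null([np.zeros(8)], [np.ones(8)], n_perm=10)

    def test_null_calibration_under_independence(self):
        """Observed dPAC sits inside the central 95% of its null ~95% of runs."""
        inside = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            phases, amps = self._null_epochs(rng)
            est = debiased_pac(
                _series(np.concatenate(phases), np.concatenate(amps)),
                _series(np.concatenate(phases), np.concatenate(amps)),
            )
            null = surrogate_null(phases, amps, n_perm=200, seed=seed)
            lo, hi = np.quantile(null.values, [0.025, 0.975])
            inside += lo <= est.dpac_magnitude <= hi
        assert 0.90 <= inside / n_sim <= 0.99

    def test_scale_equivariance(self):
        """Scaling all amplitudes by c scales dPAC by c and leaves z unchanged."""
        rng = np.random.default_rng(3)
        phases, amps = self._null_epochs(rng)
        c = 3.7
        amps_scaled = [c * a for a in amps]
        def z_of(amp_list):
            cat_p = np.concatenate(phases)
            cat_a = np.concatenate(amp_list)
            est = debiased_pac(_series(cat_p, cat_a), _series(cat_p, cat_a))
            null = surrogate_null(phases, amp_list, n_perm=300, seed=5)
            return est, dpac_z(est, null)
        est1, z1 = z_of(amps)
        est2, z2 = z_of(amps_scaled)
        assert est2.dpac_magnitude == pytest.approx(c * est1.dpac_magnitude, rel=1e-9)
        assert z2 == pytest.approx(z1, rel=1e-9)


class TestDpacZ:
    def test_definition(self):
        rng = np.random.default_rng(0)
        phases = [rng.uniform(-np.pi, np.pi, 64) for _ in range(3)]
        amps = [rng.uniform(0.5, 1.5, 64) for _ in range(3)]
        null = surrogate_null(phases, amps, n_perm=100, seed=0)
        assert dpac_z(null.mean, null) == pytest.approx(0.0)
        assert dpac_z(null.mean + 2 * null.std, null) == pytest.approx(2.0)

    def test_zero_null_std_rejected(self):
        from deltabeta.cfc import SurrogateNull

        null = SurrogateNull(values=np.ones(10), seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            dpac_z(1.0, null)

    def test_power_under_strong_coupling(self):
        """Injected pac_depth 0.8 at moderate noise is detected almost always."""
        import deltabeta as db
        from deltabeta.preprocessing import preprocess_epoch_matrix
        from deltabeta.cfc import coupling_from_epochs

        hits = 0
        for seed in range(100):
            cfg = db.SimulationConfig(pac_depth=0.8, noise_sd=0.25)
            rng = np.random.default_rng(seed)
            eps = db.synthetic.generate_epochs(cfg, rng=rng, n_epochs=6,
                                               with_envelopes=False)
            phase, amp_d, amp_b = preprocess_epoch_matrix(
                np.stack([e.samples for e in eps]), cfg.sampling_rate
            )
            null = surrogate_null(list(phase), list(amp_b), n_perm=200, seed=rng)
            est = debiased_pac(_series(phase.ravel(), amp_d.ravel()),
                               _series(phase.ravel(), amp_b.ravel()))
            hits += dpac_z(est, null) > 1.645
        assert hits >= 90


class TestAmplitudeCorrelation:
    def test_affine_dependence(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.5, 2.0, 500)
        est = amplitude_correlation(d, 2 * d + 1)
        assert est.r == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.5, 2.0, 500)
        assert amplitude_correlation(d, -d).r == pytest.approx(-1.0, abs=1e-12)

    def test_independent_envelopes_near_zero(self):
        n = 5952
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            r = amplitude_correlation(
                np.abs(rng.standard_normal(n)), np.abs(rng.standard_normal(n))
            ).r
            hits += abs(r) < 0.05
        assert hits >= 95

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0.5, 2.0, 300)
        b = np.abs(rng.standard_normal(300)) + 0.1
        base = amplitude_correlation(d, b).r
        assert amplitude_correlation(0.2 * d + 3, 7 * b + 0.5).r == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            amplitude_correlation(np.ones(10), np.arange(10.0))


class TestElectrodeComposite:
    def test_mean_of_three(self):
        assert electrode_composite({"F3": 0.2, "Fz": 0.4, "F4": 0.6}) == pytest.approx(0.4)

    def test_identical_values(self):
        assert electrode_composite({"F3": 0.7, "Fz": 0.7, "F4": 0.7}) == pytest.approx(0.7)

    def test_order_invariant(self):
        a = electrode_composite({"F3": 0.1, "Fz": 0.5, "F4": 0.9})
        b = electrode_composite({"F4": 0.9, "F3": 0.1, "Fz": 0.5})
        assert a == b

    def test_missing_electrode_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            electrode_composite({"F3": 0.1, "Fz": 0.5})
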