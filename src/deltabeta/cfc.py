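"""Cross-frequency coupling estimators: debiased PAC, surrogate null, AAC.

Given a delta-phase series phi_t and a beta-amplitude series a_t over the
same timepoints, the estimators are

* phase clustering        PC   = (1/n) * sum_t exp(i*phi_t)
* raw PAC (mean form)     PAC  = (1/n) * sum_t a_t * exp(i*phi_t)
* debiased PAC            dPAC = |(1/n) * sum_t a_t * (exp(i*phi_t) - PC)|

Subtracting PC from every unit phase vector before the amplitude-weighted
average removes the bias that a non-uniform phase-angle distribution
induces in raw PAC.  Statistical significance comes from a surrogate null
built by randomly re-pairing whole epochs of phase with the intact
amplitude epochs; dPACz standardizes the observed dPAC against that null.

The amplitude-amplitude correlation (AAC) is the product-moment correlation
of the delta and beta Hilbert envelopes over all timepoints of the
concatenated epochs (Spearman variant available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as ss

from .preprocessing import AnalyticSeries

__all__ = [
    "CouplingEstimate",
    "SurrogateNull",
    "AACEstimate",
    "phase_clustering",
    "debiased_pac",
    "surrogate_null",
    "dpac_z",
    "amplitude_correlation",
    "electrode_composite",
    "coupling_from_epochs",
]


def phase_clustering(phases: np.ndarray) -> complex:
    """Complex mean of unit phase vectors: (1/n) * sum exp(i*phi).

    The modulus measures non-uniformity of the phase-angle distribution
    (0 = uniform, 1 = total clustering); the argument is the mean direction.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("phase_clustering requires a nonempty phase series")
    return complex(np.mean(np.exp(1j * phases)))


@dataclass(frozen=True)
class CouplingEstimate:
    """Debiased PAC for one subject x condition x electrode set."""

    pac_complex: complex  # mean-normalized raw PAC, (1/n) sum a_t exp(i phi_t)
    pc: complex
    dpac_complex: complex
    n_samples: int
    degenerate: bool = False  # all-zero amplitude input

    @property
    def dpac_magnitude(self) -> float:
        return abs(self.dpac_complex)

    @property
    def pac_magnitude(self) -> float:
        return abs(self.pac_complex)

    @property
    def pc_magnitude(self) -> float:
        return abs(self.pc)

    @property
    def preferred_phase(self) -> float:
        """Argument of the debiased mean vector, radians in (-pi, pi]."""
        return float(np.angle(self.dpac_complex))


def _dpac_from_arrays(phases: np.ndarray, amplitudes: np.ndarray) -> CouplingEstimate:
    phases = np.asarray(phases, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if phases.shape != amplitudes.shape or phases.ndim != 1:
        raise ValueError("phase and amplitude series must be 1-D and equal length")
    if phases.size == 0:
        raise ValueError("empty input")
    vectors = np.exp(1j * phases)
    pc = complex(vectors.mean())
    pac = complex(np.mean(amplitudes * vectors))
    dpac = complex(np.mean(amplitudes * (vectors - pc)))
    degenerate = bool(np.all(amplitudes == 0))
    return CouplingEstimate(
        pac_complex=pac,
        pc=pc,
        dpac_complex=dpac,
        n_samples=phases.size,
        degenerate=degenerate,
    )


def debiased_pac(
    series_delta: AnalyticSeries | np.ndarray,
    series_beta: AnalyticSeries | np.ndarray,
) -> CouplingEstimate:
    """Debiased PAC between a delta phase series and a beta amplitude series.

    Delta supplies the phase, beta the amplitude; both must cover the same
    timepoints.  Accepts :class:`AnalyticSeries` or plain arrays (a phase
    array and an amplitude array).  A constant-zero amplitude yields
    dPAC = 0 with the ``degenerate`` flag set.
    """
    phases = getattr(series_delta, "phase", series_delta)
    amplitudes = getattr(series_beta, "amplitude", series_beta)
    phases = np.asarray(phases, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if phases.size != amplitudes.size:
        raise ValueError(
            f"length mismatch: delta has {phases.size}, beta has {amplitudes.size} samples"
        )
    return _dpac_from_arrays(phases, amplitudes)


@dataclass(frozen=True)
class SurrogateNull:
    """Epoch-shuffled surrogate distribution of dPAC magnitudes."""

    values: np.ndarray
    seed: int
    method: str = "permute"

    @property
    def n_perm(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        """Sample standard deviation (n-1 denominator) of the surrogates."""
        return float(self.values.std(ddof=1))


def _as_matrix(epochs: Sequence[AnalyticSeries] | Sequence[np.ndarray], attr: str) -> np.ndarray:
    rows = []
    for e in epochs:
        value = getattr(e, attr, None)  # AnalyticSeries or any phase/amplitude pair
        rows.append(np.asarray(e if value is None else value, dtype=float))
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError("all epochs must have equal length")
    return np.stack(rows)


def surrogate_null(
    delta_epochs: Sequence[AnalyticSeries] | Sequence[np.ndarray],
    beta_epochs: Sequence[AnalyticSeries] | Sequence[np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "permute",
) -> SurrogateNull:
    """Surrogate dPAC null by re-pairing phase epochs with amplitude epochs.

    Each draw applies a uniform random permutation of epoch indices to the
    phase epochs only, leaving the amplitude epochs intact, and recomputes
    dPAC over the re-paired concatenation.  The identity permutation is
    permitted.  ``method='shift'`` instead rotates the pairing circularly by
    a random nonzero offset.

    Epoch shuffling permutes whole phase epochs, so the concatenated phase
    multiset -- and hence PC and the amplitude mean -- is permutation
    invariant.  Writing dPAC = |(1/n) sum_j sum_t a_{j,t} exp(i phi_{p(j),t})
    - mean(a)*PC| lets each surrogate be assembled from the precomputed
    cross-epoch sums M[j, k] = sum_t a_{j,t} exp(i phi_{k,t}).
    """
    phase = _as_matrix(delta_epochs, "phase")
    amp = _as_matrix(beta_epochs, "amplitude")
    if phase.shape != amp.shape:
        raise ValueError("delta and beta epoch stacks must have matching shapes")
    m = phase.shape[0]
    if m < 2:
        raise ValueError("epoch shuffling undefined: need at least 2 epochs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("permute", "shift"):
        raise ValueError("method must be 'permute' or 'shift'")

    n = phase.size
    vectors = np.exp(1j * phase)  # (m, T)
    pc = vectors.mean()
    amp_mean = amp.mean()
    cross = amp @ vectors.T  # cross[j, k] = sum_t a_{j,t} exp(i phi_{k,t})

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "permute":
        perms = np.stack([rng.permutation(m) for _ in range(n_perm)])
    else:
        shifts = rng.integers(1, m, size=n_perm)
        base = np.arange(m)
        perms = np.stack([(base + s) % m for s in shifts])
    rows = np.arange(m)
    sums = cross[rows[None, :], perms].sum(axis=1)  # (n_perm,)
    values = np.abs(sums / n - amp_mean * pc)
    return SurrogateNull(
        values=values,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        method=method,
    )


def dpac_z(estimate: CouplingEstimate | float, null: SurrogateNull) -> float:
    """Standardize dPAC against its surrogate null: (dPAC - mean) / std."""
    std = null.std
    if std == 0 or not np.isfinite(std):
        raise ValueError("degenerate surrogate set: null standard deviation is zero")
    value = estimate.dpac_magnitude if isinstance(estimate, CouplingEstimate) else float(estimate)
    return (value - null.mean) / std


@dataclass(frozen=True)
class AACEstimate:
    """Within-subject delta-beta amplitude-envelope correlation."""

    r: float
    n_samples: int
    method: str = "pearson"


def amplitude_correlation(
    delta_amp: np.ndarray,
    beta_amp: np.ndarray,
    method: str = "pearson",
) -> AACEstimate:
    """Correlate the delta and beta amplitude envelopes over all timepoints."""
    delta_amp = np.asarray(delta_amp, dtype=float).ravel()
    beta_amp = np.asarray(beta_amp, dtype=float).ravel()
    if delta_amp.size != beta_amp.size:
        raise ValueError("envelope series must have equal length")
    if delta_amp.size < 2:
        raise ValueError("need at least 2 timepoints")
    if delta_amp.std() == 0 or beta_amp.std() == 0:
        raise ValueError("zero-variance envelope: correlation undefined")
    if method == "pearson":
        r = ss.pearsonr(delta_amp, beta_amp).statistic
    elif method == "spearman":
        r = ss.spearmanr(delta_amp, beta_amp).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return AACEstimate(r=float(r), n_samples=delta_amp.size, method=method)


def electrode_composite(
    per_electrode_values: Mapping[str, float],
    electrodes: Sequence[str] = ("F3", "Fz", "F4"),
) -> float:
    """Arithmetic mean of a metric over the frontal electrode set."""
    missing = [e for e in electrodes if e not in per_electrode_values]
    if missing:
        raise ValueError(f"missing electrode value(s): {missing}")
    extra = [e for e in per_electrode_values if e not in electrodes]
    if extra:
        raise ValueError(f"unexpected electrode value(s): {extra}")
    values = np.array([per_electrode_values[e] for e in electrodes], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite electrode value")
    return float(values.mean())


def coupling_from_epochs(
    delta_epochs: Sequence[AnalyticSeries] | Sequence[np.ndarray],
    beta_epochs: Sequence[AnalyticSeries] | Sequence[np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "permute",
    pc_scope: str = "concat",
    aac_method: str = "pearson",
) -> dict:
    """Full per-electrode coupling analysis over a set of trimmed epochs.

    Concatenates the epochs into one phase and one amplitude series,
    computes PC / PAC / dPAC, the epoch-shuffled surrogate null, dPACz, and
    the envelope correlation.  ``pc_scope='epoch'`` subtracts each epoch's
    own PC instead of the concatenation-wide PC (diagnostic option; the
    surrogate uses the same scope).
    """
    phase = _as_matrix(delta_epochs, "phase")
    amp_b = _as_matrix(beta_epochs, "amplitude")
    amp_d = _as_matrix(delta_epochs, "amplitude")
    if pc_scope == "epoch":
        # subtracting per-epoch PC re-centres each epoch's phase vectors
        vectors = np.exp(1j * phase)
        pcs = vectors.mean(axis=1, keepdims=True)
        dpac = complex(np.mean(amp_b * (vectors - pcs)))
        est = CouplingEstimate(
            pac_complex=complex(np.mean(amp_b * vectors)),
            pc=complex(vectors.mean()),
            dpac_complex=dpac,
            n_samples=phase.size,
            degenerate=bool(np.all(amp_b == 0)),
        )
    elif pc_scope == "concat":
        est = _dpac_from_arrays(phase.ravel(), amp_b.ravel())
    else:
        raise ValueError("pc_scope must be 'concat' or 'epoch'")
    null = surrogate_null(
        list(phase), list(amp_b), n_perm=n_perm, seed=seed, method=method
    ) if pc_scope == "concat" else _surrogate_null_epoch_pc(phase, amp_b, n_perm, seed, method)
    z = dpac_z(est, null)
    aac = amplitude_correlation(amp_d.ravel(), amp_b.ravel(), method=aac_method)
    return {"estimate": est, "null": null, "dpac_z": z, "aac": aac}


def _surrogate_null_epoch_pc(
    phase: np.ndarray,
    amp: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator,
    method: str,
) -> SurrogateNull:
    """Direct (non-factorized) surrogate recomputation under per-epoch PC."""
    m = phase.shape[0]
    if m < 2:
        raise ValueError("epoch shuffling undefined: need at least 2 epochs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vectors = np.exp(1j * phase)
    pcs = vectors.mean(axis=1, keepdims=True)
    centred = vectors - pcs
    values = np.empty(n_perm)
    for i in range(n_perm):
        if method == "permute":
            perm = rng.permutation(m)
        else:
            perm = (np.arange(m) + rng.integers(1, m)) % m
        values[i] = abs(np.mean(amp * centred[perm]))
    return SurrogateNull(
        values=values,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        method=method,
    )
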