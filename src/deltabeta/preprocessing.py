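"""Filtering / Hilbert preprocessing chain for delta-beta coupling analysis.

The chain applied to every selected epoch is::

    downsample (512 -> 128 Hz) -> zero-phase Butterworth band-pass
        -> Hilbert analytic signal -> trim 16 samples per edge

The delta (1-4 Hz) and beta (14-30 Hz) chains run independently on the
*same* epoch; delta supplies instantaneous phase, beta supplies the
amplitude envelope.  All operations here are deterministic except
:func:`select_clean_epochs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Epoch",
    "AnalyticSeries",
    "DELTA_BAND",
    "BETA_BAND",
    "DELTA_ORDER",
    "BETA_ORDER",
    "ANALYSIS_RATE",
    "EDGE_TRIM",
    "segment_epochs",
    "select_clean_epochs",
    "downsample",
    "bandpass_zero_phase",
    "hilbert_decompose",
    "trim_edges",
    "analytic_chain",
    "preprocess_epoch_matrix",
]

DELTA_BAND: tuple[float, float] = (1.0, 4.0)
BETA_BAND: tuple[float, float] = (14.0, 30.0)
#: one-pass band-pass filter order; doubled by forward-backward filtering
DELTA_ORDER: int = 8
BETA_ORDER: int = 34
ANALYSIS_RATE: float = 128.0
#: samples removed per epoch edge after the Hilbert transform
EDGE_TRIM: int = 16


@dataclass
class Epoch:
    """One fixed-length single-channel segment, the atomic analysis unit."""

    samples: np.ndarray
    sampling_rate: float
    channel: str | None = None
    condition: str | None = None
    position_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Epoch samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("Epoch is empty")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class AnalyticSeries:
    """Per-sample instantaneous phase and amplitude of one band-passed epoch.

    ``phase`` is in radians in (-pi, pi], with phase 0 at the positive peak
    of the band-limited oscillation (Hilbert convention for a cosine);
    ``amplitude`` is the nonnegative modulus of the analytic signal.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    band: str
    sampling_rate: float = ANALYSIS_RATE

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must have equal length")
        if self.phase.ndim != 1:
            raise ValueError("AnalyticSeries must be one-dimensional")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")

    @property
    def n(self) -> int:
        return self.phase.size


def segment_epochs(
    signal: np.ndarray,
    sampling_rate: float,
    epoch_duration: float = 8.0,
    channel: str | None = None,
    condition: str | None = None,
) -> list[Epoch]:
    """Cut a continuous single-channel series into non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.
    """
    signal = np.asarray(signal, dtype=float)
    n_per_epoch = int(round(epoch_duration * sampling_rate))
    if abs(epoch_duration * sampling_rate - n_per_epoch) > 1e-9:
        raise ValueError("epoch_duration x sampling_rate must be an integer")
    if signal.size < n_per_epoch:
        raise ValueError(
            f"signal of {signal.size} samples is shorter than one epoch "
            f"({n_per_epoch} samples)"
        )
    n_epochs = signal.size // n_per_epoch
    return [
        Epoch(
            samples=signal[i * n_per_epoch : (i + 1) * n_per_epoch],
            sampling_rate=sampling_rate,
            channel=channel,
            condition=condition,
            position_index=i,
        )
        for i in range(n_epochs)
    ]


def select_clean_epochs(
    epochs: Sequence[Epoch],
    clean_mask: Sequence[bool],
    n_early: int,
    n_late: int,
    seed: int | np.random.Generator = 0,
    pool_size: int = 10,
) -> tuple[list[Epoch], list[Epoch]]:
    """Randomly select clean epochs from the early and late ends of a recording.

    ``n_early`` epochs are drawn uniformly without replacement from the clean
    epochs among the first ``pool_size``, and ``n_late`` from the clean epochs
    among the last ``pool_size``.  Selected epochs keep their original order.
    """
    if len(clean_mask) != len(epochs):
        raise ValueError("clean_mask must match epochs in length")
    mask = np.asarray(clean_mask, dtype=bool)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    early_pool = [i for i in range(min(pool_size, len(epochs))) if mask[i]]
    late_start = max(len(epochs) - pool_size, 0)
    late_pool = [i for i in range(late_start, len(epochs)) if mask[i]]

    if len(early_pool) < n_early:
        raise ValueError(
            f"need {n_early} clean early epochs but only {len(early_pool)} "
            f"of the first {pool_size} are clean"
        )
    if len(late_pool) < n_late:
        raise ValueError(
            f"need {n_late} clean late epochs but only {len(late_pool)} "
            f"of the last {pool_size} are clean"
        )

    early_idx = sorted(rng.choice(early_pool, size=n_early, replace=False))
    late_idx = sorted(rng.choice(late_pool, size=n_late, replace=False))
    return [epochs[i] for i in early_idx], [epochs[i] for i in late_idx]


def _antialias_taps(factor: int, sampling_rate: float, numtaps: int = 129) -> np.ndarray:
    target_nyquist = sampling_rate / factor / 2.0
    return sps.firwin(numtaps, 0.8 * target_nyquist, fs=sampling_rate)


def downsample(epoch: Epoch, target_rate: float = ANALYSIS_RATE) -> Epoch:
    """Anti-alias filter and decimate an epoch to ``target_rate``.

    The decimation factor must be an integer; a zero-phase FIR low-pass with
    cutoff at 0.8x the target Nyquist precedes sample picking.
    """
    factor = epoch.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {epoch.sampling_rate}/{target_rate} is not an integer"
        )
    factor = int(round(factor))
    if target_rate / 2.0 <= BETA_BAND[1]:
        raise ValueError(
            f"target Nyquist {target_rate / 2.0} Hz does not cover the beta "
            f"band edge {BETA_BAND[1]} Hz"
        )
    if factor == 1:
        return replace(epoch, samples=epoch.samples.copy(), sampling_rate=float(target_rate))
    taps = _antialias_taps(factor, epoch.sampling_rate)
    filtered = sps.filtfilt(taps, [1.0], epoch.samples)
    return replace(epoch, samples=filtered[::factor], sampling_rate=float(target_rate))


def _design_bandpass(band: tuple[float, float], order: int, sampling_rate: float) -> np.ndarray:
    low, high = band
    nyquist = sampling_rate / 2.0
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
        )
    if order % 2 != 0 or order < 2:
        raise ValueError("band-pass order must be an even positive integer")
    # butter() with btype='bandpass' returns a filter of order 2N; the
    # configured order is the overall one-pass order, so N = order // 2.
    sos = sps.butter(order // 2, band, btype="bandpass", fs=sampling_rate, output="sos")
    poles_ok = all(
        np.all(np.abs(np.roots(section[3:])) < 1.0) for section in sos
    )
    if not poles_ok:
        raise ValueError(
            "unstable band-pass realization; re-design with cascaded "
            "second-order sections at a lower order or sampling rate"
        )
    return sos


def bandpass_zero_phase(
    epoch: Epoch,
    band: tuple[float, float],
    order: int,
    demean: bool = True,
) -> Epoch:
    """Forward-backward Butterworth band-pass (zero net phase shift).

    ``order`` is the one-pass order of the band-pass design; the effective
    order doubles through the forward and backward passes.  The filter is
    realized as cascaded second-order sections for numerical stability.
    """
    sos = _design_bandpass(band, order, epoch.sampling_rate)
    x = epoch.samples
    if demean:
        x = x - x.mean()
    filtered = sps.sosfiltfilt(sos, x)
    return replace(epoch, samples=filtered)


def hilbert_decompose(filtered: Epoch, band: str = "") -> AnalyticSeries:
    """Analytic signal of a band-limited epoch: per-sample phase and amplitude."""
    if filtered.n_samples == 0:
        raise ValueError("cannot decompose an empty epoch")
    analytic = sps.hilbert(filtered.samples)
    return AnalyticSeries(
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        band=band,
        sampling_rate=filtered.sampling_rate,
    )


def trim_edges(series: AnalyticSeries, n_trim: int = EDGE_TRIM) -> AnalyticSeries:
    """Drop ``n_trim`` samples from each end to remove filter edge artefacts."""
    if n_trim < 0:
        raise ValueError("n_trim must be nonnegative")
    if n_trim == 0:
        return series
    if series.n <= 2 * n_trim:
        raise ValueError(
            f"series of {series.n} samples is too short to trim {n_trim} per edge"
        )
    sl = slice(n_trim, series.n - n_trim)
    return AnalyticSeries(
        phase=series.phase[sl],
        amplitude=series.amplitude[sl],
        band=series.band,
        sampling_rate=series.sampling_rate,
    )


def analytic_chain(
    epoch: Epoch,
    band: tuple[float, float],
    order: int,
    band_label: str = "",
    target_rate: float = ANALYSIS_RATE,
    n_trim: int = EDGE_TRIM,
    demean: bool = True,
) -> AnalyticSeries:
    """Full per-epoch chain: downsample, band-pass, Hilbert, trim."""
    low = downsample(epoch, target_rate) if epoch.sampling_rate != target_rate else epoch
    filtered = bandpass_zero_phase(low, band, order, demean=demean)
    return trim_edges(hilbert_decompose(filtered, band=band_label), n_trim=n_trim)


def preprocess_epoch_matrix(
    epochs: np.ndarray,
    sampling_rate: float,
    target_rate: float = ANALYSIS_RATE,
    delta_band: tuple[float, float] = DELTA_BAND,
    beta_band: tuple[float, float] = BETA_BAND,
    delta_order: int = DELTA_ORDER,
    beta_order: int = BETA_ORDER,
    n_trim: int = EDGE_TRIM,
    demean: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized chain over a stack of epochs.

    ``epochs`` has shape (n_epochs, n_samples).  Returns
    ``(delta_phase, delta_amplitude, beta_amplitude)``, each of shape
    (n_epochs, n_trimmed).  Numerically identical to running
    :func:`analytic_chain` per epoch; used by the pipeline for speed.
    """
    x = np.asarray(epochs, dtype=float)
    if x.ndim != 2:
        raise ValueError("epochs must be a 2-D (n_epochs, n_samples) array")
    factor = sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("decimation factor must be an integer")
    factor = int(round(factor))
    if factor > 1:
        taps = _antialias_taps(factor, sampling_rate)
        x = sps.filtfilt(taps, [1.0], x, axis=-1)[:, ::factor]
    if demean:
        x = x - x.mean(axis=-1, keepdims=True)

    sos_d = _design_bandpass(delta_band, delta_order, target_rate)
    sos_b = _design_bandpass(beta_band, beta_order, target_rate)
    delta = sps.sosfiltfilt(sos_d, x, axis=-1)
    beta = sps.sosfiltfilt(sos_b, x, axis=-1)
    a_d = sps.hilbert(delta, axis=-1)
    a_b = sps.hilbert(beta, axis=-1)
    sl = slice(n_trim, x.shape[-1] - n_trim) if n_trim else slice(None)
    return np.angle(a_d[:, sl]), np.abs(a_d[:, sl]), np.abs(a_b[:, sl])
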