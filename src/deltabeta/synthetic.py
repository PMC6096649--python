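"""Synthetic EEG generator with controllable delta-beta coupling.

Emulates the statistical structure the coupling analysis assumes: a delta
(1-4 Hz) oscillation and a beta (14-30 Hz) oscillation embedded in 1/f-like
background noise, with

* phase-amplitude coupling: the beta amplitude is modulated as
  ``base * (1 + pac_depth * cos(phi_delta - preferred_phase))``,
* amplitude-amplitude correlation: slowly varying delta and beta envelopes
  built from a shared latent envelope mixed so their population correlation
  equals ``aac_rho``,
* phase-clustering bias: a monotone within-cycle time-warp of the delta
  waveform that makes the delta phase-angle distribution non-uniform
  without changing duration or sampling rate.

The beta carrier sits at the band centre (22 Hz); the delta carrier sits
at 1.75 Hz so that the second harmonic the phase-clustering warp creates
(3.5 Hz) stays inside the delta band and survives band-pass filtering --
a warp of a mid-band 2.5 Hz carrier would put its sidebands at 0 and 5 Hz,
where the filter removes them and uniformizes the phase again.  Every
generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .preprocessing import Epoch

__all__ = [
    "SimulationConfig",
    "SubjectData",
    "SyntheticCohort",
    "CHANNELS",
    "CONDITIONS",
    "GROUPS",
    "DEFAULT_GROUP_SIZES",
    "generate_pac_epoch",
    "generate_aac_epochs",
    "generate_epochs",
    "apply_phase_clustering_bias",
    "generate_cohort",
]

CHANNELS: tuple[str, ...] = ("F3", "Fz", "F4")
CONDITIONS: tuple[str, ...] = (
    "resting",
    "early_anticipation",
    "late_anticipation",
    "early_recovery",
    "late_recovery",
)
GROUPS: tuple[str, ...] = ("LSA", "HSA")
#: study-sized cohort: 32 low and 20 high socially anxious subjects
DEFAULT_GROUP_SIZES: Mapping[str, int] = {"LSA": 32, "HSA": 20}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording condition.

    ``pac_depth`` is the fractional beta-amplitude modulation by delta phase
    (0 = none, 1 = full); ``aac_rho`` the target correlation of the slow
    delta and beta envelopes; ``noise_sd`` the ratio of background-noise SD
    to the SD of the summed oscillatory components; ``phase_bias`` in [0, 1]
    controls the non-uniformity of the delta phase distribution (0 =
    uniform).
    """

    sampling_rate: float = 512.0
    epoch_duration: float = 8.0
    n_epochs_per_condition: int = 6
    delta_band: tuple[float, float] = (1.0, 4.0)
    beta_band: tuple[float, float] = (14.0, 30.0)
    pac_depth: float = 0.5
    aac_rho: float = 0.0
    noise_sd: float = 0.5
    phase_bias: float = 0.0
    preferred_phase: float = 0.0
    seed: int = 0
    noise_color: str = "pink"
    delta_amplitude: float = 1.0
    beta_amplitude: float = 0.25
    env_depth: float = 0.35
    env_tau: float = 0.4
    delta_carrier: float = 1.75
    beta_carrier: float = 22.0
    carrier_jitter: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must lie in [0, 1]")
        if not -1.0 <= self.aac_rho <= 1.0:
            raise ValueError("aac_rho must lie in [-1, 1]")
        if not 0.0 <= self.phase_bias <= 1.0:
            raise ValueError("phase_bias must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name, (low, high) in (("delta", self.delta_band), ("beta", self.beta_band)):
            if not 0 < low < high:
                raise ValueError(f"{name} band edges must satisfy 0 < low < high")
            if high >= self.sampling_rate / 2.0:
                raise ValueError(
                    f"{name} band edge {high} Hz reaches the Nyquist frequency "
                    f"({self.sampling_rate / 2.0} Hz)"
                )
        n = self.epoch_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_duration x sampling_rate must be an integer")
        if self.noise_color not in ("pink", "white"):
            raise ValueError("noise_color must be 'pink' or 'white'")
        if self.n_epochs_per_condition < 1:
            raise ValueError("n_epochs_per_condition must be >= 1")
        if not self.delta_band[0] <= self.delta_carrier <= self.delta_band[1]:
            raise ValueError("delta_carrier must lie inside the delta band")
        if not self.beta_band[0] <= self.beta_carrier <= self.beta_band[1]:
            raise ValueError("beta_carrier must lie inside the beta band")
        if not 0.0 <= self.carrier_jitter < 1.0:
            raise ValueError("carrier_jitter must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate))

    @property
    def delta_freq(self) -> float:
        return self.delta_carrier

    @property
    def beta_freq(self) -> float:
        return self.beta_carrier


def _rng_of(cfg: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def _pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent power-shaped Gaussian noise, unit SD."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _smooth_latent(n: int, fs: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized: a slow latent envelope."""
    width = max(int(round(tau * fs)), 1)
    half = 4 * width
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / width) ** 2)
    kernel /= kernel.sum()
    raw = rng.standard_normal(n + 2 * half)
    smooth = fftconvolve(raw, kernel, mode="same")[half:-half]
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _delta_phase(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Instantaneous delta phase; warped toward ``preferred_phase`` if biased.

    The carrier frequency receives a small uniform per-epoch jitter
    (``carrier_jitter`` fractional range) so that, like real broadband delta,
    the phase of one epoch does not stay aligned with the amplitude
    modulation of another -- without it, epoch re-pairing would merely
    rotate a perfectly periodic coupling vector instead of destroying it and
    the surrogate null would grow with the injected coupling.
    """
    t = np.arange(cfg.n_samples) / cfg.sampling_rate
    freq = cfg.delta_freq * (1.0 + cfg.carrier_jitter * rng.uniform(-1.0, 1.0))
    theta = 2.0 * math.pi * freq * t + rng.uniform(-math.pi, math.pi)
    if cfg.phase_bias > 0:
        # monotone warp: d(theta')/d(theta) = 1 - b*cos(theta - mu) > 0 for b < 1,
        # so sample density peaks where cos(theta - mu) = 1, i.e. at mu.
        b = 0.95 * cfg.phase_bias
        theta = theta - b * np.sin(theta - cfg.preferred_phase)
    return theta


def _envelope_pair(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two slow positive envelopes whose population correlation is aac_rho.

    Built by mixing a shared latent with independent latents:
    ``z1 = a*S + sqrt(1-a^2)*I1``, ``z2 = sign(rho)*a*S + sqrt(1-a^2)*I2``
    with ``a = sqrt(|rho|)``, so corr(z1, z2) = rho.
    """
    n, fs, tau = cfg.n_samples, cfg.sampling_rate, cfg.env_tau
    shared = _smooth_latent(n, fs, tau, rng)
    ind1 = _smooth_latent(n, fs, tau, rng)
    ind2 = _smooth_latent(n, fs, tau, rng)
    a = math.sqrt(abs(cfg.aac_rho))
    b = math.sqrt(max(1.0 - abs(cfg.aac_rho), 0.0))
    z1 = a * shared + b * ind1
    z2 = math.copysign(a, cfg.aac_rho) * shared + b * ind2 if cfg.aac_rho != 0 else ind2
    if abs(cfg.aac_rho) == 1.0:
        z2 = math.copysign(1.0, cfg.aac_rho) * z1
    env1 = np.clip(1.0 + cfg.env_depth * z1, 0.05, None)
    env2 = np.clip(1.0 + cfg.env_depth * z2, 0.05, None)
    return env1, env2


def _compose_epoch(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    with_envelopes: bool,
    position_index: int | None = None,
    channel: str | None = None,
    condition: str | None = None,
) -> tuple[Epoch, np.ndarray, np.ndarray]:
    theta = _delta_phase(cfg, rng)
    t = np.arange(cfg.n_samples) / cfg.sampling_rate
    psi0 = rng.uniform(-math.pi, math.pi)
    if with_envelopes:
        env_d, env_b = _envelope_pair(cfg, rng)
    else:
        env_d = np.ones(cfg.n_samples)
        env_b = np.ones(cfg.n_samples)
    delta = cfg.delta_amplitude * env_d * np.cos(theta)
    beta_amp = (
        cfg.beta_amplitude
        * env_b
        * (1.0 + cfg.pac_depth * np.cos(theta - cfg.preferred_phase))
    )
    beta = beta_amp * np.cos(2.0 * math.pi * cfg.beta_freq * t + psi0)
    osc = delta + beta
    if cfg.noise_sd > 0:
        unit = (
            _pink_noise(cfg.n_samples, rng)
            if cfg.noise_color == "pink"
            else rng.standard_normal(cfg.n_samples)
        )
        osc = osc + cfg.noise_sd * osc.std() * unit
    epoch = Epoch(
        samples=osc,
        sampling_rate=cfg.sampling_rate,
        channel=channel,
        condition=condition,
        position_index=position_index,
    )
    return epoch, env_d, env_b, beta_amp


def generate_pac_epoch(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_envelope: bool = False,
):
    """One epoch with delta-phase -> beta-amplitude coupling of depth ``pac_depth``.

    The initial delta phase is randomized per epoch; no slow envelopes are
    applied (see :func:`generate_aac_epochs` for envelope coupling).
    Deterministic given ``cfg.seed`` (or an explicit ``rng``).
    """
    epoch, _, _, beta_env = _compose_epoch(cfg, _rng_of(cfg, rng), with_envelopes=False)
    if return_envelope:
        return epoch, beta_env
    return epoch


def generate_aac_epochs(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_epochs: int | None = None,
    return_envelopes: bool = False,
):
    """Epochs whose delta and beta envelopes correlate at ``aac_rho``.

    With ``return_envelopes=True`` also returns the injected (pre-noise)
    delta and beta envelope arrays, one pair per epoch.
    """
    rng = _rng_of(cfg, rng)
    n_epochs = cfg.n_epochs_per_condition if n_epochs is None else n_epochs
    epochs: list[Epoch] = []
    envs: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n_epochs):
        epoch, env_d, env_b, _ = _compose_epoch(cfg, rng, with_envelopes=True, position_index=i)
        epochs.append(epoch)
        envs.append((env_d, env_b))
    if return_envelopes:
        return epochs, envs
    return epochs


def generate_epochs(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_epochs: int | None = None,
    with_envelopes: bool = True,
    channel: str | None = None,
    condition: str | None = None,
) -> list[Epoch]:
    """General-purpose epoch set with both coupling mechanisms active."""
    rng = _rng_of(cfg, rng)
    n_epochs = cfg.n_epochs_per_condition if n_epochs is None else n_epochs
    return [
        _compose_epoch(
            cfg, rng, with_envelopes=with_envelopes,
            position_index=i, channel=channel, condition=condition,
        )[0]
        for i in range(n_epochs)
    ]


def apply_phase_clustering_bias(epoch: Epoch, cfg: SimulationConfig) -> Epoch:
    """Warp an epoch in time within each delta cycle to cluster delta phases.

    The warp ``w(t) = t - c*(sin(2*pi*f_d*t - mu) - sin(-mu))`` with
    ``c = 0.95*phase_bias/(2*pi*f_d)`` is monotone, preserves the first and
    last sample times, and leaves duration and sampling rate unchanged.  The
    resulting delta phase-angle distribution is non-uniform with |PC|
    increasing in ``phase_bias``.
    """
    if cfg.phase_bias == 0:
        return replace(epoch, samples=epoch.samples.copy())
    f_d = cfg.delta_freq
    mu = cfg.preferred_phase
    c = 0.95 * cfg.phase_bias / (2.0 * math.pi * f_d)
    t = np.arange(epoch.n_samples) / epoch.sampling_rate
    warped_t = t - c * (np.sin(2.0 * math.pi * f_d * t - mu) - math.sin(-mu))
    warped_t = np.clip(warped_t, t[0], t[-1])
    return replace(epoch, samples=np.interp(warped_t, t, epoch.samples))


@dataclass
class SubjectData:
    """All epochs and covariates for one synthetic subject."""

    subject_id: str
    group: str
    #: condition -> array of shape (n_channels, n_epochs, n_samples)
    data: dict[str, np.ndarray]
    covariates: dict[str, float] = field(default_factory=dict)
    coupling_scale: float = 1.0


@dataclass
class SyntheticCohort:
    subjects: list[SubjectData]
    channels: tuple[str, ...]
    conditions: tuple[str, ...]
    sampling_rate: float
    provenance: dict

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.subjects:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        return sizes


def generate_cohort(
    cfg_by_group_condition: Mapping[tuple[str, str], SimulationConfig]
    | Mapping[str, SimulationConfig],
    group_sizes: Mapping[str, int] = DEFAULT_GROUP_SIZES,
    conditions: Sequence[str] = CONDITIONS,
    channels: Sequence[str] = CHANNELS,
    master_seed: int = 0,
    subject_scale_sd: float = 0.0,
    covariate_rho: float | None = None,
) -> SyntheticCohort:
    """Generate a full cohort with reproducible per-subject seeds.

    ``cfg_by_group_condition`` maps ``(group, condition)`` to a
    :class:`SimulationConfig`; a mapping keyed by group alone applies that
    group's config to every condition.  ``subject_scale_sd`` adds
    between-subject variability by scaling each subject's injected coupling
    (pac_depth and aac_rho) by a truncated-normal factor; ``covariate_rho``
    (if given) adds a synthetic nervousness score correlated at that rho
    with the subject's coupling scale, to exercise the correlation layer.
    """
    groups = list(group_sizes)
    for g, size in group_sizes.items():
        if size < 2:
            raise ValueError(f"group {g!r} must have at least 2 subjects")

    def cfg_for(group: str, condition: str) -> SimulationConfig:
        if (group, condition) in cfg_by_group_condition:
            return cfg_by_group_condition[(group, condition)]  # type: ignore[index]
        if group in cfg_by_group_condition:
            return cfg_by_group_condition[group]  # type: ignore[index]
        raise ValueError(f"missing simulation config for group {group!r}, condition {condition!r}")

    # validate all configs up front
    base_cfgs = {(g, c): cfg_for(g, c) for g in groups for c in conditions}
    first = next(iter(base_cfgs.values()))
    if any(c.sampling_rate != first.sampling_rate for c in base_cfgs.values()):
        raise ValueError("all configs must share one sampling rate")

    n_total = sum(group_sizes.values())
    child_seeds = np.random.SeedSequence(master_seed).spawn(n_total)
    subjects: list[SubjectData] = []
    idx = 0
    for group in groups:
        for j in range(group_sizes[group]):
            rng = np.random.default_rng(child_seeds[idx])
            scale = 1.0
            if subject_scale_sd > 0:
                scale = max(rng.normal(1.0, subject_scale_sd), 0.0)
            data: dict[str, np.ndarray] = {}
            for condition in conditions:
                cfg = base_cfgs[(group, condition)]
                if scale != 1.0:
                    cfg = replace(
                        cfg,
                        pac_depth=float(np.clip(cfg.pac_depth * scale, 0.0, 1.0)),
                        aac_rho=float(np.clip(cfg.aac_rho * scale, -1.0, 1.0)),
                    )
                arr = np.empty(
                    (len(channels), cfg.n_epochs_per_condition, cfg.n_samples)
                )
                for k, channel in enumerate(channels):
                    eps = generate_epochs(
                        cfg, rng=rng, with_envelopes=True,
                        channel=channel, condition=condition,
                    )
                    arr[k] = np.stack([e.samples for e in eps])
                data[condition] = arr
            covariates: dict[str, float] = {}
            if covariate_rho is not None:
                z_scale = (scale - 1.0) / subject_scale_sd if subject_scale_sd > 0 else 0.0
                noise = rng.standard_normal()
                latent = covariate_rho * z_scale + math.sqrt(
                    max(1.0 - covariate_rho**2, 0.0)
                ) * noise
                covariates["nervousness"] = float(np.clip(50.0 + 15.0 * latent, 0.0, 100.0))
            subjects.append(
                SubjectData(
                    subject_id=f"{group}{j + 1:03d}",
                    group=group,
                    data=data,
                    covariates=covariates,
                    coupling_scale=scale,
                )
            )
            idx += 1
    provenance = {
        "master_seed": master_seed,
        "group_sizes": dict(group_sizes),
        "subject_scale_sd": subject_scale_sd,
        "covariate_rho": covariate_rho,
        "configs": {
            f"{g}/{c}": vars(cfg).copy() for (g, c), cfg in base_cfgs.items()
        },
    }
    return SyntheticCohort(
        subjects=subjects,
        channels=tuple(channels),
        conditions=tuple(conditions),
        sampling_rate=first.sampling_rate,
        provenance=provenance,
    )
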