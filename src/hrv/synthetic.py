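"""IPFM-based synthetic RR-interval generator.

The integral pulse frequency modulation (IPFM) model emits a beat every time
the running integral of an instantaneous heart rate signal crosses an
integer.  Modulating that rate with a respiratory-band sinusoid (HF), a
slower Mayer-wave sinusoid (LF) and a smoothed broadband noise term produces
tachograms with controlled spectral content — the standard way to exercise an
HRV pipeline when real Holter recordings are unavailable.

The default preset emulates a young adult dog asleep: mean RR 560 ms
(~107 bpm), respiratory peak at 0.30 Hz, LF oscillation at 0.09 Hz.  A
``sympatho_shift`` parameter in [0, 1] moves the model toward sympathetic
predominance — faster rate, damped respiratory sinus arrhythmia, enhanced LF
— emulating the autonomic signature of doxorubicin cardiotoxicity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d

from .series import BeatSeries, parse_clock

#: IPFM integration grid step (s).  Crossing times are linearly interpolated
#: between grid nodes, so beat-time error is O(dt^2) of the rate curvature.
IPFM_GRID_DT = 0.004

#: Width (s) of the moving-average window applied to the broadband
#: rate-modulation noise, keeping its variance finite across all bands.
NOISE_SMOOTH_S = 2.0

# sympatho_shift=1 maps to: 8% faster rate, 60% loss of HF (vagal) amplitude,
# 40% gain of LF amplitude.  These are package constants shaping the Pre/Post
# contrast, not physiological claims.
SHIFT_MEAN_RR = 0.08
SHIFT_A_HF = 0.60
SHIFT_A_LF = 0.40


@dataclass(frozen=True)
class AutonomicConfig:
    """Parameters of the instantaneous-rate model.

    Rate (beats/s) on the integration grid:

    ``r(t) = (1000/mean_rr) * (1 + a_lf sin(2 pi f_lf t + phase_lf)
    + a_hf sin(2 pi f_hf t + phase_hf) + eta(t))``

    with ``eta`` a smoothed Gaussian process of standard deviation
    ``noise_sd``.  Phases left as ``None`` are drawn from the seed.
    """

    mean_rr: float = 560.0          # ms; ~107 bpm canine sleep preset
    a_hf: float = 0.12              # respiratory (vagal) modulation depth
    f_hf: float = 0.30              # Hz, respiratory frequency
    a_lf: float = 0.05              # LF (Mayer-wave) modulation depth
    f_lf: float = 0.09              # Hz
    noise_sd: float = 0.02          # broadband modulation SD
    duration: float = 8 * 3600.0    # s
    sympatho_shift: float = 0.0     # 0 = vagal-dominant, 1 = full shift
    phase_hf: float | None = None   # rad; None -> random
    phase_lf: float | None = None
    record_start_clock: str = "00:00"

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.a_hf, self.a_lf, self.noise_sd) < 0:
            raise ValueError("modulation amplitudes must be non-negative")
        if not 0 <= self.a_hf + self.a_lf + 3 * self.noise_sd < 1:
            raise ValueError("a_hf + a_lf + 3*noise_sd must lie in [0, 1) "
                             "so the instantaneous rate stays positive")
        if not 0 <= self.sympatho_shift <= 1:
            raise ValueError("sympatho_shift must lie in [0, 1]")
        parse_clock(self.record_start_clock)

    def shifted(self) -> "AutonomicConfig":
        """Apply the sympathovagal shift, returning an equivalent config with
        ``sympatho_shift = 0`` and rescaled rate parameters."""
        rho = self.sympatho_shift
        if rho == 0:
            return self
        return dataclasses.replace(
            self,
            mean_rr=self.mean_rr * (1 - SHIFT_MEAN_RR * rho),
            a_hf=self.a_hf * (1 - SHIFT_A_HF * rho),
            a_lf=self.a_lf * (1 + SHIFT_A_LF * rho),
            sympatho_shift=0.0,
        )


@dataclass(frozen=True)
class ArtifactConfig:
    """Contamination model: premature (ectopic) and dropped (missed) beats."""

    ectopic_rate: float = 0.01      # per-beat probability of a premature beat
    missed_rate: float = 0.0        # per-beat probability of a dropped beat
    prematurity: float = 0.4        # fraction of the local RR the ectopic is early

    def __post_init__(self) -> None:
        for name in ("ectopic_rate", "missed_rate"):
            if not 0 <= getattr(self, name) <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2]")
        if not 0 < self.prematurity < 0.9:
            raise ValueError("prematurity must lie in (0, 0.9)")


def _smoothed_noise(rng: np.random.Generator, n: int, sd: float, dt: float) -> np.ndarray:
    """Gaussian white noise, moving-average smoothed, rescaled to SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    window = max(int(round(NOISE_SMOOTH_S / dt)), 1)
    eta = uniform_filter1d(rng.standard_normal(n), size=window, mode="reflect")
    scale = eta.std()
    if scale > 0:
        eta *= sd / scale
    return eta


def generate_beats(config: AutonomicConfig, seed) -> BeatSeries:
    """Simulate beat times from the IPFM model.

    ``seed`` fixes all randomness (phases when unset, and the noise path);
    it may be an int, a ``SeedSequence`` or a ``Generator``.
    """
    cfg = config.shifted()
    rng = np.random.default_rng(seed)
    # Phases are drawn before the noise path so that setting them explicitly
    # does not change the noise realisation for a given seed.
    phase_lf = rng.uniform(0, 2 * np.pi) if cfg.phase_lf is None else cfg.phase_lf
    phase_hf = rng.uniform(0, 2 * np.pi) if cfg.phase_hf is None else cfg.phase_hf

    dt = IPFM_GRID_DT
    n = int(np.floor(cfg.duration / dt)) + 1
    t = np.arange(n) * dt
    mod = np.zeros(n)
    if cfg.a_lf:
        mod += cfg.a_lf * np.sin(2 * np.pi * cfg.f_lf * t + phase_lf)
    if cfg.a_hf:
        mod += cfg.a_hf * np.sin(2 * np.pi * cfg.f_hf * t + phase_hf)
    mod += _smoothed_noise(rng, n, cfg.noise_sd, dt)

    rate = (1000.0 / cfg.mean_rr) * (1.0 + mod)  # beats per second
    if rate.min() <= 0:
        raise ValueError("rejected configuration: instantaneous rate is not "
                         "positive everywhere on the integration grid")

    phi = cumulative_trapezoid(rate, dx=dt, initial=0.0)
    # Tolerate float rounding at the record end: a crossing landing within
    # ~1e-9 beats of the final grid node still counts.
    kmax = int(np.floor(phi[-1] + 1e-9))
    ks = np.arange(1, kmax + 1, dtype=float)
    idx = np.minimum(np.searchsorted(phi, ks), len(phi) - 1)  # idx >= 1
    lo = phi[idx - 1]
    times = t[idx - 1] + (ks - lo) / (phi[idx] - lo) * dt
    labels = np.array(["normal"] * len(times), dtype=object)
    return BeatSeries(times, labels, record_start_clock=cfg.record_start_clock)


def inject_artifacts(beats: BeatSeries, cfg: ArtifactConfig, seed) -> BeatSeries:
    """Contaminate a beat series with premature (ectopic) and missed beats.

    Each beat is independently dropped with probability ``missed_rate``, or
    else shifted earlier by ``prematurity`` times the preceding RR interval
    and relabelled ``ectopic`` with probability ``ectopic_rate``.  Ground
    truth is retained in the labels.  A perturbation that would break strict
    time ordering is skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(beats)
    u = rng.random((n, 2))
    times: list[float] = []
    labels: list[str] = []
    for i in range(n):
        if u[i, 0] < cfg.missed_rate:
            continue
        t_i = float(beats.times[i])
        lab = beats.labels[i]
        if u[i, 1] < cfg.ectopic_rate and i > 0:
            shifted = t_i - cfg.prematurity * (beats.times[i] - beats.times[i - 1])
            if not times or shifted > times[-1]:
                t_i, lab = shifted, "ectopic"
        if times and t_i <= times[-1]:
            continue  # original position collides with a prior perturbation
        times.append(t_i)
        labels.append(lab)
    return BeatSeries(np.asarray(times), np.asarray(labels, dtype=object),
                      record_start_clock=beats.record_start_clock)


def generate_cohort(
    pre_cfg: AutonomicConfig,
    shift: float,
    n_subjects: int,
    seed,
) -> list[tuple[BeatSeries, BeatSeries]]:
    """Simulate a paired Pre/Post cohort.

    Each subject draws mild inter-individual jitter (5% relative SD on mean
    RR and both modulation amplitudes), then is simulated once with
    ``sympatho_shift = 0`` (Pre) and once with ``sympatho_shift = shift``
    (Post), with distinct sub-seeds so noise paths differ.
    """
    if n_subjects < 2:
        raise ValueError("a paired cohort needs at least 2 subjects")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cohort: list[tuple[BeatSeries, BeatSeries]] = []
    for child in ss.spawn(n_subjects):
        jitter_seed, pre_seed, post_seed = child.spawn(3)
        jrng = np.random.default_rng(jitter_seed)
        j = 1.0 + 0.05 * jrng.standard_normal(3)
        j = np.clip(j, 0.7, 1.3)
        subj = dataclasses.replace(
            pre_cfg,
            mean_rr=pre_cfg.mean_rr * j[0],
            a_hf=pre_cfg.a_hf * j[1],
            a_lf=pre_cfg.a_lf * j[2],
        )
        pre = generate_beats(dataclasses.replace(subj, sympatho_shift=0.0), pre_seed)
        post = generate_beats(dataclasses.replace(subj, sympatho_shift=shift), post_seed)
        cohort.append((pre, post))
    return cohort
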