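"""Synthetic multi-participant ERP studies with known ground truth.

Each participant is simulated as a continuous multichannel recording composed
of additive sources chosen so that every preprocessing choice in the multiverse
has something to act on:

* 1/f ("pink") background noise — filtered white noise with spectral
  exponent ~= 1, the canonical EEG noise floor;
* slow drift — a cumulative random walk low-passed below 0.1 Hz, giving
  high-pass filtering / detrending / baseline correction a target;
* alpha-band (10 Hz) oscillations with a slowly varying envelope, stronger
  over posterior sites — a target for low-pass filter choices;
* line noise at the mains frequency;
* event-locked ERP components with class-dependent amplitudes (the planted,
  decodable condition effect);
* ocular artifacts (blinks and saccades) projected from periocular sources
  with frontal scalp topographies — a target for EOG-correlation ICA;
* muscle bursts (band-limited > 15 Hz noise) at peripheral channels — a
  target for spectral-slope/peripherality ICA.

Trial-wise artifact occurrence can covary with the condition label at a
configurable point-biserial correlation rho, implemented through a thresholded
Gaussian copula: a latent bivariate normal links the class indicator and the
artifact indicator, with the latent correlation solved numerically so that the
binary-binary (phi) correlation matches rho.  This emulates condition-locked
involuntary eye movements, the mechanism by which artifact correction can
*reduce* apparent decoding performance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal, stats

from .containers import (
    ContinuousRecording,
    EOG_SOURCE_LAYOUT,
    LAYOUT_POS,
    SCALP_LAYOUT,
    channel_positions,
)
from .seeding import child_rng

__all__ = [
    "ERPComponent", "ArtifactSpec", "SynthConfig", "GroundTruth",
    "default_config", "generate_recording", "generate_study",
    "generate_null_study", "events_to_tsv", "latent_copula_correlation",
]

REQUIRED_CHANNELS = ("Cz", "Fp2", "P9", "P10",
                     "HEOG_left", "HEOG_right", "VEOG_lower")


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass
class ERPComponent:
    """One event-locked ERP component with class-dependent amplitude.

    The waveform is a Gaussian bump ``amp * exp(-(t - latency)^2 / (2 width^2))``
    projected onto the scalp through a sparse per-channel topography.
    """

    topography: dict[str, float]
    latency: float              # s after event onset
    width: float                # Gaussian SD, s
    amplitudes: tuple[float, float]   # microvolts per class (class 0, class 1)


@dataclass
class ArtifactSpec:
    """Trial-locked artifact generator settings.

    ``rate`` is the per-trial occurrence probability; ``class_cov`` the target
    point-biserial correlation between occurrence and the condition label.
    """

    rate: float = 0.0
    amplitude: float = 0.0      # microvolts at the strongest site
    class_cov: float = 0.0      # rho in [-1, 1]
    band: tuple[float, float] = (20.0, 60.0)   # muscle burst band, Hz

    def __post_init__(self) -> None:
        if not -1.0 <= self.class_cov <= 1.0:
            raise ConfigError("artifact class covariance must be in [-1, 1]")
        if self.rate < 0 or self.rate > 1:
            raise ConfigError("artifact rate must be a probability")
        if self.amplitude < 0:
            raise ConfigError("artifact amplitude must be >= 0")


@dataclass
class SynthConfig:
    """Full description of a synthetic ERP study."""

    n_participants: int = 20
    n_trials: tuple[int, int] = (100, 100)      # per class
    sfreq: float = 128.0
    channel_names: list[str] = field(
        default_factory=lambda: list(SCALP_LAYOUT) + list(EOG_SOURCE_LAYOUT))
    epoch_window: tuple[float, float] = (-0.4, 0.8)
    erp_components: list[ERPComponent] = field(default_factory=list)
    artifact_ocular: ArtifactSpec = field(default_factory=ArtifactSpec)
    artifact_muscle: ArtifactSpec = field(default_factory=ArtifactSpec)
    drift_sd: float = 0.1       # random-walk step SD, microvolts
    alpha_amp: float = 4.0      # microvolts
    line_noise: tuple[float, float] = (50.0, 2.0)   # Hz, microvolts
    noise_sd: float = 4.0       # 1/f background SD, microvolts
    trial_spacing: float = 1.5  # s between consecutive events
    participant_effect_sd: float = 0.3   # between-participant amplitude CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ConfigError("sfreq must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ConfigError("epoch window must have t_min < t_max")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_names]
        if missing:
            raise ConfigError(f"channel layout missing required channels: {missing}")
        if min(self.n_trials) < 1:
            raise ConfigError("need at least one trial per class")
        for amp in (self.alpha_amp, self.noise_sd, self.drift_sd,
                    self.line_noise[1]):
            if amp < 0:
                raise ConfigError("amplitudes must be >= 0")
        if self.trial_spacing < self.epoch_window[1] - self.epoch_window[0]:
            raise ConfigError("trial spacing shorter than the epoch window")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["erp_components"] = [
            ERPComponent(topography=dict(c["topography"]),
                         latency=float(c["latency"]), width=float(c["width"]),
                         amplitudes=tuple(c["amplitudes"]))
            for c in d.get("erp_components", [])]
        for key in ("artifact_ocular", "artifact_muscle"):
            if key in d and isinstance(d[key], dict):
                a = dict(d[key])
                a["band"] = tuple(a.get("band", (20.0, 60.0)))
                d[key] = ArtifactSpec(**a)
        for key in ("n_trials", "epoch_window", "line_noise"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What was planted: effect location and realized artifact covariances."""

    effect_window: tuple[float, float]
    effect_channels: list[str]
    class_means: np.ndarray      # (2, n_channels, n_epoch_times), noiseless
    epoch_times: np.ndarray
    realized_class_cov: dict[str, float]


def default_config(**overrides) -> SynthConfig:
    """The package's reference study: 20 participants, two posterior ERP
    components with a 2-3 microvolt class difference, condition-covarying
    blinks and muscle bursts, and the full set of background nuisances."""
    components = [
        ERPComponent(
            topography={"P7": 0.8, "P8": 1.0, "O1": 0.5, "O2": 0.6, "Pz": 0.3},
            latency=0.17, width=0.05, amplitudes=(2.0, 4.5)),
        ERPComponent(
            topography={"Pz": 1.0, "CPz": 0.8, "P3": 0.5, "P4": 0.5, "Cz": 0.4},
            latency=0.40, width=0.12, amplitudes=(2.5, 4.5)),
    ]
    cfg = dict(
        erp_components=components,
        artifact_ocular=ArtifactSpec(rate=0.25, amplitude=80.0, class_cov=0.3),
        artifact_muscle=ArtifactSpec(rate=0.2, amplitude=20.0, class_cov=0.2,
                                     band=(20.0, 60.0)),
    )
    cfg.update(overrides)
    return SynthConfig(**cfg)


# ---------------------------------------------------------------------------
# Thresholded Gaussian copula for artifact/class covariance
# ---------------------------------------------------------------------------

def _phi_from_latent(r: float, zq: float, zp: float, q: float, p: float) -> float:
    """Phi (binary-binary Pearson) correlation implied by latent correlation r."""
    if abs(r) >= 1.0:
        r = np.sign(r) * 0.999999
    p11 = stats.multivariate_normal.cdf(
        [-zq, -zp], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    # p11 = P(class=1, artifact=1) with thresholds: indicator = latent > z
    denom = np.sqrt(q * (1 - q) * p * (1 - p))
    return (p11 - q * p) / denom


def latent_copula_correlation(rho: float, q: float, p: float) -> float:
    """Solve for the latent bivariate-normal correlation giving phi == rho.

    ``q``: class-1 probability, ``p``: artifact occurrence probability.  If the
    requested rho exceeds the Frechet bound attainable for these margins, the
    latent correlation saturates at +-0.999.
    """
    if rho == 0.0 or p in (0.0, 1.0) or q in (0.0, 1.0):
        return 0.0
    zq = stats.norm.ppf(1 - q)
    zp = stats.norm.ppf(1 - p)

    def f(r):
        return _phi_from_latent(r, zq, zp, q, p) - rho

    lo, hi = -0.999, 0.999
    flo, fhi = f(lo), f(hi)
    if flo > 0:
        return lo
    if fhi < 0:
        return hi
    from scipy.optimize import brentq
    return float(brentq(f, lo, hi, xtol=1e-6))


def _draw_artifact_occurrence(rng: np.random.Generator, labels: np.ndarray,
                              spec: ArtifactSpec) -> np.ndarray:
    """Trial-wise artifact indicator correlated with class via the copula.

    The class latent is drawn from the appropriate truncated normal given the
    (fixed, configured) label of each trial; the artifact latent is then the
    correlated Gaussian thresholded at the rate quantile.
    """
    n = labels.size
    if spec.rate <= 0 or spec.amplitude <= 0:
        return np.zeros(n, dtype=bool)
    q = labels.mean()
    if q in (0.0, 1.0):
        return rng.random(n) < spec.rate
    r = latent_copula_correlation(spec.class_cov, q, spec.rate)
    zq = stats.norm.ppf(1 - q)
    zp = stats.norm.ppf(1 - spec.rate)
    # class latent conditional on label: truncated above/below the threshold
    u = np.empty(n)
    n1 = int(labels.sum())
    u[labels == 1] = stats.truncnorm.rvs(zq, np.inf, size=n1, random_state=rng)
    u[labels == 0] = stats.truncnorm.rvs(-np.inf, zq, size=n - n1,
                                         random_state=rng)
    v = r * u + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    return v > zp


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(rng, n_ch: int, n_samp: int, exponent: float = 1.0) -> np.ndarray:
    """Unit-SD 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samp, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _drift(rng, n_ch: int, n_samp: int, step_sd: float, sfreq: float) -> np.ndarray:
    """Cumulative random walk low-passed below 0.1 Hz."""
    if step_sd <= 0:
        return np.zeros((n_ch, n_samp))
    walk = np.cumsum(rng.normal(0.0, step_sd, (n_ch, n_samp)), axis=1)
    sos = signal.butter(2, 0.1, btype="low", fs=sfreq, output="sos")
    out = signal.sosfiltfilt(sos, walk, axis=1)
    return out - out.mean(axis=1, keepdims=True)


def _alpha(rng, pos: np.ndarray, n_samp: int, sfreq: float, amp: float) -> np.ndarray:
    """10 Hz oscillation with a slow envelope, stronger posteriorly."""
    n_ch = pos.shape[0]
    if amp <= 0:
        return np.zeros((n_ch, n_samp))
    t = np.arange(n_samp) / sfreq
    sos = signal.butter(2, 1.0, btype="low", fs=sfreq, output="sos")
    env = np.abs(signal.sosfiltfilt(sos, rng.standard_normal((n_ch, n_samp)),
                                    axis=1))
    env /= env.mean(axis=1, keepdims=True) + 1e-12
    phase = rng.uniform(0, 2 * np.pi, (n_ch, 1))
    posterior = 0.4 + 0.6 * np.clip(-pos[:, 1], 0.0, 1.0)[:, None]
    return amp * posterior * env * np.sin(2 * np.pi * 10.0 * t + phase)


def _blink_kernel(sfreq: float) -> np.ndarray:
    """Smooth positive ~300 ms deflection (half sine)."""
    n = int(round(0.3 * sfreq))
    return np.sin(np.pi * np.arange(n) / n)


def _ocular_topography(channel_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(blink weights, saccade weights) per channel.

    Blinks: corneo-retinal dipole — positive frontal scalp, negative below the
    eyes, decaying with distance from the eye centre.  Saccades: lateral step
    pattern, opposite-sign at the two horizontal EOG sources.
    """
    pos = channel_positions(channel_names)
    eye = np.array([0.0, 1.03])
    d = np.linalg.norm(pos - eye, axis=1)
    blink = np.exp(-(d / 0.55) ** 2)
    sacc = 0.35 * pos[:, 0] * np.exp(-((pos[:, 1] - 1.0) / 0.9) ** 2)
    for i, name in enumerate(channel_names):
        if name == "VEOG_lower":
            blink[i] = -0.8          # below the eye: inverted polarity
            sacc[i] = 0.0
        elif name == "HEOG_left":
            blink[i] = 0.25
            sacc[i] = 1.0
        elif name == "HEOG_right":
            blink[i] = 0.25
            sacc[i] = -1.0
    return blink, sacc


_PERIPHERAL = ("T7", "T8", "F7", "F8", "P7", "P8", "P9", "P10")


def _muscle_topography(rng, channel_names: list[str]) -> np.ndarray:
    """Sharp, peripheral topography: one temporal focus plus weak jitter."""
    w = np.zeros(len(channel_names))
    present = [c for c in _PERIPHERAL if c in channel_names]
    focus = present[rng.integers(len(present))]
    fpos = np.array(LAYOUT_POS[focus])
    for i, name in enumerate(channel_names):
        if name in present:
            d = np.linalg.norm(np.array(LAYOUT_POS[name]) - fpos)
            w[i] = np.exp(-(d / 0.35) ** 2)
    w += 0.05 * rng.random(len(channel_names)) * (w > 0)
    return w


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _event_schedule(cfg: SynthConfig, rng) -> tuple[np.ndarray, np.ndarray, int]:
    """Event sample indices, shuffled labels, total recording length."""
    n_total = int(sum(cfg.n_trials))
    labels = np.concatenate([np.zeros(cfg.n_trials[0], int),
                             np.ones(cfg.n_trials[1], int)])
    rng.shuffle(labels)
    pad = max(1.0, -cfg.epoch_window[0] + 0.5)
    onsets_s = pad + np.arange(n_total) * cfg.trial_spacing
    onsets_s += rng.uniform(-0.05, 0.05, n_total)
    samples = np.round(onsets_s * cfg.sfreq).astype(int)
    n_samp = int(samples[-1] + (cfg.epoch_window[1] + 1.0) * cfg.sfreq)
    return samples, labels, n_samp


def _add_bump(data: np.ndarray, weights: np.ndarray, kernel: np.ndarray,
              start: int) -> None:
    """Add ``weights[:, None] * kernel`` into data at sample ``start``."""
    n_samp = data.shape[1]
    k0 = max(0, -start)
    k1 = min(kernel.size, n_samp - start)
    if k1 <= k0:
        return
    data[:, start + k0:start + k1] += np.outer(weights, kernel[k0:k1])


def generate_recording(config: SynthConfig, participant_id: int,
                       _return_occurrence: bool = False):
    """Simulate one participant's continuous recording.

    Deterministic given ``(config.seed, participant_id)``.
    """
    if participant_id >= config.n_participants:
        raise ConfigError("participant_id exceeds n_participants")
    rng = child_rng(config.seed, "recording", participant_id)
    names = list(config.channel_names)
    pos = channel_positions(names)
    n_ch = len(names)
    samples, labels, n_samp = _event_schedule(config, rng)
    sf = config.sfreq

    data = config.noise_sd * _pink_noise(rng, n_ch, n_samp)
    data += _drift(rng, n_ch, n_samp, config.drift_sd, sf)
    data += _alpha(rng, pos, n_samp, sf, config.alpha_amp)
    if config.line_noise[1] > 0:
        t = np.arange(n_samp) / sf
        gains = 1.0 + 0.2 * rng.standard_normal((n_ch, 1))
        data += config.line_noise[1] * gains * np.sin(
            2 * np.pi * config.line_noise[0] * t + rng.uniform(0, 2 * np.pi))

    # event-locked ERP components with class-dependent amplitude; every
    # participant scales all component amplitudes by an individual factor
    # (real ERP effect sizes vary substantially between people — without
    # this, group t statistics become implausibly large at moderate n)
    gain = 1.0
    if config.participant_effect_sd > 0:
        gain = max(1.0 + config.participant_effect_sd
                   * rng.standard_normal(), 0.2)
    for comp in config.erp_components:
        w = np.array([comp.topography.get(nm, 0.0) for nm in names])
        half = int(round(4 * comp.width * sf))
        tk = (np.arange(2 * half + 1) - half) / sf
        kernel = np.exp(-(tk - 0.0) ** 2 / (2 * comp.width ** 2))
        for s, lab in zip(samples, labels):
            amp = gain * comp.amplitudes[lab]
            start = int(s + round(comp.latency * sf)) - half
            _add_bump(data, w * amp, kernel, start)

    # ocular artifacts: blinks (70%) and saccades (30%), class-covarying
    occ_ocular = _draw_artifact_occurrence(rng, labels, config.artifact_ocular)
    blink_w, sacc_w = _ocular_topography(names)
    bk = _blink_kernel(sf)
    for i in np.flatnonzero(occ_ocular):
        onset = samples[i] + int(rng.uniform(-0.1, 0.4) * sf)
        if rng.random() < 0.7:
            _add_bump(data, blink_w * config.artifact_ocular.amplitude, bk, onset)
        else:
            ramp = np.concatenate([np.linspace(0, 1, int(0.05 * sf)),
                                   np.ones(int(0.25 * sf))])
            sign = 1 if rng.random() < 0.5 else -1
            _add_bump(data, sacc_w * sign * config.artifact_ocular.amplitude,
                      ramp, onset)

    # muscle bursts: band-limited noise at a peripheral focus
    occ_muscle = _draw_artifact_occurrence(rng, labels, config.artifact_muscle)
    if occ_muscle.any():
        w = _muscle_topography(rng, names)
        lo, hi = config.artifact_muscle.band
        hi = min(hi, 0.45 * sf)
        sos = signal.butter(4, [lo, hi], btype="band", fs=sf, output="sos")
        n_burst = int(0.25 * sf)
        win = np.hanning(n_burst)
        for i in np.flatnonzero(occ_muscle):
            burst = signal.sosfilt(sos, rng.standard_normal(n_burst)) * win
            sd = burst.std()
            if sd > 0:
                burst *= config.artifact_muscle.amplitude / sd
            onset = samples[i] + int(rng.uniform(-0.1, 0.4) * sf)
            _add_bump(data, w, burst, onset)

    # EOG source channels: independent sensor noise on top of the generators
    for i, name in enumerate(names):
        if name in EOG_SOURCE_LAYOUT:
            data[i] += 2.0 * rng.standard_normal(n_samp)

    events = np.column_stack([samples, labels])
    rec = ContinuousRecording(data=data, sfreq=sf, channel_names=names,
                              events=events, participant_id=participant_id)
    if _return_occurrence:
        return rec, {"ocular": occ_ocular, "muscle": occ_muscle}
    return rec


def _noiseless_class_means(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = config.epoch_window
    n_times = int(round((t1 - t0) * config.sfreq)) + 1
    times = t0 + np.arange(n_times) / config.sfreq
    names = list(config.channel_names)
    means = np.zeros((2, len(names), n_times))
    for comp in config.erp_components:
        w = np.array([comp.topography.get(nm, 0.0) for nm in names])
        kern = np.exp(-(times - comp.latency) ** 2 / (2 * comp.width ** 2))
        for cls in (0, 1):
            means[cls] += comp.amplitudes[cls] * np.outer(w, kern)
    return means, times


def generate_study(config: SynthConfig):
    """One recording per participant, plus the planted ground truth."""
    if config.n_participants < 1:
        raise ConfigError("need at least one participant")
    recs, occ_all = [], {"ocular": [], "muscle": []}
    lab_all = []
    for pid in range(config.n_participants):
        rec, occ = generate_recording(config, pid, _return_occurrence=True)
        recs.append(rec)
        for k in occ_all:
            occ_all[k].append(occ[k])
        lab_all.append(rec.events[:, 1])
    labels = np.concatenate(lab_all)
    realized = {}
    for k, v in occ_all.items():
        occ = np.concatenate(v).astype(float)
        if occ.std() > 0 and labels.std() > 0:
            realized[k] = float(np.corrcoef(occ, labels)[0, 1])
        else:
            realized[k] = 0.0
    means, times = _noiseless_class_means(config)
    if config.erp_components:
        lat = [c.latency for c in config.erp_components]
        wid = [c.width for c in config.erp_components]
        window = (min(l - 2 * w for l, w in zip(lat, wid)),
                  max(l + 2 * w for l, w in zip(lat, wid)))
        chans = sorted({ch for c in config.erp_components
                        for ch, wt in c.topography.items() if wt != 0})
    else:
        window, chans = (0.0, 0.0), []
    gt = GroundTruth(effect_window=window, effect_channels=chans,
                     class_means=means, epoch_times=times,
                     realized_class_cov=realized)
    return recs, gt


def null_config(config: SynthConfig) -> SynthConfig:
    """Copy of ``config`` with all class effects and covariances removed."""
    comps = [ERPComponent(topography=dict(c.topography), latency=c.latency,
                          width=c.width,
                          amplitudes=(float(np.mean(c.amplitudes)),) * 2)
             for c in config.erp_components]
    oc = dataclasses.replace(config.artifact_ocular, class_cov=0.0)
    mu = dataclasses.replace(config.artifact_muscle, class_cov=0.0)
    return dataclasses.replace(config, erp_components=comps,
                               artifact_ocular=oc, artifact_muscle=mu)


def generate_null_study(config: SynthConfig) -> list[ContinuousRecording]:
    """As :func:`generate_study` but with zero class effect everywhere.

    Labels remain randomly assigned to trials; every condition-dependent
    amplitude is replaced by its class mean and artifact/class covariances are
    forced to zero.
    """
    recs, _ = generate_study(null_config(config))
    return recs


def events_to_tsv(recording: ContinuousRecording, path=None):
    """Export the event table as a BIDS-style events table (TSV).

    Columns: onset (s), duration (0.0), trial_type (class label).  Returns the
    DataFrame; writes to ``path`` if given.
    """
    import pandas as pd

    df = pd.DataFrame({
        "onset": recording.events[:, 0] / recording.sfreq,
        "duration": 0.0,
        "trial_type": recording.events[:, 1],
    })
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
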