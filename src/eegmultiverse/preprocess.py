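"""Preprocessing operators for the multiverse.

Implements every preprocessing step that can be varied in a forking path, in
the main step order: ocular ICA -> muscle ICA -> filtering -> referencing ->
epoching -> detrending -> baseline correction -> peak-to-peak rejection.

Conventions
-----------
* Filters are one-pass, zero-phase, non-causal linear-phase FIR filters
  designed with a Hamming window (0.0194 passband ripple, 53 dB stopband
  attenuation); the cutoff is the half-amplitude (-6 dB) point.
* EOG bookkeeping channels are filtered like scalp channels but excluded from
  referencing, ICA estimation, rejection and interpolation.
* Epoch time axes are inclusive of both window endpoints; sample 0 is the
  event onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import (
    ChannelError,
    ContinuousRecording,
    EpochSet,
    PathInvalidError,
    channel_positions,
)
from .seeding import child_seed

__all__ = [
    "FilterSpec", "ICAReport", "RejectionLog", "ParameterError",
    "derive_bipolar_eog", "design_fir", "fir_filter", "rereference",
    "epoch", "detrend_linear", "baseline_correct",
    "correct_ocular", "correct_muscle", "reject_peak_to_peak",
]


class ParameterError(ValueError):
    """Invalid operator parameter (e.g. cutoff above Nyquist)."""


# ---------------------------------------------------------------------------
# Bipolar EOG derivation
# ---------------------------------------------------------------------------

def derive_bipolar_eog(recording: ContinuousRecording) -> ContinuousRecording:
    """Derive bipolar HEOG and VEOG channels.

    HEOG = left horizontal EOG - right horizontal EOG;
    VEOG = lower vertical EOG - Fp2.  The two derived channels are appended
    and marked non-scalp; the source channels are dropped.
    """
    idx = {name: recording.channel_index(name)
           for name in ("HEOG_left", "HEOG_right", "VEOG_lower", "Fp2")}
    heog = recording.data[idx["HEOG_left"]] - recording.data[idx["HEOG_right"]]
    veog = recording.data[idx["VEOG_lower"]] - recording.data[idx["Fp2"]]
    keep = [i for i, n in enumerate(recording.channel_names)
            if n not in ("HEOG_left", "HEOG_right", "VEOG_lower")]
    data = np.vstack([recording.data[keep], heog[None], veog[None]])
    names = [recording.channel_names[i] for i in keep] + ["HEOG", "VEOG"]
    return ContinuousRecording(data=data, sfreq=recording.sfreq,
                               channel_names=names,
                               events=recording.events.copy(),
                               participant_id=recording.participant_id)


# ---------------------------------------------------------------------------
# FIR filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """Zero-phase one-pass Hamming-window FIR band-pass/HPF/LPF design.

    Transition bandwidths follow the usual automatic rule:
    ``min(max(0.25 * cutoff, 2 Hz), cutoff)`` for the high-pass edge and
    ``min(max(0.25 * cutoff, 2 Hz), nyquist - cutoff)`` for the low-pass edge.
    """

    l_freq: float | None = None    # high-pass cutoff, Hz
    h_freq: float | None = None    # low-pass cutoff, Hz
    window: str = "hamming"
    passband_ripple: float = 0.0194
    stopband_atten_db: float = 53.0

    def __post_init__(self) -> None:
        if self.l_freq is not None and self.l_freq <= 0:
            raise ParameterError("l_freq must be > 0")
        if self.h_freq is not None and self.h_freq <= 0:
            raise ParameterError("h_freq must be > 0")
        if (self.l_freq is not None and self.h_freq is not None
                and self.l_freq >= self.h_freq):
            raise ParameterError("band-pass requires l_freq < h_freq")

    @property
    def is_identity(self) -> bool:
        return self.l_freq is None and self.h_freq is None


def _transition_bandwidth(cutoff: float, nyq: float, highpass: bool) -> float:
    tb = max(0.25 * cutoff, 2.0)
    return min(tb, cutoff) if highpass else min(tb, nyq - cutoff)


def design_fir(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Design the odd-length linear-phase FIR taps for ``spec``.

    Length follows the Hamming-window rule ``n = 3.3 / transition_bw`` seconds,
    rounded up to an odd number of taps.
    """
    nyq = sfreq / 2.0
    for cutoff in (spec.l_freq, spec.h_freq):
        if cutoff is not None and cutoff >= nyq:
            raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    if spec.is_identity:
        return np.array([1.0])
    tbs = []
    if spec.l_freq is not None:
        tbs.append(_transition_bandwidth(spec.l_freq, nyq, highpass=True))
    if spec.h_freq is not None:
        tbs.append(_transition_bandwidth(spec.h_freq, nyq, highpass=False))
    n = int(np.ceil(3.3 / min(tbs) * sfreq))
    n += (n + 1) % 2   # force odd length (type-I linear phase)
    # the configured cutoff is the passband edge; the -6 dB point sits half a
    # transition band outside it, so the stopband begins at cutoff -/+ tb
    if spec.l_freq is not None and spec.h_freq is not None:
        tb_l = _transition_bandwidth(spec.l_freq, nyq, highpass=True)
        tb_h = _transition_bandwidth(spec.h_freq, nyq, highpass=False)
        band = [spec.l_freq - tb_l / 2, spec.h_freq + tb_h / 2]
        taps = signal.firwin(n, band, window=spec.window,
                             pass_zero=False, fs=sfreq)
    elif spec.l_freq is not None:
        tb_l = _transition_bandwidth(spec.l_freq, nyq, highpass=True)
        taps = signal.firwin(n, spec.l_freq - tb_l / 2, window=spec.window,
                             pass_zero=False, fs=sfreq)
    else:
        tb_h = _transition_bandwidth(spec.h_freq, nyq, highpass=False)
        taps = signal.firwin(n, spec.h_freq + tb_h / 2, window=spec.window,
                             pass_zero=True, fs=sfreq)
    if spec.l_freq is not None:
        # firwin normalises high-pass gain at Nyquist, leaving a small DC
        # leak; shifting the symmetric response by the tap sum (via the
        # centre tap) nulls DC exactly at a sub-ripple passband cost
        taps[(taps.size - 1) // 2] -= taps.sum()
    return taps


def _filter_array(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply odd-length linear-phase taps once with zero net delay.

    Edges are reflect-padded by half the filter length before convolution so
    the full signal length is preserved without start-up transients wrapping.
    """
    if taps.size == 1:
        return data * taps[0]
    half = (taps.size - 1) // 2
    if data.shape[-1] <= taps.size:
        raise ParameterError("signal shorter than the filter length")
    pad = min(half, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)],
                    mode="reflect")
    out = signal.fftconvolve(padded, taps[None], mode="same", axes=-1)
    return out[..., pad:pad + data.shape[-1]]


def fir_filter(recording: ContinuousRecording,
               spec: FilterSpec) -> ContinuousRecording:
    """Filter all channels (scalp and EOG alike) with the designed FIR."""
    taps = design_fir(spec, recording.sfreq)
    out = recording.copy()
    out.data = _filter_array(out.data, taps)
    return out


# ---------------------------------------------------------------------------
# Referencing, epoching, detrending, baseline
# ---------------------------------------------------------------------------

def rereference(x, scheme: str):
    """Subtract a reference signal from every scalp channel.

    ``scheme`` is ``"Cz"`` (single channel), ``"P9P10"`` (near-mastoid pair
    average) or ``"average"`` (mean of all scalp channels).  EOG channels are
    left untouched.  Works on both continuous recordings and epoch sets.
    """
    out = x.copy()
    scalp = out.scalp_indices
    if isinstance(out, EpochSet):
        dat = out.data          # (trials, channels, time)
        ch_axis = 1
    else:
        dat = out.data[None]    # (1, channels, time)
        ch_axis = 1
    if scheme == "average":
        ref = dat[:, scalp].mean(axis=ch_axis, keepdims=True)
    elif scheme == "Cz":
        ref = dat[:, [out.channel_index("Cz")]]
    elif scheme == "P9P10":
        idx = [out.channel_index("P9"), out.channel_index("P10")]
        ref = dat[:, idx].mean(axis=ch_axis, keepdims=True)
    else:
        raise ParameterError(f"unknown reference scheme {scheme!r}")
    dat[:, scalp] = dat[:, scalp] - ref
    if not isinstance(out, EpochSet):
        out.data = dat[0]
    return out


def epoch(recording: ContinuousRecording,
          window: tuple[float, float]) -> EpochSet:
    """Cut one epoch per event; events too close to an edge are dropped.

    The time axis has ``round((t_max - t_min) * sfreq) + 1`` samples and both
    endpoints are included.
    """
    t_min, t_max = window
    if t_min >= t_max:
        raise ParameterError("epoch window must have t_min < t_max")
    if recording.events.size == 0:
        raise ParameterError("recording has no events")
    sf = recording.sfreq
    n_times = int(round((t_max - t_min) * sf)) + 1
    offset = int(round(t_min * sf))
    times = t_min + np.arange(n_times) / sf
    starts = recording.events[:, 0] + offset
    ok = (starts >= 0) & (starts + n_times <= recording.n_samples)
    if not ok.any():
        raise ParameterError("no events fit inside the recording")
    kept = np.flatnonzero(ok)
    data = np.stack([recording.data[:, s:s + n_times]
                     for s in starts[kept]])
    return EpochSet(data=data, labels=recording.events[kept, 1], times=times,
                    channel_names=list(recording.channel_names), sfreq=sf,
                    participant_id=recording.participant_id,
                    kept_trial_index=kept)


def detrend_linear(epochs: EpochSet) -> EpochSet:
    """Remove each trial x channel's least-squares line, keeping residuals."""
    if epochs.n_times < 2:
        raise ParameterError("detrending needs at least two time points")
    t = epochs.times
    G = np.column_stack([np.ones_like(t), t])             # (T, 2)
    proj = G @ np.linalg.pinv(G)                          # (T, T) hat matrix
    out = epochs.copy()
    out.data = out.data - out.data @ proj.T
    return out


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float]) -> EpochSet:
    """Subtract the mean over the baseline window per trial and channel."""
    t0, t1 = window
    if t0 >= t1:
        raise ParameterError("baseline window must have t0 < t1")
    eps = 0.5 / epochs.sfreq
    if t0 < epochs.times[0] - eps or t1 > epochs.times[-1] + eps:
        raise ParameterError("baseline window outside the epoch window")
    mask = (epochs.times >= t0 - eps) & (epochs.times <= t1 + eps)
    if not mask.any():
        raise ParameterError("baseline window contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# ICA-based artifact correction
# ---------------------------------------------------------------------------

@dataclass
class ICAReport:
    """Outcome of one ICA correction pass."""

    kind: str                       # "ocular" | "muscle"
    n_components: int
    flagged_components: list[int]
    scores: dict[str, np.ndarray]   # per-criterion score per component
    converged: bool
    seed: int
    status: str = "ok"              # "ok" | "not_converged"


def _fit_ica_on_highpassed(recording: ContinuousRecording, seed: int,
                           n_components: int, max_iter: int):
    """Fit FastICA on a 1 Hz high-passed copy of the scalp channels.

    Returns (unmixing W, mixing A, channel means, sources on the filtered
    copy, converged flag).  Sources of any other dataset with the same
    channels are ``W @ (X - mean)``.
    """
    from sklearn.decomposition import FastICA

    scalp = recording.scalp_indices
    hp = fir_filter(recording, FilterSpec(l_freq=1.0))
    X = hp.data[scalp].T                      # samples x channels
    n_components = min(n_components, len(scalp))
    ica = FastICA(n_components=n_components, max_iter=max_iter, tol=1e-4,
                  whiten="unit-variance", random_state=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S = ica.fit_transform(X)              # samples x comps
    # The strict fixed-point criterion rarely triggers on EEG-like data whose
    # background is Gaussian: the Gaussian subspace rotates freely without
    # affecting the non-Gaussian (artifact) components we flag.  The solution
    # is therefore usable whenever it is finite; a non-finite unmixing is a
    # genuine failure.
    converged = bool(np.isfinite(ica.components_).all()
                     and np.isfinite(ica.mixing_).all())
    W = ica.components_                       # comps x channels
    A = ica.mixing_                           # channels x comps
    mean = ica.mean_
    return W, A, mean, S.T, converged         # sources: comps x samples


def _remove_components(recording: ContinuousRecording, W, A, mean,
                       flagged: list[int]) -> ContinuousRecording:
    """Subtract flagged components from the *unfiltered* scalp data."""
    out = recording.copy()
    if not flagged:
        return out
    scalp = out.scalp_indices
    X = out.data[scalp] - mean[:, None]        # channels x samples
    S = W @ X                                  # comps x samples
    out.data[scalp] -= A[:, flagged] @ S[flagged]
    return out


def _adaptive_z_flag(scores: np.ndarray, threshold: float = 3.0) -> list[int]:
    """Iterative adaptive z-scoring: flag components whose score exceeds
    ``threshold`` SDs of the remaining (unflagged) scores, until stable."""
    flagged: set[int] = set()
    while True:
        rest = np.array([i for i in range(scores.size) if i not in flagged])
        if rest.size < 3:
            break
        mu, sd = scores[rest].mean(), scores[rest].std()
        if sd == 0:
            break
        new = {int(i) for i in rest if (scores[i] - mu) / sd > threshold}
        if not new:
            break
        flagged |= new
    return sorted(flagged)


def correct_ocular(recording: ContinuousRecording, seed: int,
                   n_components: int = 20, max_iter: int = 500,
                   z_threshold: float = 3.0):
    """Remove ocular ICA components identified by EOG correlation.

    ICA is fitted on a 1 Hz high-passed copy of the scalp channels; components
    whose absolute correlation with the (equally high-passed) bipolar HEOG or
    VEOG channel exceeds the adaptive z threshold are subtracted from the
    original unfiltered data.
    """
    for ch in ("HEOG", "VEOG"):
        recording.channel_index(ch)     # raises ChannelError if absent
    W, A, mean, S, converged = _fit_ica_on_highpassed(
        recording, seed, n_components, max_iter)
    if not converged:
        report = ICAReport(kind="ocular", n_components=W.shape[0],
                           flagged_components=[], scores={}, converged=False,
                           seed=seed, status="not_converged")
        return recording.copy(), report
    hp = fir_filter(recording, FilterSpec(l_freq=1.0))
    eog = np.vstack([hp.data[recording.channel_index("HEOG")],
                     hp.data[recording.channel_index("VEOG")]])
    n_comp = S.shape[0]
    corr = np.zeros((2, n_comp))
    for e in range(2):
        ec = eog[e] - eog[e].mean()
        esd = ec.std()
        for c in range(n_comp):
            sc = S[c] - S[c].mean()
            denom = esd * sc.std()
            corr[e, c] = 0.0 if denom == 0 else (ec @ sc) / (ec.size * denom)
    scores = np.abs(corr).max(axis=0)
    flagged = _adaptive_z_flag(scores, z_threshold)
    out = _remove_components(recording, W, A, mean, flagged)
    report = ICAReport(kind="ocular", n_components=n_comp,
                       flagged_components=flagged,
                       scores={"eog_correlation": scores}, converged=True,
                       seed=seed)
    return out, report


def _psd_loglog_slope(source: np.ndarray, sfreq: float,
                      fmin: float = 7.0, fmax: float = 45.0) -> float:
    nper = min(int(2 * sfreq), source.size)
    f, p = signal.welch(source, fs=sfreq, nperseg=nper)
    m = (f >= fmin) & (f <= fmax) & (p > 0)
    if m.sum() < 3:
        return 0.0
    coef = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)
    return float(coef[0])


def correct_muscle(recording: ContinuousRecording, seed: int,
                   n_components: int = 20, max_iter: int = 500,
                   combined_z_threshold: float = 1.0):
    """Remove muscle ICA components by spectral slope, peripherality and
    spatial smoothness.

    Each criterion is z-scored across components; a component is flagged when
    the mean z exceeds ``combined_z_threshold`` *and* its 7-45 Hz log-log
    spectral slope is positive (broadband high-frequency power rising with
    frequency, the opposite of the 1/f neural background).  Must be applied
    before any low-pass filter so the 7-45 Hz slope window exists.
    """
    if recording.sfreq <= 90.0:
        raise ParameterError("sfreq must exceed 90 Hz for the 7-45 Hz slope")
    W, A, mean, S, converged = _fit_ica_on_highpassed(
        recording, seed, n_components, max_iter)
    if not converged:
        report = ICAReport(kind="muscle", n_components=W.shape[0],
                           flagged_components=[], scores={}, converged=False,
                           seed=seed, status="not_converged")
        return recording.copy(), report
    n_comp = S.shape[0]
    scalp = recording.scalp_indices
    pos = channel_positions([recording.channel_names[i] for i in scalp])
    radius = np.linalg.norm(pos, axis=1)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    wgt = np.exp(-d2 / 0.2)
    np.fill_diagonal(wgt, 0.0)

    slopes = np.array([_psd_loglog_slope(S[c], recording.sfreq)
                       for c in range(n_comp)])
    periph = np.zeros(n_comp)
    smooth = np.zeros(n_comp)
    for c in range(n_comp):
        a = A[:, c]
        aa = np.abs(a)
        periph[c] = (aa * radius).sum() / (aa.sum() + 1e-12)
        # Moran-like spatial autocorrelation of the topography
        ac = a - a.mean()
        denom = (ac ** 2).sum() * wgt.sum() + 1e-12
        smooth[c] = len(a) * (wgt * np.outer(ac, ac)).sum() / denom

    def z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    combined = (z(slopes) + z(periph) + z(-smooth)) / 3.0
    flagged = sorted(int(c) for c in range(n_comp)
                     if combined[c] > combined_z_threshold and slopes[c] > 0)
    out = _remove_components(recording, W, A, mean, flagged)
    report = ICAReport(kind="muscle", n_components=n_comp,
                       flagged_components=flagged,
                       scores={"slope": slopes, "peripherality": periph,
                               "smoothness": smooth, "combined_z": combined},
                       converged=True, seed=seed)
    return out, report


# ---------------------------------------------------------------------------
# Peak-to-peak rejection (autoreject-style)
# ---------------------------------------------------------------------------

@dataclass
class RejectionLog:
    """Outcome of peak-to-peak rejection for one epoch set."""

    mode: str                                # "interpolate" | "reject"
    thresholds: dict[str, float]             # per scalp channel, microvolts
    decisions: list[dict] = field(default_factory=list)
    consensus: float | None = None
    n_interpolate: int | None = None
    dropped_trials: list[int] = field(default_factory=list)


def _cv_thresholds(ptp_fit: np.ndarray, data_fit: np.ndarray,
                   rng: np.random.Generator, n_folds: int = 5,
                   n_candidates: int = 15) -> np.ndarray:
    """Per-channel peak-to-peak thresholds by 5-fold cross-validation.

    For each candidate threshold the *average signal* of the sub-threshold
    training trials is compared (RMSE over time) with the median signal of
    the validation trials — the robust reference that artifact trials cannot
    distort; the candidate minimising the CV error wins.  Candidates span the
    upper quantile range and always include a keep-everything threshold, so
    clean data selects no rejection at all.
    """
    n_trials, n_ch = ptp_fit.shape
    qs = np.linspace(0.3, 1.0, n_candidates)
    cands = np.quantile(ptp_fit, qs, axis=0)            # (n_cand, n_ch)
    cands = np.vstack([cands, ptp_fit.max(axis=0) * 1.1 + 1e-9])
    order = rng.permutation(n_trials)
    folds = np.array_split(order, n_folds)
    err = np.zeros((cands.shape[0], n_ch, n_folds))
    for k in range(n_folds):
        val = folds[k]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        med_val = np.median(data_fit[val], axis=0)       # (n_ch, n_times)
        for ci in range(cands.shape[0]):
            keep = ptp_fit[train] <= cands[ci][None, :]  # (n_train, n_ch)
            n_keep = np.maximum(keep.sum(axis=0), 1)
            mean_keep = np.einsum("nc,nct->ct", keep.astype(float),
                                  data_fit[train]) / n_keep[:, None]
            mean_keep[keep.sum(axis=0) == 0] = np.inf
            err[ci, :, k] = np.sqrt(((mean_keep - med_val) ** 2).mean(axis=1))
    mean_err = err.mean(axis=2)
    se_err = err.std(axis=2, ddof=1) / np.sqrt(n_folds)
    # 1-SE parsimony rule: the largest (least interventionist) threshold
    # whose CV error is within one SE of the per-channel minimum, so clean
    # data selects no rejection at all
    best = mean_err.argmin(axis=0)
    ch_idx = np.arange(n_ch)
    limit = mean_err[best, ch_idx] + se_err[best, ch_idx]
    chosen = np.array([np.flatnonzero(mean_err[:, c] <= limit[c]).max()
                       for c in ch_idx])
    return cands[chosen, ch_idx]


def _neighbor_graph(names: list[str], k: int = 4):
    pos = channel_positions(names)
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    nb_idx = np.argsort(d, axis=1)[:, :k]
    nb_w = 1.0 / (d[np.arange(len(names))[:, None], nb_idx] + 1e-9)
    return nb_idx, nb_w


def _interpolate_trial(trial: np.ndarray, bad: np.ndarray,
                       nb_idx: np.ndarray, nb_w: np.ndarray) -> None:
    """Replace bad channels in-place with inverse-distance neighbor averages."""
    source = trial.copy()
    for ch in np.flatnonzero(bad):
        nbs = nb_idx[ch]
        w = nb_w[ch] * (~bad[nbs])
        if w.sum() == 0:        # all neighbors bad: fall back to all good
            good = np.flatnonzero(~bad)
            if good.size == 0:
                continue
            trial[ch] = source[good].mean(axis=0)
        else:
            trial[ch] = (w[:, None] * source[nbs]).sum(axis=0) / w.sum()


def reject_peak_to_peak(epochs: EpochSet, mode: str, seed: int,
                        consensus=(0.2, 0.4, 0.6, 0.8),
                        n_interpolate=(4, 8, 16, 32),
                        fit_fraction: float = 0.25,
                        min_trials_per_class: int = 10):
    """Autoreject-style data-driven peak-to-peak artifact correction.

    Per-channel thresholds are cross-validated on a ``fit_fraction`` subset of
    the epochs.  In *interpolate* mode every bad channel x trial entry is
    replaced by neighbor interpolation and the trial count is unchanged.  In
    *reject* mode a grid search over ``consensus`` x ``n_interpolate`` decides,
    per trial, between interpolating the worst channels and dropping the
    trial.  If a class falls below ``min_trials_per_class`` surviving trials,
    the forking path is invalid for this participant
    (:class:`~eegmultiverse.containers.PathInvalidError`).
    """
    if mode not in ("interpolate", "reject"):
        raise ParameterError(f"unknown rejection mode {mode!r}")
    rng = np.random.default_rng(child_seed(seed, "autoreject", mode))
    scalp = epochs.scalp_indices
    names = [epochs.channel_names[i] for i in scalp]
    ptp = np.ptp(epochs.data[:, scalp, :], axis=2)      # (trials, n_scalp)
    n_trials = epochs.n_trials
    # at least 20 fitting epochs so the per-fold median stays robust
    n_fit = max(int(np.ceil(fit_fraction * n_trials)), 20)
    n_fit = min(n_fit, n_trials)
    fit_idx = rng.choice(n_trials, size=n_fit, replace=False)
    thresholds = _cv_thresholds(ptp[fit_idx], epochs.data[fit_idx][:, scalp, :],
                                rng)
    bad = ptp > thresholds[None, :]                     # (trials, n_scalp)
    nb_idx, nb_w = _neighbor_graph(names)
    out = epochs.copy()
    log = RejectionLog(mode=mode,
                       thresholds=dict(zip(names, thresholds.tolist())))

    if mode == "interpolate":
        for t in range(n_trials):
            if bad[t].any():
                _interpolate_trial(out.data[t][scalp], bad[t], nb_idx, nb_w)
                log.decisions.append(
                    {"trial": t, "action": "interpolate",
                     "channels": [names[c] for c in np.flatnonzero(bad[t])]})
            else:
                log.decisions.append({"trial": t, "action": "keep"})
        return out, log

    # reject mode: grid search over consensus x n_interpolate, scored by
    # 5-fold CV on the fit subset: cleaned average of the kept training
    # trials (bad channels masked, worst first, up to n_interpolate) vs the
    # median signal of the validation trials
    n_scalp = len(scalp)
    data_fit = epochs.data[fit_idx][:, scalp, :]
    ptp_f, bad_f = ptp[fit_idx], bad[fit_idx]
    folds = np.array_split(rng.permutation(len(fit_idx)), 5)
    best_score, best_pair = np.inf, (consensus[0], n_interpolate[0])
    for kappa in consensus:
        for n_int in n_interpolate:
            score = 0.0
            for k in range(5):
                val = folds[k]
                train = np.concatenate([folds[j] for j in range(5) if j != k])
                med_val = np.median(data_fit[val], axis=0)
                wsum = np.zeros((n_scalp, data_fit.shape[2]))
                wcnt = np.zeros(n_scalp)
                for t in train:
                    n_bad = int(bad_f[t].sum())
                    if n_bad > kappa * n_scalp:
                        continue                      # dropped
                    mask = np.ones(n_scalp, dtype=bool)
                    if n_bad:
                        over = np.flatnonzero(bad_f[t])
                        worst = over[np.argsort(ptp_f[t][over])[::-1][:n_int]]
                        mask[worst] = False           # masked as missing
                    wsum[mask] += data_fit[t][mask]
                    wcnt[mask] += 1
                if wcnt.min() == 0:
                    score = np.inf
                    break
                mean_clean = wsum / wcnt[:, None]
                score += float(np.sqrt(((mean_clean - med_val) ** 2).mean()))
            if score < best_score:
                best_score, best_pair = score, (kappa, n_int)
    kappa, n_int = best_pair
    log.consensus, log.n_interpolate = kappa, n_int

    keep_rows = []
    for t in range(n_trials):
        n_bad = int(bad[t].sum())
        if n_bad > kappa * n_scalp:
            log.decisions.append({"trial": t, "action": "drop",
                                  "reason": f"{n_bad} bad channels"})
            log.dropped_trials.append(t)
            continue
        if n_bad:
            over = np.flatnonzero(bad[t])
            worst = over[np.argsort(ptp[t][over] - thresholds[over])
                         [::-1][:n_int]]
            mask = np.zeros(n_scalp, dtype=bool)
            mask[worst] = True
            _interpolate_trial(out.data[t][scalp], mask, nb_idx, nb_w)
            log.decisions.append(
                {"trial": t, "action": "interpolate",
                 "channels": [names[c] for c in worst]})
        else:
            log.decisions.append({"trial": t, "action": "keep"})
        keep_rows.append(t)

    keep_rows = np.array(keep_rows, dtype=int)
    out.data = out.data[keep_rows]
    out.labels = out.labels[keep_rows]
    out.kept_trial_index = out.kept_trial_index[keep_rows]
    counts = np.bincount(out.labels, minlength=2)
    if counts.min() < min_trials_per_class:
        raise PathInvalidError(
            f"only {counts.min()} trials left in a class after rejection")
    return out, log
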