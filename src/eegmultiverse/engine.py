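"""Forking-path definition, enumeration, execution and ranking.

A forking path is one complete combination of preprocessing choices — the
multiverse coordinate.  The default step grid mirrors the full factorial
design of the study: 2 (ocular ICA) x 2 (muscle ICA) x 4 (LPF) x 3 (HPF) x
3 (reference) x 2 (detrend) x 3 (baseline) x 3 (rejection) = 2592 paths.
The first level of every step is the smallest intervention (the reference
level for downstream factorial models).

Operators are applied in the fixed main order: ocular ICA -> muscle ICA ->
low-/high-pass filtering (a single band-pass when both cutoffs are set) ->
re-referencing -> epoching -> detrending -> baseline correction ->
peak-to-peak rejection.  "none" levels are identities.  Execution is a pure
function of (recordings, path, master seed); within a multiverse run the
continuous-stage results (ICA, filtering, referencing) are memoised across
paths sharing the same level prefix, which cannot change results because the
per-stage child seeds depend only on the stage-relevant levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as pp
from .cluster_stats import (
    ClusterTestConfig,
    average_accuracy_metric,
    cluster_mass_test,
    detect_baseline_artifact,
    tfce_sum,
)
from .containers import ContinuousRecording, EpochSet, PathInvalidError
from .decode import DecoderConfig, time_resolved_decode
from .seeding import child_seed

__all__ = [
    "DEFAULT_GRID", "DEFAULT_REFERENCE_PATH", "StepGrid", "ForkingPath",
    "MultiverseTable", "enumerate_paths", "prepare_recording",
    "execute_path", "run_multiverse", "rank_paths", "substitute_single_step",
]

#: The full factorial grid of the multiverse (2592 paths).
DEFAULT_GRID: dict[str, list[str]] = {
    "ocular": ["none", "ica"],
    "muscle": ["none", "ica"],
    "lpf": ["none", "45", "20", "6"],
    "hpf": ["none", "0.1", "0.5"],
    "reference": ["Cz", "P9P10", "average"],
    "detrend": ["none", "linear"],
    "baseline": ["none", "200ms", "400ms"],
    "reject": ["none", "interpolate", "reject"],
}

BASELINE_WINDOWS = {"200ms": (-0.2, 0.0), "400ms": (-0.4, 0.0)}


class GridError(ValueError):
    """Invalid step grid."""


@dataclass
class StepGrid:
    """Ordered mapping step name -> list of levels.

    The first level of each step is the reference ("smallest intervention")
    level.
    """

    steps: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})

    def __post_init__(self) -> None:
        for step, levels in self.steps.items():
            if not levels:
                raise GridError(f"step {step!r} has no levels")
            if len(set(levels)) != len(levels):
                raise GridError(f"step {step!r} has duplicate levels")

    @property
    def n_paths(self) -> int:
        out = 1
        for levels in self.steps.values():
            out *= len(levels)
        return out

    def reference_levels(self) -> dict[str, str]:
        return {step: levels[0] for step, levels in self.steps.items()}


@dataclass(frozen=True)
class ForkingPath:
    """One level per preprocessing step; the multiverse coordinate."""

    levels: tuple[tuple[str, str], ...]     # ((step, level), ...) in order

    @classmethod
    def from_dict(cls, levels: dict[str, str]) -> "ForkingPath":
        return cls(tuple(levels.items()))

    def as_dict(self) -> dict[str, str]:
        return dict(self.levels)

    @property
    def id(self) -> str:
        return "|".join(f"{s}={l}" for s, l in self.levels)

    @classmethod
    def from_id(cls, path_id: str) -> "ForkingPath":
        pairs = [tuple(tok.split("=", 1)) for tok in path_id.split("|")]
        return cls(tuple(pairs))   # type: ignore[arg-type]

    def replace(self, step: str, level: str) -> "ForkingPath":
        return ForkingPath(tuple((s, level if s == step else l)
                                 for s, l in self.levels))


#: The example forking path of the study design: near-mastoid reference,
#: 0.1 Hz HPF, no LPF, both ICA corrections, interpolate-mode rejection,
#: 200 ms baseline, no detrending.
DEFAULT_REFERENCE_PATH = ForkingPath.from_dict({
    "ocular": "ica", "muscle": "ica", "lpf": "none", "hpf": "0.1",
    "reference": "P9P10", "detrend": "none", "baseline": "200ms",
    "reject": "interpolate",
})


def enumerate_paths(grid: StepGrid | dict) -> list[ForkingPath]:
    """All level combinations in deterministic lexicographic order."""
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    names = list(grid.steps)
    paths = []
    for combo in itertools.product(*(grid.steps[n] for n in names)):
        paths.append(ForkingPath(tuple(zip(names, combo))))
    return paths


def fractional_factorial(grid: StepGrid | dict, parity: int = 0) -> list[ForkingPath]:
    """Half-fraction of a factorial: keep paths whose level-index sum is even
    (``parity=0``) or odd.  With two levels per step this is the classical
    resolution-maximising half fraction — every step still varies and every
    two-step combination is balanced, at half the cost."""
    paths = enumerate_paths(grid)
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    out = []
    for p in paths:
        s = sum(grid.steps[step].index(level) for step, level in p.levels)
        if s % 2 == parity:
            out.append(p)
    return out


def prepare_recording(recording: ContinuousRecording) -> ContinuousRecording:
    """Study-style data preparation before the multiverse: derive bipolar
    HEOG/VEOG channels and apply a temporary Cz reference (the final
    reference is set by each forking path; referencing is idempotent under
    re-referencing, so the temporary reference does not bias any path)."""
    rec = pp.derive_bipolar_eog(recording)
    return pp.rereference(rec, "Cz")


def _continuous_stage(recording: ContinuousRecording, levels: dict[str, str],
                      master_seed: int, cache: dict | None):
    """Apply the continuous-signal steps with optional memoisation."""
    pid = recording.participant_id

    def cached(key, fn):
        if cache is None:
            return fn()
        if key not in cache:
            cache[key] = fn()
        return cache[key]

    rec = recording
    if levels.get("ocular", "none") == "ica":
        rec = cached((pid, "ocular"), lambda r=rec: pp.correct_ocular(
            r, child_seed(master_seed, "ocular-ica", pid))[0])
    if levels.get("muscle", "none") == "ica":
        key = (pid, "ocular:" + levels.get("ocular", "none"), "muscle")
        rec = cached(key, lambda r=rec: pp.correct_muscle(
            r, child_seed(master_seed, "muscle-ica", pid))[0])
    l_freq = None if levels.get("hpf", "none") == "none" else float(levels["hpf"])
    h_freq = None if levels.get("lpf", "none") == "none" else float(levels["lpf"])
    if l_freq is not None or h_freq is not None:
        key = (pid, levels.get("ocular", "none"), levels.get("muscle", "none"),
               "filt", levels.get("lpf"), levels.get("hpf"))
        rec = cached(key, lambda r=rec: pp.fir_filter(
            r, pp.FilterSpec(l_freq=l_freq, h_freq=h_freq)))
    if levels.get("reference", "none") != "none":
        key = (pid, levels.get("ocular", "none"), levels.get("muscle", "none"),
               levels.get("lpf"), levels.get("hpf"), "ref", levels["reference"])
        rec = cached(key, lambda r=rec: pp.rereference(
            r, levels["reference"]))
    return rec


def execute_path(recordings: list[ContinuousRecording], path: ForkingPath,
                 epoch_window: tuple[float, float] = (-0.4, 0.8),
                 master_seed: int = 0, min_trials_per_class: int = 10,
                 _cache: dict | None = None):
    """Run one forking path over all participants.

    Returns ``(epochs_by_participant, failures)`` where ``failures`` maps a
    participant id to the reason the path is invalid for them (e.g. too few
    trials after rejection).  Deterministic given ``(recordings, path,
    master_seed)``; the memoisation cache never changes results.
    """
    levels = path.as_dict()
    epochs_by_pid: dict[int, EpochSet] = {}
    failures: dict[int, str] = {}
    for rec in recordings:
        pid = rec.participant_id
        try:
            cont = _continuous_stage(rec, levels, master_seed, _cache)
            ep = pp.epoch(cont, epoch_window)
            if levels.get("detrend", "none") == "linear":
                ep = pp.detrend_linear(ep)
            if levels.get("baseline", "none") != "none":
                ep = pp.baseline_correct(ep, BASELINE_WINDOWS[levels["baseline"]])
            if levels.get("reject", "none") != "none":
                ep, _ = pp.reject_peak_to_peak(
                    ep, levels["reject"],
                    seed=child_seed(master_seed, "reject", pid,
                                    levels["reject"]),
                    min_trials_per_class=min_trials_per_class)
            epochs_by_pid[pid] = ep
        except PathInvalidError as err:
            failures[pid] = str(err)
    return epochs_by_pid, failures


@dataclass
class MultiverseTable:
    """Long-format result store: one row per (path, participant, metric).

    Group-level metrics carry ``participant = -1``.  Failed (path,
    participant) combinations are present with a non-"ok" status rather than
    silently absent.
    """

    df: pd.DataFrame

    COLUMNS = ("path_id", "participant", "metric", "value",
               "n_trials_used", "status")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MultiverseTable":
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df=df)

    def group_metric(self, metric: str) -> pd.Series:
        sel = self.df[(self.df.metric == metric)
                      & (self.df.participant == -1)
                      & (self.df.status == "ok")]
        return sel.set_index("path_id")["value"]

    def participant_metric(self, metric: str) -> pd.DataFrame:
        sel = self.df[(self.df.metric == metric) & (self.df.participant >= 0)
                      & (self.df.status == "ok")]
        return sel[["path_id", "participant", "value"]]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MultiverseTable":
        return cls(df=pd.read_csv(path, sep="\t"))


def run_multiverse(recordings: list[ContinuousRecording],
                   grid: StepGrid | dict | list[ForkingPath],
                   epoch_window: tuple[float, float] = (-0.4, 0.8),
                   decoder_config: DecoderConfig | None = None,
                   stats_config: ClusterTestConfig | None = None,
                   master_seed: int = 0,
                   compute_tfce: bool = False,
                   baseline_boundary: float = 0.0,
                   min_participants: int = 2,
                   progress: bool = False) -> MultiverseTable:
    """Decode and quantify every forking path of a (possibly reduced) grid.

    Per path: execute the preprocessing, decode time-resolved per
    participant, and compute the group cluster-mass T-sum (plus optional
    TFCE-sum), the baseline-artifact flag and the post-baseline average
    accuracy.  Group statistics require at least ``min_participants`` valid
    participants; failures are recorded per (path, participant) with an
    explicit status.
    """
    if decoder_config is None:
        decoder_config = DecoderConfig(seed=child_seed(master_seed, "decode"))
    if stats_config is None:
        stats_config = ClusterTestConfig(seed=child_seed(master_seed, "stats"))
    if isinstance(grid, list):
        paths = grid
    else:
        paths = enumerate_paths(grid)
    cache: dict = {}
    rows: list[dict] = []
    iterator = paths
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(paths, desc="multiverse")
        except ImportError:
            pass
    for path in iterator:
        epochs_by_pid, failures = execute_path(
            recordings, path, epoch_window=epoch_window,
            master_seed=master_seed,
            min_trials_per_class=decoder_config.n_folds, _cache=cache)
        for pid, reason in failures.items():
            rows.append(dict(path_id=path.id, participant=pid,
                             metric="avg_accuracy", value=np.nan,
                             n_trials_used=0, status="too_few_trials"))
        series = []
        for pid, ep in sorted(epochs_by_pid.items()):
            try:
                dts = time_resolved_decode(ep, decoder_config,
                                           path_id=path.id)
            except PathInvalidError as err:
                rows.append(dict(path_id=path.id, participant=pid,
                                 metric="avg_accuracy", value=np.nan,
                                 n_trials_used=ep.n_trials,
                                 status="too_few_trials"))
                continue
            series.append(dts)
            rows.append(dict(
                path_id=path.id, participant=pid, metric="avg_accuracy",
                value=average_accuracy_metric(dts.accuracy, dts.times,
                                              baseline_boundary),
                n_trials_used=dts.n_trials_used, status="ok"))
        if len(series) < min_participants:
            rows.append(dict(path_id=path.id, participant=-1, metric="t_sum",
                             value=np.nan, n_trials_used=0,
                             status="too_few_participants"))
            continue
        stack = np.vstack([s.accuracy for s in series])
        times = series[0].times
        res = cluster_mass_test(stack, times, stats_config)
        n_used = int(np.mean([s.n_trials_used for s in series]))
        rows.append(dict(path_id=path.id, participant=-1, metric="t_sum",
                         value=res.total_t_sum, n_trials_used=n_used,
                         status="ok"))
        rows.append(dict(path_id=path.id, participant=-1,
                         metric="baseline_artifact",
                         value=float(detect_baseline_artifact(
                             res, baseline_boundary)),
                         n_trials_used=n_used, status="ok"))
        rows.append(dict(path_id=path.id, participant=-1,
                         metric="avg_accuracy_group",
                         value=float(np.mean([average_accuracy_metric(
                             s.accuracy, times, baseline_boundary)
                             for s in series])),
                         n_trials_used=n_used, status="ok"))
        if compute_tfce:
            rows.append(dict(path_id=path.id, participant=-1,
                             metric="tfce_sum",
                             value=tfce_sum(stack, times,
                                            chance=stats_config.chance),
                             n_trials_used=n_used, status="ok"))
    return MultiverseTable.from_rows(rows)


def rank_paths(table: MultiverseTable, metric: str = "t_sum") -> pd.DataFrame:
    """Rank paths from best (#1) to worst by a metric, descending.

    Per-participant metrics are participant-averaged first.  Ties are broken
    deterministically by path id.
    """
    group = table.group_metric(metric)
    if group.empty:
        per = table.participant_metric(metric)
        if per.empty:
            raise KeyError(f"metric {metric!r} not present in the table")
        group = per.groupby("path_id")["value"].mean()
    out = group.rename("value").reset_index()
    out = out.sort_values(["value", "path_id"],
                          ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def substitute_single_step(table: MultiverseTable, grid: StepGrid | dict,
                           reference_path: ForkingPath = DEFAULT_REFERENCE_PATH,
                           metric: str = "t_sum") -> pd.DataFrame:
    """Effect of manipulating one single preprocessing step at a time.

    For every step and non-reference level, the metric difference between the
    path equal to ``reference_path`` with that single level substituted and
    the reference path itself.
    """
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    values = table.group_metric(metric)
    if values.empty:
        per = table.participant_metric(metric)
        values = per.groupby("path_id")["value"].mean()
    if reference_path.id not in values.index:
        raise KeyError("reference path missing from the results table")
    ref_value = values[reference_path.id]
    ref_levels = reference_path.as_dict()
    rows = []
    for step, levels in grid.steps.items():
        for level in levels:
            if level == ref_levels.get(step):
                continue
            alt = reference_path.replace(step, level)
            delta = (values[alt.id] - ref_value
                     if alt.id in values.index else np.nan)
            rows.append(dict(step=step, level=level,
                             reference_level=ref_levels.get(step),
                             delta=delta,
                             status="ok" if alt.id in values.index
                             else "missing"))
    return pd.DataFrame(rows)
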