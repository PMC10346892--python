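"""From labeled circuits to the stacked, scaled, balanced design matrix.

The pipeline follows five stages:

1. **Transition removal** — the label stream is split into maximal
   single-activity runs and half of ``transition_removal`` samples are
   deleted from each side of every activity boundary (ambiguous transition
   kinematics carry unreliable ground truth).
2. **Window segmentation** — each run is tiled with non-overlapping
   ``window``-sample windows; the tiling is repeated ``n_passes`` times at
   start offsets ``0, shift, 2*shift, ...`` so the union of passes equals a
   stride-``shift`` sliding window.  Incomplete trailing windows are dropped.
3. **Feature extraction** — nine time-domain statistics per window per
   channel: mean, median, standard deviation (population), minimum, maximum,
   initial value, final value, mean absolute value about the mean (MAV) and
   waveform length (WL, the summed absolute first differences).
4. **Context stacking** — feature rows of ``context`` consecutive windows of
   the same (circuit, run, pass) are concatenated, oldest first, labeled by
   the newest window, giving the classifier short-term memory.
5. **Scaling and balancing** — column z-scoring with statistics fitted on the
   training split only, and class balancing by seeded downsampling to the
   smallest class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import N_ACTIVITIES
from .errors import ConfigurationError, EmptyInputError
from .ingest import Circuit

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "std",
    "min",
    "max",
    "initial",
    "final",
    "mav",
    "wl",
)
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing and stacking parameters.

    Defaults: 25-sample windows (0.05 s at 500 Hz), 5-sample shift applied in
    5 passes (together spanning every 5th start position), 500 samples
    (1 s) removed around each activity transition, and 3-window context.
    ``median_mode`` selects the sorted median ("sorted", default) or the raw
    center sample ("center") for the median feature.
    """

    window: int = 25
    shift: int = 5
    n_passes: int = 5
    transition_removal: int = 500
    context: int = 3
    median_mode: str = "sorted"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.shift <= self.window:
            raise ValueError("shift must satisfy 0 < shift <= window")
        if self.n_passes < 1 or self.n_passes * self.shift > self.window:
            raise ValueError("need 1 <= n_passes and n_passes*shift <= window")
        if self.transition_removal < 0 or self.transition_removal % 2:
            raise ValueError("transition_removal must be even and >= 0")
        if self.context < 1:
            raise ValueError("context must be >= 1")
        if self.median_mode not in ("sorted", "center"):
            raise ValueError("median_mode must be 'sorted' or 'center'")


@dataclass(frozen=True)
class ActivityRun:
    """A contiguous single-activity sample slice ``[start, stop)``."""

    activity: int
    start: int
    stop: int
    run_index: int

    @property
    def length(self) -> int:
        return self.stop - self.start


def remove_transitions(circuit: Circuit, cfg: SegmentationConfig) -> list[ActivityRun]:
    """Split into single-activity runs, trimming samples around each boundary.

    ``transition_removal/2`` samples are deleted from the end of the earlier
    run and from the start of the later run at every label change; the
    circuit's first and last samples are not trimmed.  Runs left shorter than
    one window are dropped.
    """
    labels = circuit.labels
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(labels)]))
    half = cfg.transition_removal // 2

    runs: list[ActivityRun] = []
    last = len(starts) - 1
    for i, (a, b) in enumerate(zip(starts, stops)):
        lo = a + (half if i > 0 else 0)
        hi = b - (half if i < last else 0)
        if hi - lo >= cfg.window:
            runs.append(ActivityRun(int(labels[a]), int(lo), int(hi), run_index=i))
    return runs


def window_starts(length: int, cfg: SegmentationConfig):
    """Window start positions for all passes over a run of ``length`` samples.

    Returns ``(starts, pass_offsets, window_indices)`` arrays in pass-major
    order: within pass offset ``o`` windows start at ``o, o+W, o+2W, ...``
    while ``start + W <= length``.
    """
    starts, offs, idxs = [], [], []
    for p in range(cfg.n_passes):
        o = p * cfg.shift
        n = max(0, (length - o) // cfg.window) if length >= o else 0
        for m in range(n):
            starts.append(o + m * cfg.window)
            offs.append(o)
            idxs.append(m)
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(offs, dtype=np.int64),
        np.asarray(idxs, dtype=np.int64),
    )


@dataclass(frozen=True)
class Window:
    """One fixed-length single-channel slice with its provenance."""

    values: np.ndarray
    channel: str
    pass_offset: int
    window_index: int
    activity: int
    subject_id: str = ""
    circuit_id: str = ""


def segment_run(
    samples: np.ndarray,
    cfg: SegmentationConfig,
    channels=None,
    activity: int = -1,
    subject_id: str = "",
    circuit_id: str = "",
) -> list[Window]:
    """Materialize all windows of an ``[L, C]`` run, channel by channel.

    Mostly an inspection/testing aid; the bulk pipeline uses
    :func:`build_feature_table`, which computes features without building
    ``Window`` objects.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1 and samples.shape[1] > 1 and channels is None:
        samples = samples.T  # accept a 1-D signal as a single channel
    L, C = samples.shape
    if channels is None:
        channels = tuple(f"ch{j}" for j in range(C))
    starts, offs, idxs = window_starts(L, cfg)
    out = []
    for j, ch in enumerate(channels):
        for s, o, m in zip(starts, offs, idxs):
            out.append(
                Window(
                    values=samples[s : s + cfg.window, j].copy(),
                    channel=ch,
                    pass_offset=int(o),
                    window_index=int(m),
                    activity=activity,
                    subject_id=subject_id,
                    circuit_id=circuit_id,
                )
            )
    return out


def extract_features(window, median_mode: str = "sorted") -> np.ndarray:
    """The nine time-domain features of one window (see module docstring).

    Accepts a :class:`Window` or a plain 1-D array of length >= 2.
    """
    values = window.values if isinstance(window, Window) else window
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("window must be a 1-D array of length >= 2")
    return extract_features_batch(values[None, :], median_mode=median_mode)[0]


def extract_features_batch(windows: np.ndarray, median_mode: str = "sorted") -> np.ndarray:
    """Features along the last axis of a ``[..., W]`` stack of windows."""
    x = np.asarray(windows, dtype=float)
    W = x.shape[-1]
    if W < 2:
        raise ValueError("window length must be >= 2")
    mean = x.mean(axis=-1)
    if median_mode == "sorted":
        med = np.median(x, axis=-1)
    else:  # raw center sample x_{i + (W-1)//2}
        med = x[..., (W - 1) // 2]
    std = x.std(axis=-1)
    mav = np.abs(x - mean[..., None]).mean(axis=-1)
    wl = np.abs(np.diff(x, axis=-1)).sum(axis=-1)
    return np.stack(
        [mean, med, std, x.min(axis=-1), x.max(axis=-1), x[..., 0], x[..., -1], mav, wl],
        axis=-1,
    )


@dataclass
class FeatureTable:
    """Per-window feature rows with provenance.

    ``X`` is ``[N, 9*C]`` in channel-major column order (all nine features of
    channel 0, then channel 1, ...); ``meta`` carries subject_id, circuit_id,
    run_index, activity, pass_offset and window_index per row.
    """

    X: np.ndarray
    meta: pd.DataFrame
    channels: tuple[str, ...]

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}:{f}" for ch in self.channels for f in FEATURE_NAMES]


def build_feature_table(circuits, cfg: SegmentationConfig) -> FeatureTable:
    """Run transition removal, segmentation and feature extraction.

    Rows are ordered circuit by circuit, run by run, pass-major within a run;
    all channels of one window share one row.
    """
    circuits = list(circuits)
    channels: tuple[str, ...] | None = None
    blocks: list[np.ndarray] = []
    meta_parts = []
    for c in circuits:
        if channels is None:
            channels = c.channels
        elif c.channels != channels:
            raise ConfigurationError(
                f"circuit {c.subject_id}/{c.circuit_id} has a different channel set"
            )
        for run in remove_transitions(c, cfg):
            seg = c.samples[run.start : run.stop]
            starts, offs, idxs = window_starts(run.length, cfg)
            if starts.size == 0:
                continue
            view = np.lib.stride_tricks.sliding_window_view(seg, cfg.window, axis=0)
            wins = view[starts]  # [n, C, W]
            feats = extract_features_batch(wins, median_mode=cfg.median_mode)
            blocks.append(feats.reshape(len(starts), -1))
            meta_parts.append(
                pd.DataFrame(
                    {
                        "subject_id": c.subject_id,
                        "circuit_id": c.circuit_id,
                        "run_index": run.run_index,
                        "activity": run.activity,
                        "pass_offset": offs,
                        "window_index": idxs,
                    }
                )
            )
    if channels is None:
        channels = ()
    if not blocks:
        X = np.empty((0, N_FEATURES * len(channels)))
        meta = pd.DataFrame(
            columns=[
                "subject_id",
                "circuit_id",
                "run_index",
                "activity",
                "pass_offset",
                "window_index",
            ]
        )
        return FeatureTable(X, meta, channels)
    return FeatureTable(
        np.vstack(blocks), pd.concat(meta_parts, ignore_index=True), channels
    )


@dataclass
class StackedDataset:
    """Context-stacked design matrix with labels and group provenance."""

    X: np.ndarray
    y: np.ndarray
    groups: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


_GROUP_KEYS = ["subject_id", "circuit_id", "run_index", "pass_offset"]


def stack_context(table: FeatureTable, k: int | None = None) -> StackedDataset:
    """Concatenate ``k`` consecutive windows of each (circuit, run, pass).

    Produces one row per window index ``t >= k-1`` within each group, holding
    ``[features_{t-k+1} | ... | features_t]`` and labeled by window ``t``.
    Groups never span circuits, activity runs or segmentation passes, so a
    stacked row never mixes activities.
    """
    if k is None:
        k = 3
    if k < 1:
        raise ValueError("context depth k must be >= 1")
    X, meta = table.X, table.meta
    if len(meta) == 0:
        return StackedDataset(
            np.empty((0, k * X.shape[1])), np.empty(0, dtype=np.int64), meta.copy()
        )

    part_indices: list[list[np.ndarray]] = [[] for _ in range(k)]
    last: list[np.ndarray] = []
    for _, pos in meta.groupby(_GROUP_KEYS, sort=False).indices.items():
        pos = np.asarray(pos)
        order = np.argsort(meta["window_index"].to_numpy()[pos], kind="stable")
        pos = pos[order]
        m = len(pos)
        if m < k:
            continue
        for j in range(k):
            part_indices[j].append(pos[j : m - k + 1 + j])
        last.append(pos[k - 1 :])

    if not last:
        return StackedDataset(
            np.empty((0, k * X.shape[1])), np.empty(0, dtype=np.int64), meta.iloc[:0].copy()
        )
    last_idx = np.concatenate(last)
    X_stacked = np.hstack([X[np.concatenate(p)] for p in part_indices])
    y = meta["activity"].to_numpy()[last_idx].astype(np.int64)
    groups = meta.iloc[last_idx].reset_index(drop=True)
    return StackedDataset(X_stacked, y, groups)


@dataclass(frozen=True)
class ScalerStats:
    """Column means and scales of a z-scoring transform (training split only)."""

    mean: np.ndarray
    scale: np.ndarray
    n_fit: int


def fit_scaler(X_train: np.ndarray, eps: float = 1e-12) -> ScalerStats:
    """Column-wise mean/standard-deviation statistics.

    Columns with (near-)zero variance get scale 1 so they pass through merely
    centered.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise EmptyInputError("cannot fit scaler on an empty matrix")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale = np.where(scale > eps, scale, 1.0)
    return ScalerStats(mean=mean, scale=scale, n_fit=X_train.shape[0])


def apply_scaler(X: np.ndarray, stats: ScalerStats) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != stats.mean.shape[0]:
        raise ValueError("column count does not match fitted scaler")
    return (X - stats.mean) / stats.scale


def balance_classes(
    ds: StackedDataset, seed: int, classes=None
) -> StackedDataset:
    """Downsample every class to the smallest class count (without replacement).

    ``classes`` defaults to the classes present in ``ds.y``; pass
    ``range(7)`` to require all seven activities.  Relative row order is
    preserved among the surviving rows.
    """
    if classes is None:
        classes = np.unique(ds.y)
    classes = [int(c) for c in classes]
    counts = {c: int((ds.y == c).sum()) for c in classes}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise EmptyInputError(f"classes with zero rows cannot be balanced: {missing}")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.flatnonzero(ds.y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return StackedDataset(ds.X[keep], ds.y[keep], ds.groups.iloc[keep].reset_index(drop=True))
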