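"""Leave-one-subject-out experiments and reporting.

Each fold holds out every circuit of one subject for testing; the remaining
(seen) subjects contribute training circuits (capped at 8 per subject) and a
seeded draw of validation circuits.  With the default synthetic study of 8
subjects and 10 circuits each, every fold therefore trains on 56 circuits,
validates on 14 and tests on 4 — all from the unseen subject.

Metrics are computed from scratch here: confusion matrices in the fixed
activity order, overall accuracy, and one-vs-rest per-class F1
``TP / (TP + (FP + FN)/2)``.  Scaler fitting and class balancing always see
training rows only, so held-out subjects cannot leak into the weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .channels import ACTIVITY_NAMES, N_ACTIVITIES
from .errors import GaitannError
from .ingest import Circuit, validate_circuit
from .model import ModelContainer, NetworkParams, TrainConfig, forward, predict, train
from .preprocess import (
    FeatureTable,
    ScalerStats,
    SegmentationConfig,
    StackedDataset,
    apply_scaler,
    balance_classes,
    build_feature_table,
    extract_features_batch,
    stack_context,
    window_starts,
    remove_transitions,
)

CircuitKey = tuple[str, str]


@dataclass(frozen=True)
class FoldSpec:
    """Circuit assignment of one leave-one-subject-out fold."""

    test_subject: str
    train_circuits: tuple[CircuitKey, ...]
    val_circuits: tuple[CircuitKey, ...]
    test_circuits: tuple[CircuitKey, ...]

    def __post_init__(self) -> None:
        if any(s != self.test_subject for s, _ in self.test_circuits):
            raise ValueError("test circuits must belong to the test subject")
        seen = self.train_circuits + self.val_circuits
        if any(s == self.test_subject for s, _ in seen):
            raise ValueError("train/val circuits must exclude the test subject")
        if set(self.train_circuits) & set(self.val_circuits):
            raise ValueError("train and val circuits overlap")


def make_loso_folds(
    circuits,
    val_per_subject: int = 2,
    test_per_unseen: int = 4,
    train_cap: int = 8,
    seed: int = 0,
) -> list[FoldSpec]:
    """One fold per subject; validation/test circuits drawn by seeded sampling."""
    by_subject: dict[str, list[CircuitKey]] = {}
    for c in circuits:
        by_subject.setdefault(c.subject_id, []).append((c.subject_id, c.circuit_id))
    subjects = list(by_subject)
    if len(subjects) < 2:
        raise GaitannError("need at least 2 subjects for leave-one-subject-out")
    for s, keys in by_subject.items():
        if len(keys) < val_per_subject + 1:
            raise GaitannError(
                f"subject {s} has {len(keys)} circuits; "
                f"needs at least {val_per_subject + 1}"
            )

    folds = []
    for i, test_subject in enumerate(subjects):
        rng = np.random.default_rng([seed, i])
        pool = by_subject[test_subject]
        if len(pool) < test_per_unseen:
            raise GaitannError(
                f"subject {test_subject} has {len(pool)} circuits; "
                f"needs at least {test_per_unseen} for testing"
            )
        test = [pool[j] for j in sorted(rng.choice(len(pool), test_per_unseen, replace=False))]
        train_keys: list[CircuitKey] = []
        val_keys: list[CircuitKey] = []
        for s in subjects:
            if s == test_subject:
                continue
            keys = by_subject[s]
            val_idx = sorted(rng.choice(len(keys), val_per_subject, replace=False))
            val_keys += [keys[j] for j in val_idx]
            rest = [k for j, k in enumerate(keys) if j not in val_idx]
            if train_cap is not None and len(rest) > train_cap:
                rest = [
                    rest[j]
                    for j in sorted(rng.choice(len(rest), train_cap, replace=False))
                ]
            train_keys += rest
        folds.append(
            FoldSpec(test_subject, tuple(train_keys), tuple(val_keys), tuple(test))
        )
    return folds


def confusion(y_true, y_pred, K: int = N_ACTIVITIES) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        min(y_true.min(), y_pred.min()) < 0 or max(y_true.max(), y_pred.max()) >= K
    ):
        raise ValueError(f"class codes must lie in 0..{K - 1}")
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    total = cm.sum()
    return float(np.trace(cm) / total) if total else 0.0


def f1_per_class(cm: np.ndarray, return_flags: bool = False):
    """One-vs-rest F1 = TP / (TP + (FP + FN)/2) per class.

    A class absent from both truth and predictions (TP=FP=FN=0) scores 0 and
    is flagged degenerate, keeping macro averages conservative.
    """
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = tp + 0.5 * (fp + fn)
    degenerate = denom == 0
    f1 = np.where(degenerate, 0.0, tp / np.where(degenerate, 1.0, denom))
    return (f1, degenerate) if return_flags else f1


@dataclass
class SplitResult:
    confusion: np.ndarray
    accuracy: float
    f1: np.ndarray
    n_rows: int


@dataclass
class FoldResult:
    test_subject: str
    splits: dict[str, SplitResult]
    final_cost: float
    n_iterations: int
    train_seconds: float
    inference_us_mean: float
    inference_us_sd: float
    params: NetworkParams | None = None
    scaler: ScalerStats | None = None


@dataclass
class EvalReport:
    """Per-fold results plus unweighted across-fold means."""

    folds: list[FoldResult]
    seg_cfg: SegmentationConfig
    train_cfg: TrainConfig
    channel_subset: str | list[str]
    seed: int

    def mean_accuracy(self, split: str) -> float:
        return float(np.mean([f.splits[split].accuracy for f in self.folds]))

    def mean_macro_f1(self, split: str) -> float:
        return float(np.mean([f.splits[split].f1.mean() for f in self.folds]))

    def mean_inference_us(self) -> float:
        return float(np.mean([f.inference_us_mean for f in self.folds]))

    def to_text(self) -> str:
        lines = [
            f"Leave-one-subject-out report ({len(self.folds)} folds, "
            f"channels={self.channel_subset}, seed={self.seed})",
            "",
        ]
        for f in self.folds:
            lines.append(
                f"fold test_subject={f.test_subject}: "
                + "  ".join(
                    f"{name} acc={r.accuracy:.4f} macroF1={r.f1.mean():.4f} (n={r.n_rows})"
                    for name, r in f.splits.items()
                )
                + f"  [cost={f.final_cost:.4f}, iters={f.n_iterations}, "
                f"train={f.train_seconds:.1f}s, infer={f.inference_us_mean:.1f}us]"
            )
        lines.append("")
        for split in ("train", "val", "test"):
            lines.append(
                f"mean {split}: accuracy={self.mean_accuracy(split):.4f} "
                f"macroF1={self.mean_macro_f1(split):.4f}"
            )
        lines.append(f"mean inference per stacked row: {self.mean_inference_us():.1f} us")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            fh.write(self.to_text() + "\n")
        for f in self.folds:
            for split, r in f.splits.items():
                pd.DataFrame(
                    r.confusion, index=ACTIVITY_NAMES, columns=ACTIVITY_NAMES
                ).to_csv(os.path.join(out_dir, f"confusion_{f.test_subject}_{split}.csv"))


def _concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    return FeatureTable(
        X=np.vstack([t.X for t in tables]),
        meta=pd.concat([t.meta for t in tables], ignore_index=True),
        channels=tables[0].channels,
    )


def _fold_seed(seed: int, fold_index: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, fold_index, salt]).generate_state(1)[0] % (2**31))


def evaluate_split(params: NetworkParams, ds: StackedDataset, scaler) -> SplitResult:
    Xs = apply_scaler(ds.X, scaler)
    y_pred = predict(params, Xs)
    cm = confusion(ds.y, y_pred)
    return SplitResult(cm, accuracy(cm), f1_per_class(cm), ds.n_rows)


def run_experiment(
    circuits,
    seg_cfg: SegmentationConfig | None = None,
    train_cfg: TrainConfig | None = None,
    channel_subset="all",
    seed: int = 0,
    val_per_subject: int = 2,
    test_per_unseen: int = 4,
    train_cap: int = 8,
    balance_eval: bool = False,
    folds: list[FoldSpec] | None = None,
    timing_rows: int = 200,
) -> EvalReport:
    """The full leave-one-subject-out experiment.

    Preprocessing features are computed once per circuit and shared across
    folds; scaler statistics and class balancing come from each fold's
    training split only.  Fully reproducible from ``seed`` (fold draws,
    balancing and weight initialization all derive from it).
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    train_cfg = train_cfg or TrainConfig()

    circuits = [c.select_channels(channel_subset) for c in circuits]
    kept = []
    for c in circuits:
        findings = validate_circuit(c, window_size=seg_cfg.window)
        if not any(f.severity == "fatal" for f in findings):
            kept.append(c)
    if not kept:
        raise GaitannError("no valid circuits")
    circuits = kept

    # features and context stacking never cross circuits, so both are computed
    # once per circuit and shared across folds
    stacked: dict[CircuitKey, StackedDataset] = {}
    sums: dict[CircuitKey, np.ndarray] = {}
    sumsqs: dict[CircuitKey, np.ndarray] = {}
    for c in circuits:
        key = (c.subject_id, c.circuit_id)
        ds = stack_context(build_feature_table([c], seg_cfg), seg_cfg.context)
        stacked[key] = ds
        sums[key] = ds.X.sum(axis=0)
        sumsqs[key] = np.einsum("ij,ij->j", ds.X, ds.X)
    if folds is None:
        folds = make_loso_folds(
            circuits, val_per_subject, test_per_unseen, train_cap, seed
        )

    results = []
    for i, fold in enumerate(folds):
        # scaler statistics over the (unbalanced) training rows, aggregated
        # from per-circuit moments so the full matrix is never materialized
        n_tr = sum(stacked[k].n_rows for k in fold.train_circuits)
        if n_tr == 0:
            raise GaitannError(f"fold {i}: no training rows")
        mean = sum(sums[k] for k in fold.train_circuits) / n_tr
        var = sum(sumsqs[k] for k in fold.train_circuits) / n_tr - mean**2
        scale = np.sqrt(np.maximum(var, 0.0))
        scaler = ScalerStats(mean=mean, scale=np.where(scale > 1e-12, scale, 1.0), n_fit=n_tr)

        # balance by index before materializing the training matrix
        y_parts = [stacked[k].y for k in fold.train_circuits]
        y_tr = np.concatenate(y_parts)
        counts = np.bincount(y_tr, minlength=N_ACTIVITIES)
        missing = np.flatnonzero(counts == 0)
        if missing.size:
            raise GaitannError(f"fold {i}: classes with zero training rows: {missing.tolist()}")
        n_min = int(counts.min())
        rng = np.random.default_rng(_fold_seed(seed, i, 1))
        keep_parts = []
        for cls in range(N_ACTIVITIES):
            idx = np.flatnonzero(y_tr == cls)
            if len(idx) > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep_parts.append(idx)
        keep = np.sort(np.concatenate(keep_parts))
        offsets = np.cumsum([0] + [len(y) for y in y_parts])
        width = next(iter(stacked.values())).X.shape[1]
        Xtr = np.empty((len(keep), width))
        pos = 0
        for j, k in enumerate(fold.train_circuits):
            local = keep[(keep >= offsets[j]) & (keep < offsets[j + 1])] - offsets[j]
            Xtr[pos : pos + len(local)] = stacked[k].X[local]
            pos += len(local)
        ytr = y_tr[keep]
        Xtr = apply_scaler(Xtr, scaler)

        fold_cfg = replace(train_cfg, seed=_fold_seed(seed, i, 2))
        t0 = time.perf_counter()
        params, trace = train(None, Xtr, ytr, fold_cfg, K=N_ACTIVITIES)
        train_seconds = time.perf_counter() - t0

        splits: dict[str, SplitResult] = {}
        cm_tr = confusion(ytr, predict(params, Xtr))
        splits["train"] = SplitResult(cm_tr, accuracy(cm_tr), f1_per_class(cm_tr), len(ytr))
        del Xtr, ytr

        for name, keys in (("val", fold.val_circuits), ("test", fold.test_circuits)):
            ds = StackedDataset(
                X=np.vstack([stacked[k].X for k in keys]),
                y=np.concatenate([stacked[k].y for k in keys]),
                groups=pd.concat([stacked[k].groups for k in keys], ignore_index=True),
            )
            if balance_eval:
                ds = balance_classes(ds, seed=_fold_seed(seed, i, 3))
            splits[name] = evaluate_split(params, ds, scaler)
            if name == "test":
                us_mean, us_sd = _time_rows(params, apply_scaler(ds.X, scaler), timing_rows)
            del ds

        results.append(
            FoldResult(
                test_subject=fold.test_subject,
                splits=splits,
                final_cost=float(trace.cost[-1]) if len(trace.cost) else float("nan"),
                n_iterations=len(trace.cost),
                train_seconds=train_seconds,
                inference_us_mean=us_mean,
                inference_us_sd=us_sd,
                params=params,
                scaler=scaler,
            )
        )
    return EvalReport(results, seg_cfg, train_cfg, channel_subset, seed)


def _time_rows(params: NetworkParams, X: np.ndarray, n: int) -> tuple[float, float]:
    if X.shape[0] == 0 or n <= 0:
        return float("nan"), float("nan")
    idx = np.arange(X.shape[0])[: max(1, n)]
    times = np.empty(len(idx))
    for j, r in enumerate(idx):
        row = X[r : r + 1]
        t0 = time.perf_counter()
        forward(params, row)
        times[j] = time.perf_counter() - t0
    return float(times.mean() * 1e6), float(times.std() * 1e6) if len(idx) > 1 else 0.0


@dataclass
class TimingSummary:
    preprocess_us_mean: float
    preprocess_us_sd: float
    inference_us_mean: float
    inference_us_sd: float


def time_pipeline(container: ModelContainer, circuits, n_samples: int = 1000) -> TimingSummary:
    """Wall-clock per-stacked-row preprocessing and inference times.

    Informational only: numbers depend on the host machine and are never
    compared against any reference.
    """
    cfg = container.seg_cfg
    triples: list[np.ndarray] = []
    for c in circuits:
        for run in remove_transitions(c, cfg):
            seg = c.samples[run.start : run.stop]
            starts, offs, idxs = window_starts(run.length, cfg)
            view = np.lib.stride_tricks.sliding_window_view(seg, cfg.window, axis=0)
            for p in range(cfg.n_passes):
                sel = starts[offs == p * cfg.shift]
                for t in range(cfg.context - 1, len(sel)):
                    triples.append(view[sel[t - cfg.context + 1 : t + 1]])  # [k, C, W]
                    if len(triples) >= n_samples:
                        break
                if len(triples) >= n_samples:
                    break
            if len(triples) >= n_samples:
                break
        if len(triples) >= n_samples:
            break
    if not triples:
        raise GaitannError("circuits yield no stacked rows at this configuration")

    pre = np.empty(len(triples))
    inf = np.empty(len(triples))
    for j, wins in enumerate(triples):
        t0 = time.perf_counter()
        feats = extract_features_batch(wins, median_mode=cfg.median_mode)
        row = feats.reshape(1, -1)
        row = apply_scaler(row, container.scaler)
        t1 = time.perf_counter()
        forward(container.params, row)
        t2 = time.perf_counter()
        pre[j] = t1 - t0
        inf[j] = t2 - t1
    sd = (lambda a: float(a.std()) if len(a) > 1 else 0.0)
    return TimingSummary(
        preprocess_us_mean=float(pre.mean() * 1e6),
        preprocess_us_sd=sd(pre) * 1e6,
        inference_us_mean=float(inf.mean() * 1e6),
        inference_us_sd=sd(inf) * 1e6,
    )
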