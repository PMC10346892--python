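"""Reading, writing and validating labeled multichannel circuit recordings.

A *motion circuit* is one continuous recording of a subject traversing a fixed
activity sequence; it is the atomic unit of train/validation/test splitting.
Circuits are exchanged as comma-delimited text with a header row and columns

    subject_id, circuit_id, sample_idx, <channel columns...>, label

where ``sample_idx`` is 0-based and contiguous within a circuit and ``label``
holds either activity names (``sitting`` ... ``stair_descent``) or their
integer codes 0-6.  One file may hold many circuits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    CANONICAL_CHANNEL_NAMES,
    ACTIVITY_NAMES,
    N_ACTIVITIES,
    resolve_channel_subset,
)
from .errors import EmptyInputError, LabelError, ParseError, SchemaError

META_COLUMNS = ("subject_id", "circuit_id", "sample_idx")
LABEL_COLUMN = "label"

DEFAULT_SAMPLE_RATE = 500.0


@dataclass
class Circuit:
    """One labeled multichannel recording of a single subject.

    ``samples`` is a ``[T, C]`` float array in the channel order given by
    ``channels``; ``labels`` is a length-``T`` integer vector of activity
    codes.  ``parity`` records which of the two activity-sequence variants the
    circuit follows.
    """

    subject_id: str
    circuit_id: str
    parity: str
    samples: np.ndarray
    labels: np.ndarray
    channels: tuple[str, ...]
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a [T, C] matrix")
        if self.samples.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"samples rows ({self.samples.shape[0]}) != labels length "
                f"({self.labels.shape[0]})"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("circuit must contain at least one sample")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError("samples columns != number of channels")
        if self.parity not in ("even", "odd"):
            raise ValueError("parity must be 'even' or 'odd'")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def select_channels(self, subset) -> "Circuit":
        """Project onto a named subset or explicit channel list (pure projection)."""
        names = resolve_channel_subset(subset)
        missing = set(names) - set(self.channels)
        if missing:
            raise KeyError(f"circuit lacks channels: {sorted(missing)}")
        idx = [self.channels.index(n) for n in names]
        return Circuit(
            subject_id=self.subject_id,
            circuit_id=self.circuit_id,
            parity=self.parity,
            samples=self.samples[:, idx],
            labels=self.labels,
            channels=names,
            sample_rate=self.sample_rate,
        )


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is 'fatal' or 'warning'."""

    severity: str
    code: str
    message: str
    channel: str | None = None
    index: int | None = None


def circuit_parity(circuit_id: str) -> str:
    """Infer even/odd parity from the trailing integer in a circuit id."""
    m = re.search(r"(\d+)\s*$", str(circuit_id))
    if m is None:
        return "even"
    return "even" if int(m.group(1)) % 2 == 0 else "odd"


def _parse_labels(raw: pd.Series, path) -> np.ndarray:
    from .channels import activity_from_label

    codes = np.empty(len(raw), dtype=np.int64)
    lookup: dict[object, int] = {}
    for pos, value in enumerate(raw.to_numpy()):
        if value not in lookup:
            try:
                lookup[value] = int(activity_from_label(value))
            except ValueError as exc:
                raise LabelError(f"{path}: row {pos}: {exc}") from None
        codes[pos] = lookup[value]
    return codes


def read_circuits(path, channel_subset="all") -> list[Circuit]:
    """Read all circuits from a delimited-text file.

    Circuits are returned grouped by ``(subject_id, circuit_id)`` in order of
    first appearance, with sample columns restricted to ``channel_subset``
    (a subset name or explicit channel-name list) in canonical order.
    """
    names = resolve_channel_subset(channel_subset)
    try:
        df = pd.read_csv(
            path,
            dtype={"subject_id": str, "circuit_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty file") from None
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    required = list(META_COLUMNS) + list(names) + [LABEL_COLUMN]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    values = np.empty((len(df), len(names)), dtype=float)
    for j, col in enumerate(names):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: column {col!r}, row {row}: "
                f"non-numeric sample {df[col].iloc[row]!r}"
            )
        values[:, j] = numeric.to_numpy()

    labels = _parse_labels(df[LABEL_COLUMN], path)

    circuits: list[Circuit] = []
    keys = list(zip(df["subject_id"].to_numpy(), df["circuit_id"].to_numpy()))
    order: dict[tuple, np.ndarray] = {}
    for pos, key in enumerate(keys):
        order.setdefault(key, []).append(pos)
    for (subject_id, circuit_id), rows in order.items():
        rows = np.asarray(rows)
        circuits.append(
            Circuit(
                subject_id=str(subject_id),
                circuit_id=str(circuit_id),
                parity=circuit_parity(circuit_id),
                samples=values[rows],
                labels=labels[rows],
                channels=names,
            )
        )
    return circuits


def write_circuits(circuits, path) -> None:
    """Write circuits to the delimited-text schema (round-trips bitwise)."""
    circuits = list(circuits)
    if not circuits:
        raise EmptyInputError("no circuits to write")
    channels = circuits[0].channels
    frames = []
    for c in circuits:
        if c.channels != channels:
            raise SchemaError("all circuits in one file must share a channel set")
        frame = pd.DataFrame(c.samples, columns=list(channels))
        frame.insert(0, "sample_idx", np.arange(c.n_samples))
        frame.insert(0, "circuit_id", c.circuit_id)
        frame.insert(0, "subject_id", c.subject_id)
        frame[LABEL_COLUMN] = [ACTIVITY_NAMES[k] for k in c.labels]
        frames.append(frame)
    # %.17g round-trips any float64 exactly through text
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def validate_circuit(circuit: Circuit, window_size: int = 25) -> list[Finding]:
    """Check a circuit for defects that would corrupt downstream processing.

    Returns findings rather than raising; circuits with any ``fatal`` finding
    must be excluded by callers.
    """
    findings: list[Finding] = []

    bad = ~np.isfinite(circuit.samples)
    if bad.any():
        t, ch = np.argwhere(bad)[0]
        findings.append(
            Finding(
                "fatal",
                "non_finite_sample",
                f"non-finite sample at index {t}, channel "
                f"{circuit.channels[ch]} ({int(bad.sum())} total)",
                channel=circuit.channels[ch],
                index=int(t),
            )
        )

    out = (circuit.labels < 0) | (circuit.labels >= N_ACTIVITIES)
    if out.any():
        t = int(np.flatnonzero(out)[0])
        findings.append(
            Finding(
                "fatal",
                "label_out_of_range",
                f"label code {circuit.labels[t]} at index {t} outside 0-6",
                index=t,
            )
        )

    if circuit.n_samples < window_size:
        findings.append(
            Finding(
                "fatal",
                "too_short",
                f"circuit has {circuit.n_samples} samples, fewer than one "
                f"{window_size}-sample window",
            )
        )
    return findings
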