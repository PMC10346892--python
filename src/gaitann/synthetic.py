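"""Synthetic gait-circuit generator.

Emulates the statistical structure of lower-limb wearable recordings of a
subject traversing a fixed activity circuit: each activity imprints a
channel-specific periodic signature (baseline offset + fundamental sinusoid +
one harmonic + Gaussian noise), subjects differ by multiplicative amplitude
and cadence scales plus additive per-channel offsets, and each circuit
concatenates one labeled segment per element of the even- or odd-parity
activity sequence:

* even circuits: sitting, standing, walking, ramp ascent, walking,
  stair descent, walking, standing, sitting;
* odd circuits: the reverse variant with stair ascent and ramp descent.

The default per-(activity, channel) parameters ship in
``data/activity_profiles.csv`` (units: accelerometers m/s^2, gyroscopes
deg/s, goniometers deg) so tests can pin exact values.  This is a statistical
stand-in, not a biomechanical simulation: segments switch abruptly and there
are no transitional kinematics (the preprocessor removes activity boundaries
anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .channels import (
    ACTIVITY_NAMES,
    CANONICAL_CHANNEL_NAMES,
    N_ACTIVITIES,
    Activity,
)
from .errors import ConfigurationError
from .ingest import Circuit, DEFAULT_SAMPLE_RATE

EVEN_SEQUENCE: tuple[Activity, ...] = (
    Activity.SITTING,
    Activity.STANDING,
    Activity.WALKING,
    Activity.RAMP_ASCENT,
    Activity.WALKING,
    Activity.STAIR_DESCENT,
    Activity.WALKING,
    Activity.STANDING,
    Activity.SITTING,
)
ODD_SEQUENCE: tuple[Activity, ...] = (
    Activity.SITTING,
    Activity.STANDING,
    Activity.WALKING,
    Activity.STAIR_ASCENT,
    Activity.WALKING,
    Activity.RAMP_DESCENT,
    Activity.WALKING,
    Activity.STANDING,
    Activity.SITTING,
)


def activity_sequence(parity: str) -> tuple[Activity, ...]:
    """The fixed activity sequence for even- or odd-numbered circuits."""
    if parity == "even":
        return EVEN_SEQUENCE
    if parity == "odd":
        return ODD_SEQUENCE
    raise ValueError("parity must be 'even' or 'odd'")


@dataclass(frozen=True)
class ActivityProfile:
    """Signal parameters for one (activity, channel) pair."""

    activity: Activity
    channel: str
    offset: float
    amplitude: float
    freq_hz: float
    harmonic_ratio: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.freq_hz < 0:
            raise ValueError("freq_hz must be >= 0")


ProfileSet = dict[tuple[Activity, str], ActivityProfile]


def default_profiles() -> ProfileSet:
    """Load the packaged default activity/channel profile table."""
    with resources.files("gaitann.data").joinpath("activity_profiles.csv").open() as fh:
        table = pd.read_csv(fh)
    return profiles_from_table(table)


def profiles_from_table(table: pd.DataFrame) -> ProfileSet:
    profiles: ProfileSet = {}
    for row in table.itertuples(index=False):
        act = Activity(ACTIVITY_NAMES.index(row.activity))
        profiles[(act, row.channel)] = ActivityProfile(
            activity=act,
            channel=row.channel,
            offset=float(row.offset),
            amplitude=float(row.amplitude),
            freq_hz=float(row.freq_hz),
            harmonic_ratio=float(row.harmonic_ratio),
            noise_sd=float(row.noise_sd),
        )
    return profiles


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-level variation applied on top of the activity profiles.

    ``offset_shift`` maps channel name to an additive baseline perturbation;
    scales multiply amplitudes and gait frequencies.
    """

    subject_id: str
    amplitude_scale: float
    frequency_scale: float
    offset_shift: dict[str, float]

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0 or self.frequency_scale <= 0:
            raise ValueError("subject scales must be positive")


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic data generation.

    Defaults mirror the recording protocol being emulated: 8 subjects with 10
    circuits each (alternating parity), 500 Hz sampling, activity segments
    lasting 4-10 s.  The spread parameters set the scale of inter-subject
    variability: amplitude and cadence scales are log-normal with the given
    log-sd, and per-channel offset shifts are Gaussian with sd equal to
    ``offset_spread`` times a channel-specific scale (the dispersion of that
    channel's per-activity baselines).
    """

    n_subjects: int = 8
    circuits_per_subject: int = 10
    segment_duration_range: tuple[float, float] = (4.0, 10.0)
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0
    amplitude_spread: float = 0.25
    frequency_spread: float = 0.12
    offset_spread: float = 0.70

    def __post_init__(self) -> None:
        lo, hi = self.segment_duration_range
        if self.n_subjects < 1 or self.circuits_per_subject < 1:
            raise ValueError("counts must be >= 1")
        if not (0 < lo <= hi):
            raise ValueError("segment duration range must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


def _channel_offset_scales(profiles: ProfileSet, channels) -> dict[str, float]:
    """Per-channel scale used for subject offset shifts.

    The dispersion of a channel's per-activity baselines, floored at a
    fraction of its largest amplitude, so channels whose baselines coincide
    across activities (e.g. zero-mean gyroscopes) still vary across subjects.
    """
    scales = {}
    for ch in channels:
        offs = np.array([profiles[(Activity(a), ch)].offset for a in range(N_ACTIVITIES)])
        amps = np.array([profiles[(Activity(a), ch)].amplitude for a in range(N_ACTIVITIES)])
        scales[ch] = max(float(offs.std()), 0.15 * float(amps.max()))
    return scales


def draw_subject_profile(
    subject_id: str,
    cfg: GeneratorConfig,
    profiles: ProfileSet,
    rng: np.random.Generator,
    channels=CANONICAL_CHANNEL_NAMES,
) -> SubjectProfile:
    scales = _channel_offset_scales(profiles, channels)
    amplitude_scale = float(np.exp(rng.normal(0.0, cfg.amplitude_spread)))
    frequency_scale = float(np.exp(rng.normal(0.0, cfg.frequency_spread)))
    offset_shift = {
        ch: float(rng.normal(0.0, cfg.offset_spread * scales[ch])) for ch in channels
    }
    return SubjectProfile(subject_id, amplitude_scale, frequency_scale, offset_shift)


def _check_coverage(profiles: ProfileSet, channels) -> None:
    for a in range(N_ACTIVITIES):
        for ch in channels:
            if (Activity(a), ch) not in profiles:
                raise ConfigurationError(
                    f"profile set lacks (activity={ACTIVITY_NAMES[a]}, channel={ch})"
                )


def generate_circuit(
    subject: SubjectProfile,
    circuit_id: str,
    parity: str,
    profiles: ProfileSet,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    channels=CANONICAL_CHANNEL_NAMES,
    durations=None,
) -> Circuit:
    """Generate one labeled circuit for a subject.

    Each segment's channel signal is ``offset + offset_shift +
    a*sin(2*pi*f*t + phi) + harmonic_ratio*a*sin(4*pi*f*t + 2*phi) + noise``
    with amplitude ``a`` and frequency ``f`` scaled by the subject profile and
    the phase ``phi`` drawn independently per (segment, channel).  Labels are
    constant within a segment.
    """
    channels = tuple(channels)
    _check_coverage(profiles, channels)
    sequence = activity_sequence(parity)
    lo, hi = cfg.segment_duration_range
    if durations is None:
        durations = rng.uniform(lo, hi, size=len(sequence))
    else:
        durations = np.asarray(durations, dtype=float)
        if durations.shape != (len(sequence),):
            raise ValueError("durations must have one entry per sequence segment")

    seg_samples = [int(round(d * cfg.sample_rate)) for d in durations]
    blocks = []
    labels = []
    for act, n in zip(sequence, seg_samples):
        t = np.arange(n) / cfg.sample_rate
        seg = np.empty((n, len(channels)))
        for j, ch in enumerate(channels):
            p = profiles[(act, ch)]
            amp = p.amplitude * subject.amplitude_scale
            base = p.offset + subject.offset_shift.get(ch, 0.0)
            if p.freq_hz > 0:
                f = p.freq_hz * subject.frequency_scale
                phi = rng.uniform(0.0, 2.0 * np.pi)
                wave = amp * np.sin(2.0 * np.pi * f * t + phi)
                wave += p.harmonic_ratio * amp * np.sin(4.0 * np.pi * f * t + 2.0 * phi)
            else:
                wave = 0.0
            noise = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else 0.0
            seg[:, j] = base + wave + noise
        blocks.append(seg)
        labels.append(np.full(n, int(act), dtype=np.int64))

    return Circuit(
        subject_id=subject.subject_id,
        circuit_id=circuit_id,
        parity=parity,
        samples=np.vstack(blocks),
        labels=np.concatenate(labels),
        channels=channels,
        sample_rate=cfg.sample_rate,
    )


def generate_dataset(
    cfg: GeneratorConfig,
    profiles: ProfileSet | None = None,
    channels=CANONICAL_CHANNEL_NAMES,
) -> list[Circuit]:
    """Generate the full synthetic study: all subjects, alternating parity.

    Fully reproducible from ``cfg.seed``: subject profiles are drawn once per
    subject and each circuit uses its own spawned random stream.
    """
    if profiles is None:
        profiles = default_profiles()
    channels = tuple(channels)
    _check_coverage(profiles, channels)

    root = np.random.SeedSequence(cfg.seed)
    subject_seq, circuit_seq = root.spawn(2)
    subject_streams = subject_seq.spawn(cfg.n_subjects)
    circuit_streams = circuit_seq.spawn(cfg.n_subjects * cfg.circuits_per_subject)

    circuits: list[Circuit] = []
    k = 0
    for i in range(cfg.n_subjects):
        subject_id = f"S{i + 1:02d}"
        subject = draw_subject_profile(
            subject_id, cfg, profiles, np.random.default_rng(subject_streams[i]), channels
        )
        for j in range(cfg.circuits_per_subject):
            parity = "even" if j % 2 == 0 else "odd"
            circuits.append(
                generate_circuit(
                    subject,
                    circuit_id=f"C{j:02d}",
                    parity=parity,
                    profiles=profiles,
                    cfg=cfg,
                    rng=np.random.default_rng(circuit_streams[k]),
                    channels=channels,
                )
            )
            k += 1
    return circuits
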