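"""Domain types and preprocessing for multi-axial movement recordings.

A movement instance is recorded by ``G`` multi-axial sensors; sensor ``g``
has ``m_g`` uniaxial channels, each a real-valued time series sampled at a
fixed rate.  Classifiers consume one of four *input models* built from a
recording:

- ``VI``  (vector input):        the ``M_G = sum(m_g)`` raw channel vectors;
- ``LMI`` (local matrix input):  one ``(m_g x n_g)`` matrix per sensor;
- ``GMI`` (global matrix input): one ``(M_G x N)`` matrix over all channels;
- ``GCI`` (global cuboid input): one ``(M x N x G)`` cuboid (requires all
  sensors to have the same number of channels ``M``).

Matrix/cuboid models require equal channel durations, which real segmented
movements do not have; durations are therefore normalized to common target
lengths by linear expansion/compression, with targets learned from a
training set (rounded mean durations).  Amplitudes can optionally be
min-max normalized per channel using training-set extrema.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MODEL_TAGS",
    "UniaxialSignal",
    "MovementRecording",
    "FusedInput",
    "NormalizationSpec",
    "duration_normalize",
    "compute_target_lengths",
    "minmax_fit",
    "minmax_apply",
    "build_input",
    "segment_energy",
    "save_recording",
    "load_recording",
    "save_ensemble",
    "load_ensemble",
]

MODEL_TAGS = ("VI", "LMI", "GMI", "GCI")


class DegenerateAxisError(ValueError):
    """A channel has constant amplitude over the training set (min == max)."""


class ModelNotApplicableError(ValueError):
    """The requested input model cannot be built for this sensor layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniaxialSignal:
    """One channel ``s_gm`` of one movement: sensor ``g``, axis ``m``.

    Sensor and axis indices are 0-based internally; reports print them
    1-based to match the field's notation.
    """

    sensor: int
    axis: int
    samples: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a uniaxial signal needs >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError(
                f"non-finite samples in channel (g={self.sensor}, m={self.axis})"
            )
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class MovementRecording:
    """One movement instance: all channels of all sensors, optional label.

    Labels are class identifiers in ``1..H`` (``None`` for unlabeled test
    input).  Every ``(sensor, axis)`` pair must appear exactly once.
    """

    signals: list[UniaxialSignal]
    label: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [(s.sensor, s.axis) for s in self.signals]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sensor, axis) channel in recording")
        if self.label is not None and self.label < 1:
            raise ValueError("class labels are 1-based positive integers")
        self.signals = sorted(self.signals, key=lambda s: (s.sensor, s.axis))

    @property
    def sensors(self) -> list[int]:
        return sorted({s.sensor for s in self.signals})

    @property
    def axes_per_sensor(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.signals:
            out[s.sensor] = out.get(s.sensor, 0) + 1
        return out

    @property
    def n_channels(self) -> int:
        return len(self.signals)

    def channel(self, sensor: int, axis: int) -> UniaxialSignal:
        for s in self.signals:
            if s.sensor == sensor and s.axis == axis:
                return s
        raise KeyError(f"no channel (g={sensor}, m={axis})")

    def channel_keys(self) -> list[tuple[int, int]]:
        """Channel identifiers in sensor-major order."""
        return [(s.sensor, s.axis) for s in self.signals]

    def restrict(self, sensor: int, axis: int) -> "MovementRecording":
        """Single-channel view of this recording (for uniaxial baselines)."""
        return MovementRecording(
            signals=[self.channel(sensor, axis)],
            label=self.label,
            metadata=dict(self.metadata),
        )


@dataclass
class FusedInput:
    """A recording rendered in one of the four classifier input models."""

    model_tag: str
    payload: object  # VI: list of 1-d arrays; LMI: list of 2-d; GMI: 2-d; GCI: 3-d

    def __post_init__(self):
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model_tag!r}")


@dataclass
class NormalizationSpec:
    """Training-set statistics needed to build inputs reproducibly.

    ``channel_targets``/``sensor_targets``/``global_target`` are the rounded
    mean durations at channel, sensor, and global granularity; which one a
    model uses is decided in :func:`build_input`.  ``minmax`` maps channel
    key ``(g, m)`` to training extrema ``(lo, hi)``.
    """

    amplitude_mode: str = "none"  # "none" | "minmax_per_axis"
    minmax: dict = field(default_factory=dict)
    channel_targets: dict = field(default_factory=dict)
    sensor_targets: dict = field(default_factory=dict)
    global_target: int | None = None


# ---------------------------------------------------------------------------
# Duration normalization
# ---------------------------------------------------------------------------

def duration_normalize(signal: UniaxialSignal, target_len: int) -> UniaxialSignal:
    """Linearly expand/compress a channel to exactly ``target_len`` samples.

    Values are obtained by piecewise-linear interpolation on a uniform
    re-parameterization of the original index range; the first and last
    samples are preserved exactly.
    """
    if target_len < 2:
        raise ValueError("target length must be >= 2")
    x = signal.samples
    if x.size == target_len:
        return signal
    pos = np.linspace(0.0, x.size - 1.0, target_len)
    y = np.interp(pos, np.arange(x.size), x)
    return UniaxialSignal(signal.sensor, signal.axis, y, signal.sample_rate)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def compute_target_lengths(
    train: Sequence[MovementRecording],
    model_tag: str = "GMI",
    amplitude_mode: str = "none",
) -> NormalizationSpec:
    """Learn common duration targets (rounded means) from a training set.

    All three granularities are recorded: per-channel means (used for VI
    template averaging and per-channel CNNs), per-sensor means (LMI), and
    the global mean over every channel of every recording (GMI/GCI).
    Rounding is half-away-from-zero so targets are deterministic.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    if not train:
        raise ValueError("empty training set")
    per_channel: dict[tuple[int, int], list[int]] = {}
    per_sensor: dict[int, list[int]] = {}
    all_lens: list[int] = []
    for rec in train:
        for s in rec.signals:
            per_channel.setdefault((s.sensor, s.axis), []).append(len(s))
            per_sensor.setdefault(s.sensor, []).append(len(s))
            all_lens.append(len(s))
    spec = NormalizationSpec(amplitude_mode=amplitude_mode)
    spec.channel_targets = {
        k: max(2, _round_half_away(float(np.mean(v)))) for k, v in per_channel.items()
    }
    spec.sensor_targets = {
        g: max(2, _round_half_away(float(np.mean(v)))) for g, v in per_sensor.items()
    }
    spec.global_target = max(2, _round_half_away(float(np.mean(all_lens))))
    return spec


# ---------------------------------------------------------------------------
# Amplitude normalization
# ---------------------------------------------------------------------------

def minmax_fit(
    train: Sequence[MovementRecording],
    spec: NormalizationSpec | None = None,
) -> NormalizationSpec:
    """Learn per-channel min/max pooled over the whole training set."""
    if not train:
        raise ValueError("empty training set")
    spec = spec or NormalizationSpec()
    spec.amplitude_mode = "minmax_per_axis"
    lo: dict[tuple[int, int], float] = {}
    hi: dict[tuple[int, int], float] = {}
    for rec in train:
        for s in rec.signals:
            k = (s.sensor, s.axis)
            lo[k] = min(lo.get(k, np.inf), float(s.samples.min()))
            hi[k] = max(hi.get(k, -np.inf), float(s.samples.max()))
    for k in lo:
        if lo[k] == hi[k]:
            raise DegenerateAxisError(
                f"channel (g={k[0]}, m={k[1]}) is constant over the training set"
            )
    spec.minmax = {k: (lo[k], hi[k]) for k in lo}
    return spec


def minmax_apply(signal: UniaxialSignal, spec: NormalizationSpec) -> UniaxialSignal:
    """Map samples to ``(x - lo) / (hi - lo)`` using fitted training extrema.

    Test values outside the training range are not clipped and may fall
    outside ``[0, 1]``.
    """
    k = (signal.sensor, signal.axis)
    if k not in spec.minmax:
        raise KeyError(f"no fitted min/max for channel (g={k[0]}, m={k[1]})")
    lo, hi = spec.minmax[k]
    y = (signal.samples - lo) / (hi - lo)
    return UniaxialSignal(signal.sensor, signal.axis, y, signal.sample_rate)


# ---------------------------------------------------------------------------
# Input-model construction
# ---------------------------------------------------------------------------

def _prep_channel(
    sig: UniaxialSignal, spec: NormalizationSpec, target_len: int | None
) -> np.ndarray:
    if spec.amplitude_mode == "minmax_per_axis":
        sig = minmax_apply(sig, spec)
    if target_len is not None:
        sig = duration_normalize(sig, target_len)
    return sig.samples


def build_input(
    rec: MovementRecording,
    model_tag: str,
    spec: NormalizationSpec,
    normalize_vi_durations: bool = False,
) -> FusedInput:
    """Render a recording in one of the four input models.

    Row order in GMI (and depth order in GCI) is sensor-major then axis;
    any fixed order works but it must match between train and test time,
    so it is fixed here once.  VI keeps raw durations unless
    ``normalize_vi_durations`` is set (template averaging and per-channel
    CNNs need equal lengths across trials).
    """
    if model_tag == "VI":
        vecs = []
        for s in rec.signals:
            t = spec.channel_targets.get((s.sensor, s.axis)) if normalize_vi_durations else None
            vecs.append(_prep_channel(s, spec, t))
        return FusedInput("VI", vecs)
    if model_tag == "LMI":
        mats = []
        for g in rec.sensors:
            t = spec.sensor_targets.get(g)
            if t is None:
                raise KeyError(f"no duration target for sensor {g}")
            rows = [
                _prep_channel(s, spec, t) for s in rec.signals if s.sensor == g
            ]
            mats.append(np.vstack(rows))
        return FusedInput("LMI", mats)
    if model_tag == "GMI":
        if spec.global_target is None:
            raise KeyError("no global duration target fitted")
        rows = [_prep_channel(s, spec, spec.global_target) for s in rec.signals]
        return FusedInput("GMI", np.vstack(rows))
    if model_tag == "GCI":
        axes = rec.axes_per_sensor
        if len(set(axes.values())) != 1:
            raise ModelNotApplicableError(
                "GCI requires every sensor to have the same number of axes; "
                f"got {axes}"
            )
        if spec.global_target is None:
            raise KeyError("no global duration target fitted")
        frames = []
        for g in rec.sensors:
            rows = [
                _prep_channel(s, spec, spec.global_target)
                for s in rec.signals
                if s.sensor == g
            ]
            frames.append(np.vstack(rows))
        # cuboid (M, N, G): depth-frame g is the sensor-g local matrix
        return FusedInput("GCI", np.stack(frames, axis=-1))
    raise ValueError(f"unknown model tag {model_tag!r}")


# ---------------------------------------------------------------------------
# Energy-based segmentation
# ---------------------------------------------------------------------------

def segment_energy(
    signals: Sequence[UniaxialSignal] | np.ndarray,
    window: int = 10,
    threshold_frac: float = 0.1,
    min_gap: int = 10,
) -> list[tuple[int, int]]:
    """Locate movement segments in a continuous multi-channel stream.

    Short-time energy (squared amplitude summed over all channels, then
    over a sliding rectangular window) is compared against a fraction of
    its global peak; maximal runs at or above the threshold become
    segments, and runs closer than ``min_gap`` samples are merged.
    Returns half-open ``[start, end)`` 0-based sample intervals.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must be in (0, 1)")
    if isinstance(signals, np.ndarray):
        arr = np.atleast_2d(np.asarray(signals, dtype=float))
    else:
        arr = np.vstack([s.samples for s in signals])
    power = (arr ** 2).sum(axis=0)
    energy = np.convolve(power, np.ones(window), mode="same")
    peak = energy.max()
    if peak <= 0.0:
        return []
    active = energy >= threshold_frac * peak
    # maximal runs of active samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    runs = list(zip(edges[0::2], edges[1::2]))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([int(a), int(b)])
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------------------
# On-disk formats: one CSV per recording + JSON manifest, or an NPZ container
# ---------------------------------------------------------------------------

def save_recording(rec: MovementRecording, csv_path: str | Path) -> None:
    """Write ``sensor,axis,t,value`` rows plus a ``.json`` sidecar manifest."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["sensor", "axis", "t", "value"])
        for s in rec.signals:
            for t, v in enumerate(s.samples):
                wr.writerow([s.sensor, s.axis, t, repr(float(v))])
    manifest = {
        "label": rec.label,
        "sample_rate": rec.signals[0].sample_rate if rec.signals else None,
        "metadata": rec.metadata,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_recording(csv_path: str | Path) -> MovementRecording:
    csv_path = Path(csv_path)
    manifest_path = csv_path.with_suffix(".json")
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    rate = manifest.get("sample_rate") or 100.0
    series: dict[tuple[int, int], list[float]] = {}
    with open(csv_path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header[:4] != ["sensor", "axis", "t", "value"]:
            raise ValueError(f"{csv_path}: malformed header {header!r} at row 1")
        for i, row in enumerate(rd, start=2):
            try:
                g, m, _, v = int(row[0]), int(row[1]), int(row[2]), float(row[3])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{csv_path}: malformed row {i}: {row!r}") from exc
            series.setdefault((g, m), []).append(v)
    signals = [
        UniaxialSignal(g, m, np.asarray(v), rate) for (g, m), v in sorted(series.items())
    ]
    return MovementRecording(signals, label=manifest.get("label"),
                             metadata=manifest.get("metadata", {}))


def save_ensemble(recs: Sequence[MovementRecording], path: str | Path) -> None:
    """Single-container NPZ archive holding many recordings (fast path)."""
    arrays: dict[str, np.ndarray] = {}
    meta = []
    for i, rec in enumerate(recs):
        for s in rec.signals:
            arrays[f"r{i}_g{s.sensor}_m{s.axis}"] = s.samples
        meta.append({
            "label": rec.label,
            "sample_rate": rec.signals[0].sample_rate,
            "metadata": rec.metadata,
            "channels": rec.channel_keys(),
        })
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_ensemble(path: str | Path) -> list[MovementRecording]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        recs = []
        for i, m in enumerate(meta):
            signals = [
                UniaxialSignal(g, a, data[f"r{i}_g{g}_m{a}"], m["sample_rate"])
                for g, a in m["channels"]
            ]
            recs.append(MovementRecording(signals, label=m["label"],
                                          metadata=m["metadata"]))
    return recs
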