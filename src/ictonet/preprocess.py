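"""Recording ingestion, stage segmentation and variable-table assembly.

A recording is a multichannel local-field-potential trace (thalamus TH,
hippocampus HP, parietal cortex CX by default) sampled at 1 kHz.  An
annotation marks the onset of each experimental stage — basal state, drug
infusion, myoclonic seizure (MYO) and, for the animals that reach it,
generalized tonic-clonic seizure (GTCS).  Each stage becomes a *time slice*;
every (channel, slice) pair becomes one variable of the unrolled dynamic
Bayesian network.  Because slices have unequal durations, every slice epoch
is linearly resampled to the length of the animal's longest slice so the
variables can share a common row index.

Conventions
-----------
* Timestamps are seconds; conversion to sample index is ``floor(t * rate)``.
* Slice epochs are half-open ``[start, end)`` in sample index, so adjacent
  slices are disjoint.
* Samples after the annotated recording end (the post-GTCS refractory
  period) are always discarded: that interval does not represent any stage.
* Animals that never reach GTCS simply lack the GTCS variables; missing
  slices are omitted, not NaN-padded, so downstream structure learning for
  the MYO group runs on a 9-variable table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AnnotationError, FormatError, StructuralError

#: Canonical stage order of the acute PTZ protocol.
SLICES: tuple[str, ...] = ("basal", "infusion", "myo", "gtcs")

#: Canonical channel order: thalamus, dorsal hippocampus, parietal cortex.
CHANNELS: tuple[str, ...] = ("TH", "HP", "CX")


class Group(str, Enum):
    """Experimental group: recordings end at MYO or include GTCS."""

    MYO_GROUP = "MYO_GROUP"
    GTCS_GROUP = "GTCS_GROUP"


@dataclass(frozen=True)
class SliceSchema:
    """Total order over time slices and the Markov-order bound.

    ``markov_order_limit`` of ``None`` means unbounded: an arc may reach
    forward across any number of slices.  With a bound *m*, a variable may
    depend only on variables at most *m* slices earlier.
    """

    ordered_slices: tuple[str, ...] = SLICES
    markov_order_limit: int | None = None

    def __post_init__(self) -> None:
        if self.markov_order_limit is not None and self.markov_order_limit < 1:
            raise ValueError("markov_order_limit must be >= 1 when bounded")
        if len(set(self.ordered_slices)) != len(self.ordered_slices):
            raise ValueError("slice order must be a total order (no repeats)")

    def slice_of(self, node: str) -> str:
        """Slice label of a ``<channel>_<slice>`` variable name."""
        _, _, sl = node.rpartition("_")
        if sl not in self.ordered_slices:
            raise StructuralError(f"node {node!r} has unknown slice {sl!r}")
        return sl

    def slice_index(self, node: str) -> int:
        return self.ordered_slices.index(self.slice_of(node))

    def allows_arc(self, u: str, v: str) -> bool:
        """Temporal precedence: never backward in time, never beyond the
        Markov-order bound; intra-slice arcs are unconstrained."""
        if u == v:
            return False
        si, sj = self.slice_index(u), self.slice_index(v)
        if si > sj:
            return False
        if self.markov_order_limit is not None and sj - si > self.markov_order_limit:
            return False
        return True


@dataclass
class Recording:
    animal_id: str
    group: Group
    sample_rate: float
    channels: tuple[str, ...]
    samples: np.ndarray  # (n_channels, n_time), arbitrary field-potential units

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.group = Group(self.group)
        self.channels = tuple(self.channels)
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise FormatError("samples must be a (channels x time) matrix")
        if len(self.channels) < 2:
            raise FormatError("at least two channels are required")
        if np.isnan(self.samples).any():
            raise FormatError("missing values inside a channel row")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate


@dataclass
class StageAnnotation:
    """Stage-onset timestamps (seconds) plus the annotated recording end."""

    animal_id: str
    group: Group
    starts: dict[str, float]  # slice label -> onset, in protocol order
    recording_end: float

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        unknown = set(self.starts) - set(SLICES)
        if unknown:
            raise AnnotationError(f"unknown slice labels {sorted(unknown)}")
        self.starts = {sl: float(self.starts[sl]) for sl in SLICES if sl in self.starts}
        has_gtcs = "gtcs" in self.starts
        if has_gtcs != (self.group is Group.GTCS_GROUP):
            raise AnnotationError(
                "GTCS onset must be present iff the animal is in the GTCS group"
            )
        times = list(self.starts.values()) + [self.recording_end]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise AnnotationError("stage timestamps must be strictly increasing "
                                  "and every slice must have positive duration")

    @property
    def slice_labels(self) -> tuple[str, ...]:
        return tuple(self.starts)

    def bounds(self) -> dict[str, tuple[float, float]]:
        """Per-slice (start, end) in seconds; a slice ends where the next
        starts, the last at the annotated recording end."""
        labels = list(self.starts)
        ends = [self.starts[s] for s in labels[1:]] + [self.recording_end]
        return {s: (self.starts[s], e) for s, e in zip(labels, ends)}


@dataclass
class VariableTable:
    """Per-animal table whose columns are (channel, slice) variables on a
    common resampled row index of length ``target_length``."""

    animal_id: str
    frame: pd.DataFrame
    target_length: int

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading


def load_recording(signal_path: str | Path,
                   annotation_path: str | Path) -> tuple[Recording, StageAnnotation]:
    """Read a delimited signal file and its stage-annotation document.

    The signal file is CSV (optionally gzip-compressed) with one header row
    of channel labels and one row per sample.  The annotation is a YAML/JSON
    key-value document with keys ``animal_id``, ``group``, ``basal_start``,
    ``infusion_start``, ``myo_start``, optional ``gtcs_start`` and
    ``recording_end``, all times in seconds.
    """
    try:
        frame = pd.read_csv(signal_path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read signal file {signal_path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise FormatError("signal file must contain at least two channel columns")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric data in {signal_path}: {exc}") from exc

    with open(annotation_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise AnnotationError(f"{annotation_path} is not a key/value document")
    missing = {"animal_id", "group", "recording_end"} - set(doc)
    if missing:
        raise AnnotationError(f"annotation lacks keys {sorted(missing)}")
    starts = {sl: float(doc[f"{sl}_start"]) for sl in SLICES if f"{sl}_start" in doc}
    ann = StageAnnotation(
        animal_id=str(doc["animal_id"]),
        group=Group(doc["group"]),
        starts=starts,
        recording_end=float(doc["recording_end"]),
    )
    rate = float(doc.get("sample_rate", 1000.0))
    rec = Recording(
        animal_id=ann.animal_id,
        group=ann.group,
        sample_rate=rate,
        channels=tuple(frame.columns),
        samples=values.T,
    )
    if ann.recording_end > rec.duration + 0.5 / rate:
        raise AnnotationError(
            f"annotated end {ann.recording_end} s exceeds recording "
            f"duration {rec.duration} s"
        )
    return rec, ann


# ---------------------------------------------------------------------------
# segmentation / resampling / assembly


def segment_epochs(rec: Recording, ann: StageAnnotation) -> dict[str, np.ndarray]:
    """Cut each channel into per-slice epochs.

    Each slice covers the half-open sample interval
    ``[floor(start * rate), floor(end * rate))``.  Samples after the
    annotated end (post-GTCS refractory period) are discarded.
    """
    if ann.animal_id != rec.animal_id or ann.group is not rec.group:
        raise AnnotationError("annotation does not match recording")
    n = rec.samples.shape[1]
    epochs: dict[str, np.ndarray] = {}
    for sl, (t0, t1) in ann.bounds().items():
        i0 = math.floor(t0 * rec.sample_rate)
        i1 = math.floor(t1 * rec.sample_rate)
        i1 = min(i1, n)
        if i1 - i0 < 1:
            raise AnnotationError(f"slice {sl!r} is empty")
        epochs[sl] = rec.samples[:, i0:i1].copy()
    return epochs


def resample_epoch(x: np.ndarray, target: int) -> np.ndarray:
    """Piecewise-linear resampling of ``x`` onto ``target`` evenly spaced
    points over the same support; first and last values are preserved
    exactly."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("resample_epoch expects a 1-D vector")
    n = x.size
    if n < 2:
        raise AnnotationError("degenerate epoch: need at least 2 samples")
    if target < 2:
        raise ValueError("target length must be >= 2")
    if target == n:
        return x.copy()
    return np.interp(np.linspace(0.0, n - 1.0, target), np.arange(n), x)


def assemble_table(epochs: Mapping[str, np.ndarray],
                   schema: SliceSchema = SliceSchema(),
                   channels: Sequence[str] = CHANNELS,
                   animal_id: str = "") -> VariableTable:
    """Build the per-animal variable table from slice epochs.

    Columns are ordered slice-major then channel (``TH_basal, HP_basal, ...,
    CX_gtcs``); every column is resampled to the length of the animal's
    longest slice.  Slices the animal never reached are simply absent, so a
    GTCS-group animal with three channels yields 12 columns and a MYO-group
    animal 9.
    """
    present = [sl for sl in schema.ordered_slices if sl in epochs]
    if not present:
        raise StructuralError("no known slices in epochs")
    n_ch = len(channels)
    for sl in present:
        if epochs[sl].shape[0] != n_ch:
            raise StructuralError(
                f"slice {sl!r} has {epochs[sl].shape[0]} channels, expected {n_ch}"
            )
    target = max(epochs[sl].shape[1] for sl in present)
    data: dict[str, np.ndarray] = {}
    for sl in present:
        for ci, ch in enumerate(channels):
            data[f"{ch}_{sl}"] = resample_epoch(epochs[sl][ci], target)
    return VariableTable(animal_id=animal_id,
                         frame=pd.DataFrame(data),
                         target_length=target)


def preprocess_recording(rec: Recording, ann: StageAnnotation,
                         schema: SliceSchema = SliceSchema()) -> VariableTable:
    """Convenience: segment, resample and assemble in one call."""
    table = assemble_table(segment_epochs(rec, ann), schema,
                           channels=rec.channels, animal_id=rec.animal_id)
    return table


def write_annotation(ann: StageAnnotation, path: str | Path,
                     sample_rate: float = 1000.0) -> None:
    doc = {"animal_id": ann.animal_id, "group": ann.group.value,
           "sample_rate": float(sample_rate),
           **{f"{sl}_start": float(t) for sl, t in ann.starts.items()},
           "recording_end": float(ann.recording_end)}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
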