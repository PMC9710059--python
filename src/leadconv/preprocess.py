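"""Preprocessing: filtering, resampling, blind segmentation, normalisation
and subject-disjoint splitting.

The pipeline turns raw multi-lead records into fixed-length, per-segment
min-max normalised windows suitable as model inputs/targets:

1. resample to the target rate (band-limited polyphase resampling),
2. crop into consecutive non-overlapping windows starting at sample 0
   ("blind" segmentation — no R-peak detection or alignment of any kind),
3. band-pass each window per lead with a zero-phase second-order
   Butterworth filter (1-40 Hz by default), and
4. min-max normalise each window per lead to [-1, 1]:
   ``x_n = 2 * (x - x_min) / (x_max - x_min) - 1``.

Windows in which any requested lead is flat are dropped as a group (the
normalisation is undefined on them) and logged.  Splits are always
subject-disjoint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .records import EcgRecord, canonical_lead_name


class InvalidFilterSpecError(ValueError):
    """Filter band incompatible with the sampling rate."""


class SignalLengthError(ValueError):
    """Signal too short for the requested operation."""


class DegenerateSegmentError(ValueError):
    """Flat segment: min-max normalisation is undefined."""


class MissingLeadError(KeyError):
    """A required lead is absent from a record."""


class MetadataError(ValueError):
    """Inconsistent record/subject metadata."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (default 1-40 Hz, order 2)."""

    order: int = 2
    fc_low: float = 1.0
    fc_high: float = 40.0

    def __post_init__(self):
        if self.order < 1:
            raise InvalidFilterSpecError("filter order must be >= 1")
        if not (0 < self.fc_low < self.fc_high):
            raise InvalidFilterSpecError("need 0 < fc_low < fc_high")

    def validate_for(self, fs: float) -> None:
        if self.fc_high >= fs / 2:
            raise InvalidFilterSpecError(
                f"fc_high={self.fc_high} Hz is not below Nyquist ({fs / 2} Hz)")


@dataclass
class Segment:
    """One single-lead fixed-length window cut from a record."""

    samples: np.ndarray
    lead: str
    fs: float
    subject_id: str
    record_id: str
    offset: int  # start index into the (resampled) source record
    normalised: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.lead = canonical_lead_name(self.lead)


@dataclass(frozen=True)
class SplitSpec:
    """Subject-disjoint train/validation/test split specification."""

    fractions: tuple[float, float, float] = (0.63, 0.07, 0.30)
    test_subjects: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    phase response is zero — ECG landmarks are not displaced.
    """
    x = np.asarray(x, dtype=np.float64)
    spec.validate_for(fs)
    if x.ndim != 1:
        raise ValueError("bandpass_filter expects a 1-D signal")
    if len(x) <= 3 * spec.order:
        raise SignalLengthError(
            f"signal of length {len(x)} too short for order-{spec.order} filtering")
    sos = sps.butter(spec.order, [spec.fc_low, spec.fc_high],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited polyphase resampling; output length is
    ``round(len(x) * fs_out / fs_in)``."""
    x = np.asarray(x, dtype=np.float64)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if x.size == 0:
        raise SignalLengthError("cannot resample an empty signal")
    if fs_in == fs_out:
        return x.copy()
    frac = (Fraction(fs_out) / Fraction(fs_in)).limit_denominator(10 ** 6)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    n_out = int(round(len(x) * fs_out / fs_in))
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.concatenate([y, np.repeat(y[-1], n_out - len(y))])
    return y


def blind_segment(record: EcgRecord, window_seconds: float) -> list[dict[str, Segment]]:
    """Cut a record into consecutive non-overlapping windows from offset 0.

    Returns one ``{lead: Segment}`` group per window; the trailing remainder
    shorter than a window is dropped.  A record shorter than one window
    yields an empty list.  No alignment to cardiac landmarks is performed.
    """
    length = int(round(window_seconds * record.fs))
    if length < 1:
        raise ValueError("window must span at least one sample")
    n_windows = record.n_samples // length
    groups: list[dict[str, Segment]] = []
    for w in range(n_windows):
        off = w * length
        group = {
            lead: Segment(
                samples=record.signals[off:off + length, i],
                lead=lead, fs=record.fs,
                subject_id=record.subject_id, record_id=record.record_id,
                offset=off,
            )
            for i, lead in enumerate(record.lead_names)
        }
        groups.append(group)
    return groups


def minmax_normalise(segment: Segment) -> Segment:
    """Affine map of a segment's amplitudes onto [-1, 1]:
    ``x_n = 2 * (x - x_min) / (x_max - x_min) - 1``."""
    if segment.normalised:
        raise ValueError("segment is already normalised")
    x = segment.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateSegmentError(
            f"flat segment (lead {segment.lead}, record {segment.record_id}, "
            f"offset {segment.offset}): min-max normalisation undefined")
    y = 2.0 * (x - lo) / (hi - lo) - 1.0
    return replace(segment, samples=y, normalised=True)


def subject_split(
    records: list[EcgRecord], spec: SplitSpec = SplitSpec()
) -> tuple[list[EcgRecord], list[EcgRecord], list[EcgRecord]]:
    """Partition records into subject-disjoint (train, val, test) lists.

    With ``test_subjects`` given, those subjects form the test set and the
    rest are split train/val.  Otherwise subjects are shuffled with the seed
    and assigned greedily so cumulative sample counts approximate the
    fractions.
    """
    by_rec: dict[str, str] = {}
    for r in records:
        if by_rec.setdefault(r.record_id, r.subject_id) != r.subject_id:
            raise MetadataError(
                f"record {r.record_id} appears under conflicting subjects")
    subjects: dict[str, list[EcgRecord]] = {}
    for r in records:
        subjects.setdefault(r.subject_id, []).append(r)

    def gather(names):
        return [r for s in names for r in subjects[s]]

    if spec.test_subjects is not None:
        test_names = [s for s in subjects if s in set(spec.test_subjects)]
        rest = [s for s in subjects if s not in set(spec.test_subjects)]
        tr_frac, va_frac = spec.fractions[0], spec.fractions[1]
        denom = tr_frac + va_frac
        rel = tr_frac / denom if denom > 0 else 1.0
        names = sorted(rest)
        np.random.default_rng(spec.seed).shuffle(names)
        weights = np.array([sum(r.n_samples for r in subjects[s]) for s in names],
                           dtype=float)
        total = weights.sum()
        train_names, val_names, acc = [], [], 0.0
        for s, w in zip(names, weights):
            (train_names if acc < rel * total else val_names).append(s)
            acc += w
        if not val_names and len(train_names) > 1 and va_frac > 0:
            val_names.append(train_names.pop())
        return gather(train_names), gather(val_names), gather(test_names)

    names = sorted(subjects)
    np.random.default_rng(spec.seed).shuffle(names)
    weights = {s: sum(r.n_samples for r in subjects[s]) for s in names}
    total = sum(weights.values())
    targets = [f * total for f in spec.fractions]
    fills = [0.0, 0.0, 0.0]
    buckets: tuple[list[str], list[str], list[str]] = ([], [], [])
    for s in names:
        # assign to the set with the largest remaining deficit
        deficits = [t - f for t, f in zip(targets, fills)]
        k = int(np.argmax(deficits))
        buckets[k].append(s)
        fills[k] += weights[s]
    # every set with a positive fraction gets at least one subject
    for k in range(3):
        if spec.fractions[k] > 0 and not buckets[k]:
            donor = int(np.argmax([len(b) for b in buckets]))
            if len(buckets[donor]) > 1:
                buckets[k].append(buckets[donor].pop())
    return gather(buckets[0]), gather(buckets[1]), gather(buckets[2])


# ---------------------------------------------------------------------------
# Pipeline and dataset container
# ---------------------------------------------------------------------------

@dataclass
class SegmentDataset:
    """Aligned, preprocessed multi-lead segments.

    ``X[lead]`` is an ``(n_segments, window_length)`` array; row *i* of every
    lead covers the same time window of the same record, so input/target
    pairs correspond in time.
    """

    leads: tuple[str, ...]
    X: dict[str, np.ndarray]
    subject_ids: list[str]
    record_ids: list[str]
    offsets: np.ndarray
    labels: list[frozenset[str]]
    fs: float
    window_seconds: float
    filter_spec: FilterSpec
    dropped: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def window_length(self) -> int:
        return int(round(self.window_seconds * self.fs))

    @property
    def subjects(self) -> set[str]:
        return set(self.subject_ids)

    def select(self, idx) -> "SegmentDataset":
        idx = np.asarray(idx)
        return SegmentDataset(
            leads=self.leads,
            X={lead: self.X[lead][idx] for lead in self.leads},
            subject_ids=[self.subject_ids[i] for i in idx],
            record_ids=[self.record_ids[i] for i in idx],
            offsets=self.offsets[idx],
            labels=[self.labels[i] for i in idx],
            fs=self.fs, window_seconds=self.window_seconds,
            filter_spec=self.filter_spec, dropped=[],
        )

    def for_subjects(self, subjects) -> "SegmentDataset":
        subjects = set(subjects)
        idx = [i for i, s in enumerate(self.subject_ids) if s in subjects]
        return self.select(idx)

    def manifest(self) -> dict:
        return {
            "leads": list(self.leads),
            "n_segments": len(self),
            "fs": self.fs,
            "window_seconds": self.window_seconds,
            "filter": {"order": self.filter_spec.order,
                       "fc_low": self.filter_spec.fc_low,
                       "fc_high": self.filter_spec.fc_high},
            "subjects": sorted(self.subjects),
            "dropped": self.dropped,
        }

    def manifest_hash(self) -> str:
        """Hash of the preprocessing *configuration* (leads, rate, window,
        filter) — identical across splits of one preprocessing run."""
        m = self.manifest()
        m = {k: m[k] for k in ("leads", "fs", "window_seconds", "filter")}
        return hashlib.sha256(json.dumps(m, sort_keys=True).encode()).hexdigest()[:16]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"X_{lead}": self.X[lead] for lead in self.leads}
        np.savez_compressed(
            directory / "segments.npz",
            offsets=self.offsets,
            subject_ids=np.array(self.subject_ids),
            record_ids=np.array(self.record_ids),
            labels=np.array(["|".join(sorted(l)) for l in self.labels]),
            **arrays,
        )
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SegmentDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        data = np.load(directory / "segments.npz", allow_pickle=False)
        leads = tuple(manifest["leads"])
        return cls(
            leads=leads,
            X={lead: data[f"X_{lead}"] for lead in leads},
            subject_ids=[str(s) for s in data["subject_ids"]],
            record_ids=[str(s) for s in data["record_ids"]],
            offsets=data["offsets"],
            labels=[frozenset(t for t in str(s).split("|") if t)
                    for s in data["labels"]],
            fs=manifest["fs"],
            window_seconds=manifest["window_seconds"],
            filter_spec=FilterSpec(**manifest["filter"]),
            dropped=manifest.get("dropped", []),
        )


def preprocess_pipeline(
    records: list[EcgRecord],
    window_seconds: float = 5.0,
    filter_spec: FilterSpec = FilterSpec(),
    fs_target: float = 1000.0,
    leads: tuple[str, ...] | None = None,
    normalise_before_filter: bool = False,
) -> SegmentDataset:
    """Resample, blindly segment, filter and normalise a list of records.

    ``leads`` restricts processing to a subset (default: all twelve must be
    present).  Windows with a flat lead are dropped as a whole group and
    recorded in ``dataset.dropped``.  Filtering precedes normalisation by
    default; ``normalise_before_filter`` swaps the two (in which case the
    filtered output is re-normalised to restore the exact [-1, 1] span).
    """
    from .records import STANDARD_LEADS

    required = tuple(canonical_lead_name(l) for l in (leads or STANDARD_LEADS))
    filter_spec.validate_for(fs_target)
    X: dict[str, list[np.ndarray]] = {lead: [] for lead in required}
    subject_ids: list[str] = []
    record_ids: list[str] = []
    offsets: list[int] = []
    labels: list[frozenset[str]] = []
    dropped: list[dict] = []

    for record in records:
        for lead in required:
            if lead not in record.lead_names:
                raise MissingLeadError(
                    f"record {record.record_id} is missing required lead {lead}")
        if record.fs != fs_target:
            cols = [resample(record.lead(l), record.fs, fs_target) for l in required]
            record = EcgRecord(
                signals=np.column_stack(cols), fs=fs_target, lead_names=required,
                subject_id=record.subject_id, record_id=record.record_id,
                labels=record.labels,
            )
        for group in blind_segment(record, window_seconds):
            processed: dict[str, np.ndarray] = {}
            try:
                for lead in required:
                    seg = group[lead]
                    if np.ptp(seg.samples) == 0.0:
                        # a flat raw window carries no morphology; flag it
                        # here because filtering would mask the degeneracy
                        raise DegenerateSegmentError(
                            f"flat segment (lead {lead}, record "
                            f"{record.record_id}, offset {seg.offset})")
                    if normalise_before_filter:
                        seg = minmax_normalise(seg)
                        y = bandpass_filter(seg.samples, fs_target, filter_spec)
                        seg = minmax_normalise(replace(seg, samples=y, normalised=False))
                    else:
                        y = bandpass_filter(seg.samples, fs_target, filter_spec)
                        seg = minmax_normalise(replace(seg, samples=y))
                    processed[lead] = seg.samples
            except DegenerateSegmentError as err:
                dropped.append({
                    "record_id": record.record_id,
                    "offset": int(group[required[0]].offset),
                    "reason": str(err),
                })
                continue
            for lead in required:
                X[lead].append(processed[lead])
            first = group[required[0]]
            subject_ids.append(first.subject_id)
            record_ids.append(first.record_id)
            offsets.append(first.offset)
            labels.append(record.labels)

    length = int(round(window_seconds * fs_target))
    return SegmentDataset(
        leads=required,
        X={lead: (np.array(v) if v else np.empty((0, length))) for lead, v in X.items()},
        subject_ids=subject_ids,
        record_ids=record_ids,
        offsets=np.array(offsets, dtype=np.int64),
        labels=labels,
        fs=fs_target,
        window_seconds=window_seconds,
        filter_spec=filter_spec,
        dropped=dropped,
    )
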