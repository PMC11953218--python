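"""Data model and I/O for multi-subject, multi-condition evoked datasets.

The unit of analysis is a subject-level averaged TMS-evoked potential
(TEP): a channels x timepoints matrix in microvolts, on a fixed electrode
montage, time-locked to the TMS pulse.  A full dataset crosses every
subject with a 2 x 3 within-subject design (pulse waveform x induced
current direction).

Conventions
-----------
* Time is expressed in milliseconds relative to the TMS pulse.  The time
  of sample ``k`` is ``t0_offset + k * 1000 / srate``.
* Analysis windows are half-open ``[start, end)``; component time windows
  (:class:`ComponentDef`) are closed intervals, because the published
  component tables print touching decimals (e.g. 24.9 / 25).
* On disk, one delimited-text matrix file per subject x condition plus a
  tabular manifest (columns ``subject_id, waveform, direction, path,
  srate, t0_offset_ms``).  Matrices round-trip bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WAVEFORMS",
    "DIRECTIONS",
    "CONDITIONS",
    "DatasetError",
    "Montage",
    "SubjectEvoked",
    "EvokedDataset",
    "ComponentDef",
    "load_dataset",
    "save_dataset",
    "load_montage",
    "save_montage",
    "standard_montage_1010",
    "downsample",
    "crop",
]

WAVEFORMS = ("monophasic", "biphasic")
DIRECTIONS = ("PA", "AP", "LM")
#: The six cells of the within-subject design, in canonical order.
CONDITIONS = tuple((w, d) for w in WAVEFORMS for d in DIRECTIONS)

#: Tolerance for comparing time stamps (ms); a tiny fraction of any sample
#: period used in practice.
_T_EPS = 1e-9


class DatasetError(ValueError):
    """Raised when a dataset, record or montage violates an invariant."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

#: 74-label subset of the 10-10 system matching a TMS-EEG cap with
#: TP9/TP10 available as reference sites.  Order is anterior-to-posterior,
#: left-to-right, the usual cap ordering.
STANDARD_74 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "PO9", "PO10", "I1", "Iz", "I2",
)


@dataclass(frozen=True)
class Montage:
    """Electrode montage: ordered channel labels plus 3-D positions.

    Positions are unit-sphere-ish head coordinates in arbitrary units;
    only relative geometry is used (spatial smoothing of synthetic maps,
    topographic plotting).
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(names) < 3:
            raise DatasetError("montage needs at least 3 channels")
        if len(set(names)) != len(names):
            raise DatasetError("montage channel names must be unique")
        if pos.shape != (len(names), 3):
            raise DatasetError(
                f"positions shape {pos.shape} does not match {len(names)} channels"
            )
        if not np.all(np.isfinite(pos)):
            raise DatasetError("montage positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, labels: Iterable[str]) -> np.ndarray:
        """Channel indices for ``labels``; unknown labels raise."""
        lut = {name: i for i, name in enumerate(self.channel_names)}
        try:
            return np.array([lut[lb] for lb in labels], dtype=int)
        except KeyError as exc:
            raise DatasetError(f"channel {exc.args[0]!r} not in montage") from None


def standard_montage_1010(channel_names: Sequence[str] = STANDARD_74) -> Montage:
    """Build a montage from 10-10 labels using MNE's standard positions."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    missing = [ch for ch in channel_names if ch not in pos]
    if missing:
        raise DatasetError(f"labels not in the 10-05 standard set: {missing}")
    xyz = np.array([pos[ch] for ch in channel_names], dtype=float)
    # normalise to a unit sphere centred on the centroid, for stable
    # distance-based smoothing kernels downstream
    xyz = xyz - xyz.mean(axis=0)
    xyz = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    return Montage(tuple(channel_names), xyz)


def load_montage(path: str | Path) -> Montage:
    """Read a plain-text montage file (``label x y z`` per line)."""
    names: list[str] = []
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise DatasetError(f"montage line not 'label x y z': {line!r}")
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return Montage(tuple(names), np.array(rows))


def save_montage(montage: Montage, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# label x y z"]
    for name, (x, y, z) in zip(montage.channel_names, montage.positions):
        lines.append(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Evoked records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectEvoked:
    """One subject x condition averaged evoked response.

    Parameters
    ----------
    data
        Channels x timepoints matrix in microvolts.
    srate
        Sampling rate in samples/s.
    t0_offset
        Time of the first sample relative to the TMS pulse, in ms
        (negative for a pre-stimulus baseline).
    """

    subject_id: str
    waveform: str
    direction: str
    data: np.ndarray
    srate: float
    t0_offset: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if self.waveform not in WAVEFORMS:
            raise DatasetError(f"unknown waveform {self.waveform!r}")
        if self.direction not in DIRECTIONS:
            raise DatasetError(f"unknown direction {self.direction!r}")
        if data.ndim != 2:
            raise DatasetError("data must be channels x timepoints")
        if not self.srate > 0:
            raise DatasetError("srate must be positive")
        if not np.all(np.isfinite(data)):
            raise DatasetError(
                f"non-finite samples in record {self.subject_id}/"
                f"{self.waveform}/{self.direction}"
            )

    @property
    def condition(self) -> tuple[str, str]:
        return (self.waveform, self.direction)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in ms relative to the TMS pulse."""
        return self.t0_offset + np.arange(self.n_times) * (1000.0 / self.srate)


@dataclass(frozen=True)
class ComponentDef:
    """A named TEP component: polarity, closed time window, sensor ROI."""

    name: str
    polarity: str  # "negative" | "positive"
    toi: tuple[float, float]  # closed [lo, hi] in ms
    roi: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi", tuple(self.roi))
        object.__setattr__(self, "toi", (float(self.toi[0]), float(self.toi[1])))
        if self.polarity not in ("negative", "positive"):
            raise DatasetError(f"bad polarity {self.polarity!r}")
        lead = self.name.lstrip("M1-")[0].upper()
        if (lead == "N") != (self.polarity == "negative"):
            raise DatasetError(
                f"component {self.name}: polarity {self.polarity} contradicts name"
            )
        if not self.toi[0] < self.toi[1]:
            raise DatasetError(f"component {self.name}: empty TOI")


@dataclass
class EvokedDataset:
    """All records of a complete 2 x 3 within-subject crossing."""

    montage: Montage
    records: list[SubjectEvoked]
    analysis_window: tuple[float, float] = (5.0, 400.0)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.subject_id, None)
        return list(seen)

    @property
    def srate(self) -> float:
        return self.records[0].srate

    @property
    def times(self) -> np.ndarray:
        return self.records[0].times

    def get(self, subject_id: str, waveform: str, direction: str) -> SubjectEvoked:
        for rec in self.records:
            if (
                rec.subject_id == subject_id
                and rec.waveform == waveform
                and rec.direction == direction
            ):
                return rec
        raise DatasetError(f"no record {subject_id}/{waveform}/{direction}")

    def validate(self) -> None:
        if not self.records:
            raise DatasetError("dataset has no records")
        n_ch = self.montage.n_channels
        ref = self.records[0]
        cells: dict[str, set[tuple[str, str]]] = {}
        for rec in self.records:
            if rec.n_channels != n_ch:
                raise DatasetError(
                    f"record {rec.subject_id}/{rec.waveform}/{rec.direction}: "
                    f"{rec.n_channels} channels, montage has {n_ch}"
                )
            if rec.srate != ref.srate or rec.n_times != ref.n_times or \
                    abs(rec.t0_offset - ref.t0_offset) > _T_EPS:
                raise DatasetError(
                    f"record {rec.subject_id}/{rec.waveform}/{rec.direction}: "
                    "time axis differs from the rest of the dataset"
                )
            key = (rec.subject_id, rec.waveform, rec.direction)
            cell = cells.setdefault(rec.subject_id, set())
            if (rec.waveform, rec.direction) in cell:
                raise DatasetError(f"duplicate record {key}")
            cell.add((rec.waveform, rec.direction))
        for subj, have in cells.items():
            missing = [c for c in CONDITIONS if c not in have]
            if missing:
                w, d = missing[0]
                raise DatasetError(f"incomplete design: {subj} missing ({w}, {d})")

    # -- aggregation -------------------------------------------------------

    def stack(self, waveform: str, direction: str) -> np.ndarray:
        """Subjects x channels x timepoints array for one condition."""
        subjects = self.subjects
        return np.stack(
            [self.get(s, waveform, direction).data for s in subjects], axis=0
        )

    def grand_average(self, waveform: str, direction: str) -> np.ndarray:
        return self.stack(waveform, direction).mean(axis=0)

    def map_records(self, func) -> "EvokedDataset":
        """Apply ``func`` to every record; rebuild and re-validate."""
        return EvokedDataset(
            self.montage,
            [func(rec) for rec in self.records],
            self.analysis_window,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MANIFEST_COLS = ("subject_id", "waveform", "direction", "path", "srate", "t0_offset_ms")


def _write_matrix(rec: SubjectEvoked, montage: Montage, path: Path) -> None:
    with path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["channel"] + [f"s{k}" for k in range(rec.n_times)])
        for name, row in zip(montage.channel_names, rec.data):
            wr.writerow([name] + [repr(float(v)) for v in row])


def _read_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    with path.open(newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if not header or header[0] != "channel":
            raise DatasetError(f"{path}: not an evoked matrix file")
        names, rows = [], []
        for row in rd:
            names.append(row[0])
            rows.append([float(v) for v in row[1:]])
    return names, np.array(rows)


def save_dataset(dataset: EvokedDataset, out_dir: str | Path) -> Path:
    """Write montage, one matrix file per record, and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_montage(dataset.montage, out / "montage.txt")
    rows = []
    for rec in dataset.records:
        fname = f"{rec.subject_id}_{rec.waveform}_{rec.direction}.csv"
        _write_matrix(rec, dataset.montage, out / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "waveform": rec.waveform,
                "direction": rec.direction,
                "path": fname,
                "srate": repr(rec.srate),
                "t0_offset_ms": repr(rec.t0_offset),
            }
        )
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=_MANIFEST_COLS)
        wr.writeheader()
        wr.writerows(rows)
    return manifest


def load_dataset(
    manifest_path: str | Path,
    montage_path: str | Path | None = None,
    analysis_window: tuple[float, float] = (5.0, 400.0),
) -> EvokedDataset:
    """Load a dataset from a manifest; validate the full design.

    ``montage_path`` defaults to ``montage.txt`` next to the manifest.
    Records whose channel set disagrees with the montage are rejected
    with a diagnostic naming the offending file.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    if montage_path is None:
        montage_path = base / "montage.txt"
    montage = load_montage(montage_path)

    records: list[SubjectEvoked] = []
    with manifest_path.open(newline="") as fh:
        rd = csv.DictReader(fh)
        missing_cols = set(_MANIFEST_COLS) - set(rd.fieldnames or ())
        if missing_cols:
            raise DatasetError(f"manifest missing columns: {sorted(missing_cols)}")
        for row in rd:
            mat_path = base / row["path"]
            names, data = _read_matrix(mat_path)
            if tuple(names) != montage.channel_names:
                raise DatasetError(
                    f"{mat_path}: channel set does not match montage "
                    f"({len(names)} vs {montage.n_channels} channels)"
                )
            records.append(
                SubjectEvoked(
                    subject_id=row["subject_id"],
                    waveform=row["waveform"],
                    direction=row["direction"],
                    data=data,
                    srate=float(row["srate"]),
                    t0_offset=float(row["t0_offset_ms"]),
                )
            )
    return EvokedDataset(montage, records, analysis_window)


# ---------------------------------------------------------------------------
# Timing operations
# ---------------------------------------------------------------------------


def downsample(ev: SubjectEvoked, target_srate: float) -> SubjectEvoked:
    """Reduce the sampling rate, keeping the time axis anchored at sample 0.

    When the target divides the current rate (the usual 4800 -> 960 Hz
    case) this is plain integer decimation: every ``srate/target``-th
    sample is retained, which is safe because evoked inputs are low-pass
    filtered far below the target Nyquist.  Non-integer ratios go through
    polyphase resampling with the default anti-alias filter.
    """
    if target_srate > ev.srate:
        raise DatasetError(
            f"cannot upsample from {ev.srate} to {target_srate} Hz"
        )
    if target_srate == ev.srate:
        return ev
    ratio = ev.srate / target_srate
    if abs(ratio - round(ratio)) < 1e-9:
        data = ev.data[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        from scipy.signal import resample_poly

        frac = Fraction(target_srate / ev.srate).limit_denominator(10000)
        data = resample_poly(ev.data, frac.numerator, frac.denominator, axis=1)
    return replace(ev, data=data, srate=float(target_srate))


def crop(ev: SubjectEvoked, window_ms: tuple[float, float]) -> SubjectEvoked:
    """Restrict a record to the half-open time window ``[start, end)`` ms."""
    start, end = window_ms
    if not end > start:
        raise DatasetError(f"empty crop window {window_ms}")
    t = ev.times
    mask = (t >= start - _T_EPS) & (t < end - _T_EPS)
    if not mask.any():
        raise DatasetError(f"window {window_ms} contains no samples")
    idx = np.flatnonzero(mask)
    if not np.all(np.diff(idx) == 1):  # pragma: no cover - times are monotone
        raise DatasetError("non-contiguous crop mask")
    return replace(
        ev,
        data=ev.data[:, idx[0] : idx[-1] + 1],
        t0_offset=float(t[idx[0]]),
    )
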