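"""Recording and metadata I/O.

Recordings are read either from European Data Format (EDF/EDF+) files —
parsed by :mod:`mne` — or from plain delimited text with one column per
channel and a header row of labels (sampling rate supplied by the caller,
since the text format carries none). Amplitudes are opaque: h2 is invariant
to affine scaling, so units never affect any downstream result.

Seizure annotations come exclusively from a delimited sidecar file; EDF+
embedded annotations are ignored so there is a single source of truth.

Times are seconds from recording start; sample indices are 0-based and a
time t maps to sample floor(t * rate).
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import ROLE_ORDER, RegionRole

__all__ = [
    "Recording",
    "RegionRecording",
    "ChannelRegionMap",
    "SeizureAnnotation",
    "RecordingFormatError",
    "ChannelMapError",
    "AnnotationError",
    "FixtureIntegrityError",
    "read_recording",
    "write_recording",
    "bipolar_montage",
    "map_regions",
    "load_channel_map",
    "load_annotations",
    "write_annotations",
    "load_index_table",
    "PUBLISHED_TABLE_SHA256",
    "published_table_path",
]

#: Minimum pre-onset signal required so the seizure-onset period
#: (5 s before the tonic discharge) fits inside the recording.
SO_PRE_S = 5.0

PUBLISHED_TABLE_SHA256 = "2383835b0bddcf7b047608cc340a360259a19d59ac304d54c7f9b6bbe75265ce"

PUBLISHED_TABLE_COLUMNS = [
    "patient", "seizure", "pattern", "duration_s",
    "es_global", "es_th", "es_mt", "es_thmt",
    "so_global", "so_th", "so_mt", "so_thmt",
    "th_out", "th_in", "mt_out", "mt_in",
]


class RecordingFormatError(ValueError):
    """The file does not parse under the named recording format."""


class ChannelMapError(ValueError):
    """The channel-to-region map is inconsistent with the recording."""


class AnnotationError(ValueError):
    """A seizure annotation violates its invariants."""


class FixtureIntegrityError(ValueError):
    """The packaged per-seizure table does not match its recorded shape."""


@dataclass
class Recording:
    """A multichannel sampled signal.

    ``samples`` is channels x time; ``montage`` is either ``"referential"``
    (raw contacts) or ``"bipolar"`` (contact differences).
    """

    samples: np.ndarray
    rate: float
    labels: list[str]
    montage: str = "referential"
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise RecordingFormatError("samples must be a 2-D channels x time array")
        if self.rate <= 0:
            raise RecordingFormatError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise RecordingFormatError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise RecordingFormatError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise RecordingFormatError("samples contain non-finite values")
        if self.montage not in ("referential", "bipolar"):
            raise RecordingFormatError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None


@dataclass
class RegionRecording:
    """Signals keyed by anatomical region role, in canonical role order."""

    samples: np.ndarray
    roles: list[RegionRole]
    rate: float
    missing: tuple[RegionRole, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] != len(self.roles):
            raise ChannelMapError("one signal per mapped role required")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def signal(self, role: RegionRole) -> np.ndarray:
        return self.samples[self.roles.index(role)]


@dataclass
class ChannelRegionMap:
    """Assignment of bipolar channel labels to region roles.

    Roles may be absent (e.g. a contact excluded for artifacts) but no role
    may be claimed by two channels.
    """

    entries: dict[str, RegionRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = list(self.entries.values())
        dupes = {r for r in roles if roles.count(r) > 1}
        if dupes:
            names = ", ".join(sorted(r.value for r in dupes))
            raise ChannelMapError(f"role(s) mapped to more than one channel: {names}")


@dataclass(frozen=True)
class SeizureAnnotation:
    """Onset/end times (s from recording start) and pattern label of one seizure."""

    seizure_id: str
    patient_id: str
    t_onset: float
    t_end: float
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in ("A", "B"):
            raise AnnotationError(
                f"seizure {self.seizure_id}: unknown pattern {self.pattern!r}"
            )
        if self.t_end <= self.t_onset:
            raise AnnotationError(
                f"seizure {self.seizure_id}: t_end ({self.t_end}) must exceed "
                f"t_onset ({self.t_onset})"
            )
        if self.t_onset < SO_PRE_S:
            raise AnnotationError(
                f"seizure {self.seizure_id}: t_onset must be at least {SO_PRE_S} s "
                "into the recording (the onset period needs 5 s of pre-onset signal)"
            )


# ---------------------------------------------------------------------------
# recording read / write


def read_recording(
    path: str | Path,
    format: str = "auto",
    rate_if_delimited: float | None = None,
) -> Recording:
    """Read a referential-montage recording from EDF or delimited text.

    No filtering of any kind is applied. For ``format="delimited"`` the
    sampling rate must be passed explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingFormatError(f"no such file: {path}")
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        if rate_if_delimited is None or rate_if_delimited <= 0:
            raise RecordingFormatError(
                "delimited recordings carry no rate; pass rate_if_delimited > 0"
            )
        return _read_delimited(path, rate_if_delimited)
    raise RecordingFormatError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path: str | Path, format: str = "auto") -> Path:
    """Write a recording as delimited text or 16-bit EDF.

    EDF quantizes to 16 bits over the per-channel amplitude range; the
    delimited format is lossless up to decimal printing (17 significant
    digits, i.e. float64 round-trip).
    """
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "delimited":
        frame = pd.DataFrame(rec.samples.T, columns=rec.labels)
        frame.to_csv(path, index=False, float_format="%.17g")
    else:
        raise RecordingFormatError(f"unknown recording format {format!r}")
    return path


def _read_delimited(path: Path, rate: float) -> Recording:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed text
        raise RecordingFormatError(f"{path}: {exc}") from exc
    if frame.empty or frame.shape[1] == 0:
        raise RecordingFormatError(f"{path}: no channels found")
    try:
        samples = frame.to_numpy(dtype=float).T
    except ValueError as exc:
        raise RecordingFormatError(f"{path}: non-numeric sample value ({exc})") from exc
    return Recording(samples, rate, [str(c) for c in frame.columns])


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise RecordingFormatError(f"{path}: not readable as EDF ({exc})") from exc
    # mne rescales EDF physical values (assumed uV for EEG) to volts; undo it
    # so samples come back in the file's own physical units.
    data = raw.get_data() * 1e6
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1-s data records, 16-bit samples, unit 'uV'.

    The sampling rate must be a positive integer (EDF stores samples per
    fixed-duration record). The last partial second, if any, is zero-padded.
    """
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9 or rate <= 0:
        raise RecordingFormatError("EDF output requires an integer sampling rate")
    nchan = rec.n_channels
    n_rec = math.ceil(rec.n_samples / rate)

    pmins, pmaxs, digital = [], [], []
    for ch in rec.samples:
        integral = np.allclose(ch, np.round(ch), atol=0.0) and np.ptp(ch) <= 65535
        if integral and abs(ch.min()) < 1e7:
            # integer-valued data: unit scale makes the round trip exact
            pmin = float(np.round(ch.min()))
            pmax = pmin + 65535.0
            dig = np.round(ch - pmin).astype(np.int64) - 32768
        else:
            pmin, pmax = float(ch.min()), float(ch.max())
            if pmax - pmin < 1e-12:
                pmax = pmin + 1.0
            # EDF physical min/max headers are 8 ASCII chars; use rounded
            # bounds that still bracket the data.
            pmin = min(float(f"{pmin:.6g}"), pmin)
            pmax = max(float(f"{pmax:.6g}"), pmax)
            scale = (pmax - pmin) / 65535.0
            dig = np.round((ch - pmin) / scale).astype(np.int64) - 32768
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    def fx(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b.ljust(width)

    header = b"".join(
        [
            fx("0", 8),
            fx("X X X X", 80),
            fx("Startdate X X X X", 80),
            fx("01.01.00", 8),
            fx("00.00.00", 8),
            fx(str(256 * (nchan + 1)), 8),
            fx("", 44),
            fx(str(n_rec), 8),
            fx("1", 8),
            fx(str(nchan), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(fx(lb, 16) for lb in rec.labels),
            b"".join(fx("SEEG", 80) for _ in range(nchan)),
            b"".join(fx("uV", 8) for _ in range(nchan)),
            b"".join(fx(f"{p:.6g}", 8) for p in pmins),
            b"".join(fx(f"{p:.6g}", 8) for p in pmaxs),
            b"".join(fx("-32768", 8) for _ in range(nchan)),
            b"".join(fx("32767", 8) for _ in range(nchan)),
            b"".join(fx("", 80) for _ in range(nchan)),
            b"".join(fx(str(rate), 8) for _ in range(nchan)),
            b"".join(fx("", 32) for _ in range(nchan)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            lo, hi = r * rate, (r + 1) * rate
            for ch in digital:
                block = ch[lo:hi]
                if block.size < rate:
                    block = np.pad(block, (0, rate - block.size))
                fh.write(struct.pack(f"<{rate}h", *block))


# ---------------------------------------------------------------------------
# montage and region mapping


def bipolar_montage(rec: Recording, pairs: list[tuple[str, str]]) -> Recording:
    """Derive bipolar channels as samplewise differences of contact pairs.

    Each output channel is ``channel_i - channel_j`` labelled ``"i-j"``.
    """
    if rec.montage != "referential":
        raise RecordingFormatError("bipolar montage requires a referential recording")
    out, labels = [], []
    for a, b in pairs:
        try:
            sa = rec.channel(a)
            sb = rec.channel(b)
        except KeyError as exc:
            raise ChannelMapError(str(exc)) from exc
        out.append(sa - sb)
        labels.append(f"{a}-{b}")
    return Recording(np.asarray(out), rec.rate, labels, montage="bipolar",
                     units=rec.units)


def map_regions(rec: Recording, cmap: ChannelRegionMap) -> RegionRecording:
    """Select the channels assigned to region roles, in canonical role order.

    Unmapped roles are flagged as missing, not errors — downstream stages
    average over available pairs only.
    """
    for label in cmap.entries:
        if label not in rec.labels:
            raise ChannelMapError(f"mapped channel {label!r} not in recording")
    by_role = {role: label for label, role in cmap.entries.items()}
    roles = [r for r in ROLE_ORDER if r in by_role]
    missing = tuple(r for r in ROLE_ORDER if r not in by_role)
    samples = np.asarray([rec.channel(by_role[r]) for r in roles])
    return RegionRecording(samples, roles, rec.rate, missing=missing)


def load_channel_map(path: str | Path) -> ChannelRegionMap:
    """Read a two-column (label, role) delimited channel map."""
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "label" not in cols or "role" not in cols:
        raise ChannelMapError(f"{path}: channel map needs 'label' and 'role' columns")
    entries = {}
    for _, row in frame.iterrows():
        name = str(row[cols["role"]]).strip()
        try:
            role = RegionRole(name)
        except ValueError:
            raise ChannelMapError(f"{path}: unknown region role {name!r}") from None
        entries[str(row[cols["label"]]).strip()] = role
    return ChannelRegionMap(entries)


# ---------------------------------------------------------------------------
# annotations


ANNOTATION_COLUMNS = ["seizure_id", "patient_id", "t_onset_s", "t_end_s", "pattern"]


def load_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read and validate the seizure-annotation sidecar file.

    One row per seizure with columns ``seizure_id, patient_id, t_onset_s,
    t_end_s, pattern``. Invalid rows raise with their row number.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise AnnotationError(f"{path}: missing column(s) {missing}")
    anns = []
    for i, row in frame.iterrows():
        try:
            anns.append(
                SeizureAnnotation(
                    seizure_id=str(row["seizure_id"]),
                    patient_id=str(row["patient_id"]),
                    t_onset=float(row["t_onset_s"]),
                    t_end=float(row["t_end_s"]),
                    pattern=str(row["pattern"]).strip(),
                )
            )
        except (AnnotationError, ValueError) as exc:
            raise AnnotationError(f"{path}, row {i + 2}: {exc}") from exc
    return anns


def write_annotations(anns: list[SeizureAnnotation], path: str | Path) -> Path:
    frame = pd.DataFrame(
        [
            (a.seizure_id, a.patient_id, a.t_onset, a.t_end, a.pattern)
            for a in anns
        ],
        columns=ANNOTATION_COLUMNS,
    )
    frame.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# packaged per-seizure table


def published_table_path() -> Path:
    """Path of the packaged per-seizure electrophysiology table."""
    res = importlib.resources.files("h2sync") / "data" / "published_seizure_table.csv"
    return Path(str(res))


def load_index_table(path: str | Path | None = None):
    """Load the 22-seizure electrophysiology table into index records.

    With no argument, the packaged transcription is loaded and verified
    against its recorded SHA-256 checksum. Any file loaded through this
    function must carry the full 22-row, 16-column layout.
    """
    from .indices import SeizureIndexRecord

    packaged = path is None
    path = published_table_path() if packaged else Path(path)
    raw = Path(path).read_bytes()
    if packaged:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != PUBLISHED_TABLE_SHA256:
            raise FixtureIntegrityError(
                "packaged table checksum mismatch: the fixture has been altered"
            )
    frame = pd.read_csv(path)
    missing = [c for c in PUBLISHED_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FixtureIntegrityError(f"{path}: missing column(s) {missing}")
    if len(frame) != 22:
        raise FixtureIntegrityError(
            f"{path}: expected 22 seizures, found {len(frame)}"
        )
    records = []
    for _, row in frame.iterrows():
        records.append(
            SeizureIndexRecord(
                seizure_id=str(row["seizure"]),
                patient_id=str(row["patient"]),
                pattern=str(row["pattern"]).strip(),
                duration_s=float(row["duration_s"]),
                so_indices={
                    "global": float(row["so_global"]),
                    "th": float(row["so_th"]),
                    "mt": float(row["so_mt"]),
                    "thmt": float(row["so_thmt"]),
                },
                es_indices={
                    "global": float(row["es_global"]),
                    "th": float(row["es_th"]),
                    "mt": float(row["es_mt"]),
                    "thmt": float(row["es_thmt"]),
                },
                degrees={
                    "th_out": float(row["th_out"]),
                    "th_in": float(row["th_in"]),
                    "mt_out": float(row["mt_out"]),
                    "mt_in": float(row["mt_in"]),
                },
            )
        )
    return records
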