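"""Reading and writing every external artefact the pipeline touches.

Two EEG dialects are supported:

* **edf** — plain 16-bit EDF with a tab-separated sidecar events file
  (``<stem>.events.tsv`` with columns ``onset_s``, ``duration_s``, ``label``).
  The writer uses a fixed symmetric physical range (default ±3276.7 µV,
  i.e. 0.1 µV resolution), which makes write→read→write an exact fixed
  point of the 16-bit quantisation.
* **epoch_archive** — a documented text/columnar layout: a directory with a
  ``meta.json`` and a long-format ``epochs.tsv`` holding already-epoched
  data by condition.

Morphometry is consumed as the tab-separated tables produced by FreeSurfer's
``aparcstats2table`` / ``asegstats2table`` commands (first column = subject
identifier); MRI processing itself is out of scope.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import validate_channels

#: Condition vocabulary: rest plus the four tactile stimulus types
#: (brush hardness × stroking speed).
REST = "rest"
STIM_CONDITIONS: tuple[str, ...] = ("slow_soft", "fast_soft", "slow_hard", "fast_hard")
ALL_CONDITIONS: tuple[str, ...] = (REST,) + STIM_CONDITIONS

#: Valence pairing of the stimulus types: soft-brush stroking was rated
#: pleasant, hard-brush stroking unpleasant.
VALENCE_PAIRS: dict[str, tuple[str, ...]] = {
    "pleasant": ("slow_soft", "fast_soft"),
    "unpleasant": ("slow_hard", "fast_hard"),
}


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A continuous multichannel EEG recording in microvolts.

    ``annotations`` is a list of ``(onset_s, duration_s, label)`` marking
    condition periods (rest and stimulation trials).
    """

    channel_labels: tuple[str, ...]
    sample_rate: float
    data: np.ndarray  # (n_channels, n_samples), microvolts
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = "unknown"
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        validate_channels(self.channel_labels)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")
        length_s = self.data.shape[1] / self.sample_rate
        for onset, dur, label in self.annotations:
            if onset < 0:
                raise ValueError(f"annotation onset {onset} is negative ({label})")
            if onset + dur > length_s + 1e-9:
                raise ValueError(
                    f"annotation {label!r} at {onset}s + {dur}s extends past the "
                    f"recording end ({length_s:.3f}s)"
                )

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sample_rate


@dataclass
class EpochSet:
    """Per-subject EEG epochs organised by condition.

    ``epochs[condition]`` is an array of shape (n_epochs, n_channels,
    n_samples); all conditions share the channel ordering and epoch length.
    """

    subject_id: str
    group: str
    channels: tuple[str, ...]
    sample_rate: float
    epochs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        validate_channels(self.channels)
        n_samp = None
        for cond, arr in self.epochs.items():
            if cond not in ALL_CONDITIONS:
                raise ValueError(
                    f"unknown condition {cond!r}; expected one of {ALL_CONDITIONS}"
                )
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[1] != len(self.channels):
                raise ValueError(
                    f"epochs[{cond!r}] must be (n_epochs, {len(self.channels)}, n_samples)"
                )
            if n_samp is None:
                n_samp = arr.shape[2]
            elif arr.shape[2] != n_samp:
                raise ValueError("all epochs must have the same sample count")
            self.epochs[cond] = arr

    @property
    def epoch_samples(self) -> int:
        return next(iter(self.epochs.values())).shape[2]

    def n_epochs(self, condition: str) -> int:
        return self.epochs[condition].shape[0] if condition in self.epochs else 0

    def stim_epochs(self, conditions=STIM_CONDITIONS) -> np.ndarray:
        """Pooled stimulation epochs across the given stimulus types."""
        stacks = [self.epochs[c] for c in conditions if c in self.epochs]
        if not stacks:
            raise ValueError("no stimulation epochs present")
        return np.concatenate(stacks, axis=0)


@dataclass
class MorphometryRecord:
    """FreeSurfer-derived structural measures for one subject.

    Thickness is in millimetres per hemisphere and Desikan–Killiany-style
    region label; volumes are voxel counts.  ``surface_holes`` is the
    topological-defect count, used as a proxy for damaged brain tissue.
    """

    subject_id: str
    thickness: dict[str, dict[str, float]] = field(default_factory=dict)
    volumes: dict[str, float] = field(default_factory=dict)
    total_gray_volume: float | None = None
    surface_holes: float | None = None
    raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hemi, regions in self.thickness.items():
            for region, value in regions.items():
                if not (0.0 < value < 6.0):
                    raise ValueError(
                        f"thickness {hemi}.{region} = {value} mm outside (0, 6)"
                    )
        for name, value in self.volumes.items():
            if value < 0:
                raise ValueError(f"volume {name} = {value} is negative")
        if self.surface_holes is not None and self.surface_holes < 0:
            raise ValueError("surface_holes must be non-negative")


@dataclass
class ClinicalRecord:
    """Admission coma depth (GCS) and recovery outcome (GOSe) for a subject."""

    subject_id: str
    gcs: int
    gose: int
    group: str

    def __post_init__(self) -> None:
        if not 3 <= self.gcs <= 15:
            raise ValueError(f"GCS {self.gcs} outside [3, 15]")
        if not 1 <= self.gose <= 8:
            raise ValueError(f"GOSe {self.gose} outside [1, 8]")


# ---------------------------------------------------------------------------
# EDF dialect
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767
#: Default physical range, microvolts.  ±3276.7 gives 0.1 µV per digital unit.
DEFAULT_PHYSICAL_RANGE_UV = 3276.7


def _ascii(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path, physical_range=DEFAULT_PHYSICAL_RANGE_UV) -> Path:
    """Write a plain 16-bit EDF file plus a sidecar events table.

    Record duration is 1 s; the signal must contain a whole number of
    seconds.  Amplitudes beyond ``physical_range`` µV are rejected rather
    than silently clipped.
    """
    path = Path(path)
    rate = recording.sample_rate
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("EDF writer requires an integer sample rate")
    rate = int(round(rate))
    n_ch, n_samp = recording.data.shape
    if n_samp % rate != 0:
        raise FormatError(
            "EDF writer requires a whole number of seconds "
            f"({n_samp} samples at {rate} Hz)"
        )
    peak = float(np.max(np.abs(recording.data))) if n_samp else 0.0
    if peak > physical_range:
        raise FormatError(
            f"signal peak {peak:.1f} µV exceeds the physical range "
            f"±{physical_range} µV"
        )
    n_records = n_samp // rate

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii(f"{recording.subject_id} {recording.group}"[:80], 80)
    header += _ascii("comareact", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (1 + n_ch)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)
    header += _ascii(str(n_ch), 4)
    for lab in recording.channel_labels:
        header += _ascii(lab, 16)
    header += _ascii("AgCl electrode", 80) * n_ch
    header += _ascii("uV", 8) * n_ch
    header += _ascii(f"{-physical_range:g}", 8) * n_ch
    header += _ascii(f"{physical_range:g}", 8) * n_ch
    header += _ascii(str(-_EDF_DIG_MAX), 8) * n_ch
    header += _ascii(str(_EDF_DIG_MAX), 8) * n_ch
    header += _ascii("HP:0.05Hz LP:70Hz", 80) * n_ch
    header += _ascii(str(rate), 8) * n_ch
    header += _ascii("", 32) * n_ch

    digital = np.rint(recording.data / physical_range * _EDF_DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            chunk = digital[:, rec * rate:(rec + 1) * rate]
            fh.write(chunk.tobytes())

    events_path = _events_path(path)
    with open(events_path, "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for onset, dur, label in recording.annotations:
            fh.write(f"{onset:.6g}\t{dur:.6g}\t{label}\n")
    return path


def _events_path(edf_path: Path) -> Path:
    return edf_path.with_suffix(".events.tsv")


def read_edf(path, subject_id: str | None = None, group: str = "unknown") -> Recording:
    """Read a plain 16-bit EDF file; annotations come from the sidecar table."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        patient = head[8:88].decode("ascii", "replace").strip()
        n_records = int(head[236:244].decode().strip())
        record_dur = float(head[244:252].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig = fh.read(256 * n_ch)
        labels = [sig[16 * i:16 * (i + 1)].decode().strip() for i in range(n_ch)]
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch
        pmin = [float(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(n_ch)]
        off += 8 * n_ch
        pmax = [float(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(n_ch)]
        off += 8 * n_ch
        dmin = [int(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(n_ch)]
        off += 8 * n_ch
        dmax = [int(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(n_ch)]
        off += 8 * n_ch + 80 * n_ch
        nsamp = [int(sig[off + 8 * i:off + 8 * (i + 1)].decode()) for i in range(n_ch)]

        per_record = sum(nsamp)
        raw = np.frombuffer(fh.read(2 * per_record * n_records), dtype="<i2")
    if raw.size != per_record * n_records:
        raise FormatError(f"{path}: truncated EDF data section")

    if len(set(nsamp)) != 1:
        raise FormatError(f"{path}: heterogeneous per-channel rates are unsupported")
    rate = nsamp[0] / record_dur
    data = np.empty((n_ch, nsamp[0] * n_records), dtype=float)
    raw = raw.reshape(n_records, n_ch, nsamp[0]).astype(np.int64)
    for i in range(n_ch):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[i] = (raw[:, i, :].reshape(-1) - dmin[i]) * gain + pmin[i]

    annotations = _read_events(_events_path(path))
    sid = subject_id if subject_id is not None else (patient.split() or ["unknown"])[0]
    grp = group
    if group == "unknown" and len(patient.split()) > 1:
        grp = patient.split()[1]
    return Recording(
        channel_labels=tuple(labels),
        sample_rate=rate,
        data=data,
        annotations=annotations,
        subject_id=sid,
        group=grp,
    )


def _read_events(events_path: Path) -> list[tuple[float, float, str]]:
    if not events_path.exists():
        raise FormatError(
            f"no annotations found: supply an events file at {events_path} "
            "(tab-separated: onset_s, duration_s, label)"
        )
    table = pd.read_csv(events_path, sep="\t")
    missing = {"onset_s", "duration_s", "label"} - set(table.columns)
    if missing:
        raise FormatError(f"{events_path}: missing column(s) {sorted(missing)}")
    return [
        (float(r.onset_s), float(r.duration_s), str(r.label))
        for r in table.itertuples()
    ]


# ---------------------------------------------------------------------------
# epoch-archive dialect
# ---------------------------------------------------------------------------

def write_epoch_archive(epoch_set: EpochSet, directory) -> Path:
    """Write an EpochSet as the text epoch-archive dialect.

    Layout: ``meta.json`` (subject, group, rate, channels, condition epoch
    counts) and ``epochs.tsv`` in long format with one row per sample:
    ``condition, epoch, sample, <channel columns>``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    conditions = [c for c in ALL_CONDITIONS if c in epoch_set.epochs]
    meta = {
        "subject_id": epoch_set.subject_id,
        "group": epoch_set.group,
        "sample_rate": epoch_set.sample_rate,
        "channels": list(epoch_set.channels),
        "epoch_samples": epoch_set.epoch_samples,
        "n_epochs": {c: int(epoch_set.epochs[c].shape[0]) for c in conditions},
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    with open(directory / "epochs.tsv", "w") as fh:
        fh.write("condition\tepoch\tsample\t" + "\t".join(epoch_set.channels) + "\n")
        for cond in conditions:
            arr = epoch_set.epochs[cond]
            n_ep, n_ch, n_samp = arr.shape
            frame = pd.DataFrame(
                arr.transpose(0, 2, 1).reshape(n_ep * n_samp, n_ch),
                columns=epoch_set.channels,
            )
            frame.insert(0, "condition", cond)
            frame.insert(1, "epoch", np.repeat(np.arange(n_ep), n_samp))
            frame.insert(2, "sample", np.tile(np.arange(n_samp), n_ep))
            frame.to_csv(fh, sep="\t", index=False, header=False,
                         float_format="%.9g", lineterminator="\n")
    return directory


def read_epoch_archive(directory) -> EpochSet:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"{directory}: not an epoch archive (no meta.json)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    table = pd.read_csv(directory / "epochs.tsv", sep="\t")
    channels = list(meta["channels"])
    n_samp = int(meta["epoch_samples"])
    epochs: dict[str, np.ndarray] = {}
    for cond, sub in table.groupby("condition", sort=False):
        n_ep = int(sub["epoch"].max()) + 1
        arr = np.empty((n_ep, len(channels), n_samp), dtype=float)
        sub = sub.sort_values(["epoch", "sample"])
        values = sub[channels].to_numpy()
        if values.shape[0] != n_ep * n_samp:
            raise FormatError(
                f"{directory}: condition {cond!r} has {values.shape[0]} rows, "
                f"expected {n_ep * n_samp}"
            )
        arr[:] = values.reshape(n_ep, n_samp, len(channels)).transpose(0, 2, 1)
        epochs[str(cond)] = arr
    return EpochSet(
        subject_id=meta["subject_id"],
        group=meta["group"],
        channels=tuple(channels),
        sample_rate=float(meta["sample_rate"]),
        epochs=epochs,
    )


def epochs_to_recording(epoch_set: EpochSet) -> Recording:
    """Concatenate an EpochSet into a continuous Recording with annotations."""
    rate = epoch_set.sample_rate
    length_s = epoch_set.epoch_samples / rate
    blocks, annotations = [], []
    t = 0.0
    for cond in ALL_CONDITIONS:
        if cond not in epoch_set.epochs:
            continue
        for e in range(epoch_set.epochs[cond].shape[0]):
            blocks.append(epoch_set.epochs[cond][e])
            annotations.append((t, length_s, cond))
            t += length_s
    return Recording(
        channel_labels=epoch_set.channels,
        sample_rate=rate,
        data=np.concatenate(blocks, axis=1),
        annotations=annotations,
        subject_id=epoch_set.subject_id,
        group=epoch_set.group,
    )


def read_recording(path, dialect: str = "edf", **kwargs) -> Recording:
    """Read an EEG recording in one of the supported dialects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "edf":
        return read_edf(path, **kwargs)
    if dialect == "epoch_archive":
        return epochs_to_recording(read_epoch_archive(path))
    raise ValueError(f"unknown dialect {dialect!r}; expected 'edf' or 'epoch_archive'")


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def extract_epochs(
    recording: Recording,
    epoch_length_s: float = 10.0,
    rest_selection: str = "contiguous",
    max_rest_fragments: int | None = None,
    amplitude_threshold_uv: float | None = None,
) -> EpochSet:
    """Cut a recording into fixed-length condition epochs.

    Epochs are half-open sample windows ``[onset, onset + L)`` at 0-based
    indices with the onset rounded to the nearest sample; partial trailing
    segments are dropped.  ``rest_selection`` chooses how rest fragments are
    taken from long rest blocks when ``max_rest_fragments`` caps the count:
    ``contiguous`` (from the block start) or ``sampled`` (evenly spaced,
    non-overlapping).  ``amplitude_threshold_uv``, when set, drops epochs
    whose absolute amplitude exceeds the threshold (simple artifact gate;
    off by default).
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    if not recording.annotations:
        raise FormatError(
            "recording has no annotations: supply an events file "
            "(onset_s, duration_s, label)"
        )
    if rest_selection not in ("contiguous", "sampled"):
        raise ValueError("rest_selection must be 'contiguous' or 'sampled'")
    rate = recording.sample_rate
    n_len = int(round(epoch_length_s * rate))
    n_total = recording.data.shape[1]

    windows: dict[str, list[np.ndarray]] = {}
    for onset_s, dur_s, label in recording.annotations:
        if label not in ALL_CONDITIONS:
            raise FormatError(
                f"unknown condition label {label!r}; expected one of {ALL_CONDITIONS}"
            )
        start = int(round(onset_s * rate))
        avail = min(int(round((onset_s + dur_s) * rate)), n_total) - start
        n_fit = avail // n_len
        starts = [start + k * n_len for k in range(n_fit)]
        if label == REST and max_rest_fragments is not None and n_fit > max_rest_fragments:
            if rest_selection == "contiguous":
                starts = starts[:max_rest_fragments]
            else:
                idx = np.linspace(0, n_fit - 1, max_rest_fragments).round().astype(int)
                starts = [starts[i] for i in np.unique(idx)]
        for s0 in starts:
            windows.setdefault(label, []).append(recording.data[:, s0:s0 + n_len])

    if REST not in windows:
        raise FormatError("no complete rest epoch found (rest annotation required)")

    epochs: dict[str, np.ndarray] = {}
    for cond in ALL_CONDITIONS:
        if cond not in windows:
            if any(label == cond for _, _, label in recording.annotations):
                warnings.warn(
                    f"condition {cond!r}: no complete {epoch_length_s:g}-s epoch; omitted"
                )
            continue
        arr = np.stack(windows[cond], axis=0)
        if amplitude_threshold_uv is not None:
            keep = np.max(np.abs(arr), axis=(1, 2)) <= amplitude_threshold_uv
            if not keep.all():
                warnings.warn(
                    f"condition {cond!r}: dropped {int((~keep).sum())} epoch(s) "
                    f"exceeding ±{amplitude_threshold_uv:g} µV"
                )
            arr = arr[keep]
        if arr.shape[0]:
            epochs[cond] = arr

    if REST not in epochs:
        raise FormatError("all rest epochs were rejected")
    return EpochSet(
        subject_id=recording.subject_id,
        group=recording.group,
        channels=recording.channel_labels,
        sample_rate=rate,
        epochs=epochs,
    )


# ---------------------------------------------------------------------------
# morphometry tables
# ---------------------------------------------------------------------------

#: Desikan–Killiany-style labels recognised as cortical thickness regions
#: (merged-granularity set used in the study tables).
KNOWN_REGIONS = frozenset({
    "anteriorcingulate", "posteriorcingulate", "middlefrontal",
    "parahippocampal", "inferiorparietal", "superiorparietal",
    "paracentral", "postcentral", "precentral", "precuneus",
    "supramarginal", "insula", "meanthickness",
})

_TOTAL_GRAY_ALIASES = {"totalgrayvol", "totalgray"}
_SURFACE_HOLE_ALIASES = {"surfaceholes", "holes"}


def _read_stats_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty morphometry table") from None
    if table.shape[1] < 2 or table.shape[0] == 0:
        raise FormatError(f"{path}: morphometry table needs a subject column and data")
    return table


def _cell_float(table: pd.DataFrame, path, row: int, col: str) -> float:
    raw = table.iloc[row][col]
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}: non-numeric value {raw!r} at row {row + 1}, column {col!r}"
        ) from None


def _norm_region(column: str) -> tuple[str | None, str]:
    """Map an aparc column name to (hemisphere, normalized region label)."""
    name = column.strip().lower()
    hemi = None
    for prefix in ("lh_", "rh_", "lh.", "rh."):
        if name.startswith(prefix):
            hemi = prefix[:2]
            name = name[3:]
    if name.endswith("_thickness"):
        name = name[: -len("_thickness")]
    name = name.replace("_", "").replace("-", "").replace(" ", "")
    return hemi, name


def read_morphometry(aparc_paths, aseg_path) -> list[MorphometryRecord]:
    """Read per-hemisphere thickness tables plus the volume table.

    ``aparc_paths`` maps hemisphere (``lh``/``rh``) to an aparcstats2table
    thickness file; ``aseg_path`` is an asegstats2table volume file.  Region
    columns are normalized to lowercase Desikan–Killiany-style labels;
    unrecognised columns are kept untouched in the record's ``raw`` namespace.
    """
    if isinstance(aparc_paths, (str, Path)):
        aparc_paths = {"lh": aparc_paths}
    aseg = _read_stats_table(aseg_path)
    subj_col = aseg.columns[0]
    aseg_subjects = list(aseg[subj_col])
    if len(set(aseg_subjects)) != len(aseg_subjects):
        raise FormatError(f"{aseg_path}: duplicate subject identifiers")

    thickness: dict[str, dict[str, dict[str, float]]] = {s: {} for s in aseg_subjects}
    raw: dict[str, dict[str, float]] = {s: {} for s in aseg_subjects}
    for hemi_key, path in dict(aparc_paths).items():
        table = _read_stats_table(path)
        scol = table.columns[0]
        for row, subject in enumerate(table[scol]):
            if subject not in thickness:
                raise FormatError(
                    f"subject {subject!r} present in {path} but not in {aseg_path}"
                )
            for col in table.columns[1:]:
                hemi, region = _norm_region(col)
                hemi = hemi or str(hemi_key)
                value = _cell_float(table, path, row, col)
                if region in KNOWN_REGIONS:
                    thickness[subject].setdefault(hemi, {})[region] = value
                else:
                    raw[subject][f"{hemi}_{region}"] = value

    records = []
    for row, subject in enumerate(aseg_subjects):
        volumes: dict[str, float] = {}
        total_gray = surface_holes = None
        for col in aseg.columns[1:]:
            key = col.strip().lower().replace("_", "").replace("-", "").replace(" ", "")
            value = _cell_float(aseg, aseg_path, row, col)
            if key in _TOTAL_GRAY_ALIASES:
                total_gray = value
            elif key in _SURFACE_HOLE_ALIASES:
                surface_holes = value
            else:
                volumes[col.strip().lower()] = value
        records.append(
            MorphometryRecord(
                subject_id=str(subject),
                thickness=thickness[subject],
                volumes=volumes,
                total_gray_volume=total_gray,
                surface_holes=surface_holes,
                raw=raw[subject],
            )
        )
    return records


def write_morphometry(records: list[MorphometryRecord], out_dir) -> dict[str, Path]:
    """Write records back to the three-table layout read by read_morphometry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for hemi in ("lh", "rh"):
        regions = sorted({r for rec in records for r in rec.thickness.get(hemi, {})})
        if not regions:
            continue
        path = out_dir / f"{hemi}.aparc.thickness.tsv"
        with open(path, "w") as fh:
            header = [f"{hemi}.aparc.thickness"] + [f"{hemi}_{r}_thickness" for r in regions]
            fh.write("\t".join(header) + "\n")
            for rec in records:
                vals = [f"{rec.thickness[hemi][r]:.12g}" for r in regions]
                fh.write("\t".join([rec.subject_id] + vals) + "\n")
        paths[hemi] = path

    vol_names = sorted({v for rec in records for v in rec.volumes})
    path = out_dir / "aseg.volume.tsv"
    with open(path, "w") as fh:
        header = ["Measure:volume"] + vol_names + ["TotalGrayVol", "SurfaceHoles"]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            vals = [f"{rec.volumes[v]:.12g}" for v in vol_names]
            vals.append(f"{rec.total_gray_volume:.12g}")
            vals.append(f"{rec.surface_holes:.12g}")
            fh.write("\t".join([rec.subject_id] + vals) + "\n")
    paths["aseg"] = path
    return paths


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def read_clinical(path) -> list[ClinicalRecord]:
    table = pd.read_csv(path, sep="\t")
    missing = {"subject_id", "group", "gcs", "gose"} - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        ClinicalRecord(
            subject_id=str(r.subject_id), gcs=int(r.gcs),
            gose=int(r.gose), group=str(r.group),
        )
        for r in table.itertuples()
    ]


def write_clinical(records: list[ClinicalRecord], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subject_id\tgroup\tgcs\tgose\n")
        for rec in records:
            fh.write(f"{rec.subject_id}\t{rec.group}\t{rec.gcs}\t{rec.gose}\n")
    return path


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  parameters: dict | None = None, seed: int | None = None) -> dict:
    """Write result tables as TSV plus a machine-readable run manifest.

    Numeric values are serialized with 12 significant digits; column order
    follows the DataFrame and is therefore deterministic for a given run.
    Returns the manifest dictionary (also written as ``run_manifest.json``).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, table in tables.items():
            path = out_dir / f"{name}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.12g")
            files[name] = path.name
        import comareact

        manifest = {
            "parameters": parameters or {},
            "seed": seed,
            "tables": files,
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "comareact": comareact.__version__,
            },
        }
        with open(out_dir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise OSError(f"cannot write results under {out_dir}: {exc}") from exc
    return manifest


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
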