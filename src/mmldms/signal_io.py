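"""Polysomnography I/O: EDF recordings, epoch annotations, image datasets.

Reading EDF goes through :mod:`mne`.  Writing uses a minimal EDF writer
implemented here (16-bit samples, 1-s data records, per-channel physical
scaling), since the environment ships no EDF export library; the mne
read path keeps the writer honest via round-trip tests.  Note that EDF
stores 16-bit integers, so a written channel is recovered only to within
its quantization step (physical range / 2^16).

Epoch annotations use the repo's canonical tab-separated dialect: one
line per 30-s epoch, ``epoch_index<TAB>start_s<TAB>stage<TAB>disorder``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labels import validate_disorder, validate_modality, validate_stage
from .preprocessing import SpectrogramImage

EPOCH_SECONDS = 30.0

__all__ = [
    "Channel",
    "EpochAnnotation",
    "MultimodalRecord",
    "read_record",
    "write_record",
    "write_edf",
    "write_annotations",
    "read_annotations",
    "write_image_dataset",
    "read_image_dataset",
]


@dataclass(frozen=True)
class EpochAnnotation:
    """One scored 30-s epoch."""

    epoch_index: int
    start_time: float
    duration: float
    stage: str

    def __post_init__(self) -> None:
        if self.epoch_index < 0:
            raise ValueError("epoch_index must be >= 0")
        if abs(self.start_time - self.epoch_index * self.duration) > 1e-9:
            raise ValueError(
                f"epoch {self.epoch_index}: start_time {self.start_time} != "
                f"epoch_index x {self.duration}"
            )
        validate_stage(self.stage)


@dataclass(frozen=True)
class Channel:
    modality: str
    channel_name: str
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        validate_modality(self.modality)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass
class MultimodalRecord:
    """Synchronized multi-channel recording with epoch annotations."""

    record_id: str
    channels: list[Channel]
    annotations: list[EpochAnnotation]
    disorder: str

    def __post_init__(self) -> None:
        validate_disorder(self.disorder)
        span = len(self.annotations) * EPOCH_SECONDS
        for ch in self.channels:
            if len(ch.samples) < span * ch.sampling_rate - 0.5:
                raise ValueError(
                    f"record {self.record_id}: channel {ch.channel_name!r} is "
                    f"shorter than the annotated span ({span} s)"
                )

    def get_channel(self, modality: str, channel_name: str) -> Channel:
        for ch in self.channels:
            if ch.modality == modality and ch.channel_name == channel_name:
                return ch
        avail = [(c.modality, c.channel_name) for c in self.channels]
        raise KeyError(
            f"record {self.record_id}: no channel ({modality}, {channel_name!r}); "
            f"available: {avail}"
        )

    @property
    def n_epochs(self) -> int:
        return len(self.annotations)


# --------------------------------------------------------------------
# EDF writing (minimal, 16-bit, 1-second data records)
# --------------------------------------------------------------------

def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} longer than {width} bytes")
    return b.ljust(width)


def _fmt8(value: float) -> str:
    """Format a float into <=8 ASCII chars the way EDF headers expect."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {value} into 8 characters")


def write_edf(record: MultimodalRecord, path: str | Path) -> Path:
    """Write a record's channels to an EDF file (one data record per second).

    Every channel must span an integer number of seconds at an integer
    sampling rate; samples are scaled to int16 over a symmetric physical
    range covering the channel.  The physical dimension is written as
    'au' so readers apply no unit conversion.
    """
    path = Path(path)
    durations = set()
    for ch in record.channels:
        fs = ch.sampling_rate
        if abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"channel {ch.channel_name!r}: non-integer rate {fs}")
        if len(ch.samples) % int(round(fs)):
            raise ValueError(
                f"channel {ch.channel_name!r}: length {len(ch.samples)} is not a "
                f"whole number of seconds at {fs} Hz"
            )
        durations.add(len(ch.samples) // int(round(fs)))
    if len(durations) != 1:
        raise ValueError(f"channels span unequal durations: {sorted(durations)}")
    n_records = durations.pop()
    ns = len(record.channels)

    dmin, dmax = -32768, 32767
    digital: list[np.ndarray] = []
    pmins: list[float] = []
    pmaxs: list[float] = []
    for ch in record.channels:
        x = np.asarray(ch.samples, dtype=float)
        amp = float(np.max(np.abs(x))) if x.size else 1.0
        amp = amp if amp > 0 else 1.0
        # round-trip the printed header values so reader and writer agree
        pmin = float(_fmt8(-amp * 1.0001))
        pmax = float(_fmt8(amp * 1.0001))
        scale = (dmax - dmin) / (pmax - pmin)
        d = np.clip(np.round((x - pmin) * scale + dmin), dmin, dmax).astype("<i2")
        digital.append(d)
        pmins.append(pmin)
        pmaxs.append(pmax)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(record.record_id[:80], 80),
            _ascii(f"disorder {record.disorder}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (ns + 1)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii("1", 8),
            _ascii(str(ns), 4),
        ]
    )
    fields: list[bytes] = []
    for width, values in (
        (16, [ch.channel_name for ch in record.channels]),
        (80, ["" for _ in record.channels]),
        (8, ["au" for _ in record.channels]),
        (8, [_fmt8(p) for p in pmins]),
        (8, [_fmt8(p) for p in pmaxs]),
        (8, [str(dmin) for _ in record.channels]),
        (8, [str(dmax) for _ in record.channels]),
        (80, ["" for _ in record.channels]),
        (8, [str(int(round(ch.sampling_rate))) for ch in record.channels]),
        (32, ["" for _ in record.channels]),
    ):
        fields.extend(_ascii(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        rates = [int(round(ch.sampling_rate)) for ch in record.channels]
        for rec in range(n_records):
            for d, fs in zip(digital, rates):
                fh.write(d[rec * fs : (rec + 1) * fs].tobytes())
    return path


def write_annotations(record: MultimodalRecord, path: str | Path) -> Path:
    """Write the canonical tab-separated epoch annotation file."""
    path = Path(path)
    with open(path, "w") as fh:
        for ann in record.annotations:
            fh.write(
                f"{ann.epoch_index}\t{ann.start_time:g}\t{ann.stage}\t"
                f"{record.disorder}\n"
            )
    return path


def write_record(
    record: MultimodalRecord, edf_path: str | Path, annotation_path: str | Path
) -> tuple[Path, Path]:
    """Serialize a record as EDF + annotation TSV."""
    return write_edf(record, edf_path), write_annotations(record, annotation_path)


def read_annotations(path: str | Path) -> tuple[list[EpochAnnotation], str]:
    """Parse the canonical annotation dialect; returns (annotations, disorder)."""
    annotations: list[EpochAnnotation] = []
    disorders: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got "
                    f"{len(parts)}"
                )
            try:
                idx = int(parts[0])
                start = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            try:
                validate_stage(parts[2])
                validate_disorder(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            annotations.append(
                EpochAnnotation(
                    epoch_index=idx,
                    start_time=start,
                    duration=EPOCH_SECONDS,
                    stage=parts[2],
                )
            )
            disorders.add(parts[3])
    if not annotations:
        raise ValueError(f"{path}: no annotations found")
    if len(disorders) != 1:
        raise ValueError(
            f"{path}: expected one record-level disorder label, got {sorted(disorders)}"
        )
    return annotations, disorders.pop()


def read_record(
    edf_path: str | Path,
    annotation_path: str | Path,
    channel_map: dict[str, str],
) -> MultimodalRecord:
    """Read an EDF + annotation pair into a :class:`MultimodalRecord`.

    ``channel_map`` maps modality → EDF channel label.  Native sampling
    rates and signal units are preserved; nothing is resampled or
    rescaled.
    """
    import mne

    edf_path = Path(edf_path)
    header = mne.io.read_raw_edf(edf_path, preload=False, verbose="error")
    available = list(header.ch_names)
    channels: list[Channel] = []
    for modality, name in channel_map.items():
        validate_modality(modality)
        if name not in available:
            raise KeyError(
                f"{edf_path}: channel {name!r} not in EDF header; available "
                f"channels: {available}"
            )
        raw = mne.io.read_raw_edf(
            edf_path, include=[name], preload=True, verbose="error", units="au"
        )
        channels.append(
            Channel(
                modality=modality,
                channel_name=name,
                sampling_rate=float(raw.info["sfreq"]),
                samples=raw.get_data()[0],
            )
        )
    annotations, disorder = read_annotations(annotation_path)
    span = len(annotations) * EPOCH_SECONDS
    for ch in channels:
        if len(ch.samples) + 0.5 < span * ch.sampling_rate:
            raise ValueError(
                f"{annotation_path}: annotated span ({span} s) exceeds channel "
                f"{ch.channel_name!r} length ({len(ch.samples) / ch.sampling_rate} s)"
            )
    return MultimodalRecord(
        record_id=edf_path.stem,
        channels=channels,
        annotations=annotations,
        disorder=disorder,
    )


# --------------------------------------------------------------------
# Image datasets (PNG files + tab-separated manifest)
# --------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "filename",
    "record_id",
    "modality",
    "channel",
    "epoch_index",
    "offset_s",
    "stage",
    "disorder",
]


def write_image_dataset(
    images: list[SpectrogramImage], out_dir: str | Path
) -> Path:
    """Write one PNG per image plus a tab-separated manifest; returns manifest path."""
    if not images:
        raise ValueError("cannot write an empty image dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        fname = (
            f"{img.record_id}_{img.modality}_{img.channel}_"
            f"e{img.epoch_index:04d}_o{img.offset_s:06.2f}.png"
        )
        Image.fromarray(img.pixels, mode="RGB").save(out_dir / fname)
        rows.append(
            {
                "filename": fname,
                "record_id": img.record_id,
                "modality": img.modality,
                "channel": img.channel,
                "epoch_index": img.epoch_index,
                "offset_s": img.offset_s,
                "stage": img.stage,
                "disorder": img.disorder,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


def read_image_dataset(manifest: str | Path) -> list[SpectrogramImage]:
    """Read a PNG + manifest dataset back into :class:`SpectrogramImage` objects."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest}: manifest missing columns {missing}")
    images: list[SpectrogramImage] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        png = manifest.parent / row.filename
        if not png.exists():
            raise FileNotFoundError(f"{manifest} row {rownum}: missing PNG {png}")
        try:
            images.append(
                SpectrogramImage(
                    pixels=np.asarray(Image.open(png).convert("RGB")),
                    record_id=str(row.record_id),
                    modality=str(row.modality),
                    channel=str(row.channel),
                    epoch_index=int(row.epoch_index),
                    offset_s=float(row.offset_s),
                    stage=str(row.stage),
                    disorder=str(row.disorder),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{manifest} row {rownum}: {exc}") from exc
    return images
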