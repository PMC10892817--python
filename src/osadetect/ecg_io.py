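"""Reading and writing WFDB-style ECG records, per-minute apnea annotations,
and encoded-image datasets.

The signal container follows the PhysioNet WFDB conventions used by the
Apnea-ECG database: a text header (``<record>.hea``) naming a binary signal
file in format 16 (little-endian int16 ADC units), plus an annotation file of
16-bit MIT annotation words holding one ``N``/``A`` label per minute.  Only the
single-lead subset of the format needed for that database is supported; see
:func:`read_record` / :func:`write_record`.

Encoded images are persisted in two forms: a lossless ``.npz`` container (the
canonical training input; float32 pixels round-trip bit-exactly) and an
optional 8-bit PNG for visual inspection.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError

#: annotation type codes (MIT convention) <-> per-minute apnea symbols.
#: Code 1 is NORMAL ("N", normal breathing); code 8 is displayed as "A" and is
#: used by the Apnea-ECG annotators for minutes with disordered breathing.
_CODE_TO_SYMBOL = {1: "N", 8: "A"}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

_SKIP = 59   # long interval follows (4 bytes)
_NUM = 60    # annotator fields we tolerate but ignore
_SUB = 61
_CHN = 62
_AUX = 63


@dataclass
class EcgRecord:
    """A sampled single-lead ECG with optional per-minute labels.

    Parameters
    ----------
    record_id
        Name of the record (stem of the WFDB files).
    samples
        Signal in physical units (millivolts).
    fs
        Sampling rate in Hz.
    labels
        One ``"N"``/``"A"`` label per annotated minute, or ``None``.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("ECG samples must be finite")
        if self.labels is not None:
            bad = sorted(set(self.labels) - {"N", "A"})
            if bad:
                raise ValidationError(f"labels must be 'N' or 'A', got {bad}")
            if len(self.labels) > int(self.duration_minutes):
                raise ValidationError(
                    f"{len(self.labels)} labels but only "
                    f"{int(self.duration_minutes)} whole minutes of signal"
                )

    @property
    def duration_minutes(self) -> float:
        return len(self.samples) / self.fs / 60.0


@dataclass
class EncodedImage:
    """A 224x224x3 image in [0, 1] produced by one of the encoders."""

    pixels: np.ndarray
    modality: str                      # "CWT" | "GASF" | "GADF"
    source: tuple[str, int] = ("", 0)  # (record_id, minute_index)
    label: str = "N"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (224, 224, 3):
            raise ValidationError(
                f"encoded image must be 224x224x3, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValidationError("encoded image pixels must lie in [0, 1]")
        if self.modality not in ("CWT", "GASF", "GADF"):
            raise ValidationError(f"unknown modality {self.modality!r}")


@dataclass
class DatasetManifest:
    """Index of persisted encoded images; one row per image."""

    entries: list[dict] = field(default_factory=list)

    COLUMNS = ("record_id", "minute_index", "modality", "label", "path")

    def key_set(self) -> set[tuple[str, int, str]]:
        return {
            (e["record_id"], int(e["minute_index"]), e["modality"])
            for e in self.entries
        }


# ---------------------------------------------------------------------------
# WFDB header / signal
# ---------------------------------------------------------------------------

def read_record(path: str | Path) -> EcgRecord:
    """Read a WFDB header/signal pair into an :class:`EcgRecord`.

    ``path`` may point at the ``.hea`` file or be the extensionless record
    stem.  Only channel 0 is returned (the target data are single-lead); the
    signal is converted to physical units via ``(adc - baseline) / gain``.
    An annotation file ``<record>.apn`` next to the header, if present, is
    loaded as per-minute labels.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header at {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_id = head[0]
    n_sig = int(head[1])
    if n_sig < 1:
        raise FormatError(f"record {record_id} declares zero signal channels")
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    if len(lines) < 2:
        raise FormatError(f"header {hea} has no signal specification lines")
    sig = lines[1].split()  # channel 0 only
    dat_name, fmt_field = sig[0], sig[1]
    fmt = int(fmt_field.split("x")[0])  # tolerate samples-per-frame suffix
    if fmt != 16:
        raise FormatError(f"unsupported WFDB signal format {fmt} (only 16)")
    gain, baseline = 200.0, 0.0
    if len(sig) > 2:
        g = sig[2]
        if "/" in g:
            g = g.split("/")[0]
        if "(" in g:
            g, base = g.split("(")
            baseline = float(base.rstrip(")"))
        gain = float(g) if float(g) != 0 else 200.0
    elif len(sig) > 4:
        baseline = float(sig[4])

    dat = hea.parent / dat_name
    try:
        raw = np.fromfile(dat, dtype="<i2")
    except OSError as exc:
        raise FileNotFoundError(f"cannot read signal file {dat}: {exc}") from exc
    if n_samples:
        if raw.size < n_samples * n_sig:
            raise FormatError(
                f"{dat} holds {raw.size} samples, header expects {n_samples * n_sig}"
            )
        raw = raw[: n_samples * n_sig]
    adc = raw.reshape(-1, n_sig)[:, 0].astype(np.float64)
    samples = (adc - baseline) / gain

    labels = None
    apn = hea.with_suffix(".apn")
    if apn.exists():
        labels = read_annotations(apn)
        n_min = int(len(samples) / fs / 60.0)
        if len(labels) > n_min:
            labels = labels[:n_min]
    return EcgRecord(record_id=record_id, samples=samples, fs=fs, labels=labels)


def write_record(record: EcgRecord, directory: str | Path,
                 gain: float = 200.0) -> Path:
    """Write ``record`` as a WFDB header/signal pair (format 16).

    Returns the header path.  Labels, if present, are written as a per-minute
    annotation file ``<record>.apn``.  The ADC gain (units per mV) bounds the
    round-trip quantization error at ``1/(2*gain)`` mV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.samples * gain)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValidationError("signal amplitude exceeds int16 range at this gain")
    adc = adc.astype("<i2")
    dat = directory / f"{record.record_id}.dat"
    adc.tofile(dat)
    hea = directory / f"{record.record_id}.hea"
    n = len(adc)
    first = int(adc[0]) if n else 0
    chks = int(np.sum(adc.astype(np.int64)) % 65536)
    hea.write_text(
        f"{record.record_id} 1 {record.fs:g} {n}\n"
        f"{record.record_id}.dat 16 {gain:g}(0)/mV 16 0 {first} {chks} 0 ECG\n"
    )
    if record.labels is not None:
        write_annotations(
            record.labels, directory / f"{record.record_id}.apn", fs=record.fs
        )
    return hea


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[str]:
    """Read per-minute apnea labels from an MIT-format annotation file.

    Returns one symbol (``"N"`` or ``"A"``) per stored annotation, in
    chronological order.  NUM/SUB/CHN/AUX modifier words are skipped; any
    annotation whose type code does not map onto the binary label space is a
    :class:`FormatError`.
    """
    data = Path(path).read_bytes()
    labels: list[str] = []
    i = 0
    while i + 1 < len(data):
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        if code == 0:      # end of annotations
            break
        if code == _SKIP:  # 4-byte long interval follows; label-irrelevant
            i += 4
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            aux_len = word & 0x3FF
            i += aux_len + (aux_len % 2)
            continue
        sym = _CODE_TO_SYMBOL.get(code)
        if sym is None:
            raise FormatError(
                f"annotation type code {code} in {path} is outside the "
                f"N/A label space"
            )
        labels.append(sym)
    return labels


def write_annotations(labels: Sequence[str], path: str | Path,
                      fs: float = 100.0) -> Path:
    """Write per-minute labels as an MIT-format annotation file.

    One annotation is placed at the start of each minute.  Minute strides at
    ordinary sampling rates exceed the 10-bit short interval, so each
    annotation is preceded by a long SKIP word carrying the full sample delta.
    """
    path = Path(path)
    out = bytearray()
    delta = int(round(fs * 60))
    for k, sym in enumerate(labels):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise FormatError(f"cannot encode label {sym!r}; expected 'N' or 'A'")
        step = 0 if k == 0 else delta
        out += struct.pack("<H", (_SKIP << 10))
        out += struct.pack("<HH", (step >> 16) & 0xFFFF, step & 0xFFFF)
        out += struct.pack("<H", (code << 10))
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))
    return path


# ---------------------------------------------------------------------------
# encoded-image datasets
# ---------------------------------------------------------------------------

def write_image_dataset(images: Sequence[EncodedImage], directory: str | Path,
                        png: bool = False) -> DatasetManifest:
    """Persist encoded images losslessly and return the manifest.

    Each image becomes ``<record>_<minute>_<modality>.npz`` (float32 pixels,
    bit-exact on re-read) and optionally an 8-bit PNG preview.  Duplicate
    (record, minute, modality) keys are a :class:`ValidationError`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest()
    seen: set[tuple[str, int, str]] = set()
    for img in images:
        rid, minute = img.source
        key = (rid, int(minute), img.modality)
        if key in seen:
            raise ValidationError(f"duplicate image key {key}")
        seen.add(key)
        stem = f"{rid}_{minute:04d}_{img.modality}"
        npz_path = directory / f"{stem}.npz"
        np.savez(npz_path, pixels=img.pixels, modality=img.modality,
                 record_id=rid, minute_index=minute, label=img.label)
        if png:
            from PIL import Image

            arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(directory / f"{stem}.png")
        manifest.entries.append(
            {"record_id": rid, "minute_index": minute, "modality": img.modality,
             "label": img.label, "path": str(npz_path)}
        )
    write_manifest(manifest, directory / "manifest.csv")
    return manifest


def read_encoded_image(path: str | Path) -> EncodedImage:
    """Re-load an image written by :func:`write_image_dataset` (bit-exact)."""
    with np.load(path, allow_pickle=False) as z:
        return EncodedImage(
            pixels=z["pixels"],
            modality=str(z["modality"]),
            source=(str(z["record_id"]), int(z["minute_index"])),
            label=str(z["label"]),
        )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=DatasetManifest.COLUMNS)
        w.writeheader()
        for e in manifest.entries:
            w.writerow({c: e[c] for c in DatasetManifest.COLUMNS})
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    manifest = DatasetManifest()
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            if row["label"] not in ("N", "A"):
                raise FormatError(f"manifest label {row['label']!r} not in N/A")
            row["minute_index"] = int(row["minute_index"])
            manifest.entries.append(row)
    keys = manifest.key_set()
    if len(keys) != len(manifest.entries):
        raise FormatError("manifest contains duplicate (record, minute, modality) keys")
    return manifest
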