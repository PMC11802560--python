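"""EDF and seizure-annotation I/O.

Records are exchanged as 16-bit European Data Format (EDF) files, the
format CHB-MIT-style corpora use.  Reading goes through MNE's EDF
reader; writing is a minimal EDF implementation (no installed package
exports EDF) emitting 1-s data records with per-channel physical
scaling, validated by round-tripping through MNE.

Seizure annotations travel in one of two text dialects:

* a simple sidecar TSV next to the EDF (``<stem>.annotations.tsv``)
  with one ``onset_s<TAB>offset_s`` line per seizure — what the
  synthetic writer produces;
* the CHB-MIT plain-text summary format with "File Name:" blocks and
  "Seizure Start/End Time: N seconds" lines, parsed leniently.
"""

from __future__ import annotations

import datetime
import logging
import re
import warnings
from pathlib import Path

import numpy as np

from .simulate import EEGRecord

log = logging.getLogger(__name__)

_EDF_DIGITAL_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    text = f"{value}"[:width]
    return text.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | Path) -> Path:
    """Write a record as 16-bit EDF plus a TSV annotation sidecar.

    Data records are 1 s long, so the signal is zero-padded up to a
    whole number of seconds; each channel is scaled to its own physical
    range to minimize quantization error (16-bit).
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch, n_samp = record.data.shape
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = record.data

    pmax = np.maximum(np.abs(padded).max(axis=1), 1.0)
    digital = np.round(padded / pmax[:, None] * _EDF_DIGITAL_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(record.patient_id, 80),
            _ascii_field("synthetic EEG", 80),
            _ascii_field(now.strftime("%d.%m.%y"), 8),
            _ascii_field(now.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (n_ch + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_ch, 4),
        ]
    )
    fields = [
        [_ascii_field(name, 16) for name in record.channel_names],
        [_ascii_field("", 80)] * n_ch,  # transducer
        [_ascii_field("uV", 8)] * n_ch,
        [_ascii_field(f"{-p:.6g}"[:8], 8) for p in pmax],
        [_ascii_field(f"{p:.6g}"[:8], 8) for p in pmax],
        [_ascii_field(-_EDF_DIGITAL_MAX, 8)] * n_ch,
        [_ascii_field(_EDF_DIGITAL_MAX, 8)] * n_ch,
        [_ascii_field("", 80)] * n_ch,  # prefiltering
        [_ascii_field(fs, 8)] * n_ch,
        [_ascii_field("", 32)] * n_ch,
    ]
    signal_header = b"".join(b"".join(group) for group in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())

    write_annotation_sidecar(record.annotations, sidecar_path(path))
    return path


def sidecar_path(edf_path: str | Path) -> Path:
    p = Path(edf_path)
    return p.with_name(p.stem + ".annotations.tsv")


def write_annotation_sidecar(
    annotations: list[tuple[float, float]], path: str | Path
) -> None:
    lines = [f"{onset:g}\t{offset:g}" for onset, offset in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotation_sidecar(path: str | Path) -> list[tuple[float, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        onset, offset = line.split("\t")
        out.append((float(onset), float(offset)))
    return out


_SUMMARY_FILE = re.compile(r"file\s+name\s*:\s*(\S+)", re.I)
_SUMMARY_START = re.compile(r"seizure(?:\s+\d+)?\s+start\s+time\s*:\s*([\d.]+)", re.I)
_SUMMARY_END = re.compile(r"seizure(?:\s+\d+)?\s+end\s+time\s*:\s*([\d.]+)", re.I)


def parse_chbmit_summary(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Parse a CHB-MIT-style seizure summary into per-file interval lists.

    Handles both ``Seizure Start Time`` and ``Seizure N Start Time``
    spellings; times are taken in seconds from file start.
    """
    per_file: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    pending_start: float | None = None
    for line in Path(path).read_text().splitlines():
        m = _SUMMARY_FILE.search(line)
        if m:
            current = m.group(1)
            per_file.setdefault(current, [])
            pending_start = None
            continue
        m = _SUMMARY_START.search(line)
        if m and current is not None:
            pending_start = float(m.group(1))
            continue
        m = _SUMMARY_END.search(line)
        if m and current is not None and pending_start is not None:
            per_file[current].append((pending_start, float(m.group(1))))
            pending_start = None
    return per_file


def read_edf(
    path: str | Path,
    annotations: list[tuple[float, float]] | None = None,
    patient_id: str | None = None,
) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (microvolts).

    Annotations come from, in order of precedence: the ``annotations``
    argument, the TSV sidecar next to the file, or — absent both — an
    empty list with a logged warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"malformed EDF file {path}: {exc}") from exc

    data = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned EEG
    if annotations is None:
        sc = sidecar_path(path)
        if sc.exists():
            annotations = read_annotation_sidecar(sc)
        else:
            log.warning("no annotation sidecar for %s; empty annotation list", path)
            annotations = []
    return EEGRecord(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=list(annotations),
        patient_id=patient_id or path.stem,
    )


def save_record_npz(record: EEGRecord, path: str | Path) -> None:
    """Compact columnar dump used for intermediate pipeline artifacts."""
    np.savez(
        path,
        data=record.data,
        fs=record.fs,
        channel_names=np.array(record.channel_names),
        annotations=np.array(record.annotations, dtype=float).reshape(-1, 2),
        patient_id=record.patient_id,
    )


def load_record_npz(path: str | Path) -> EEGRecord:
    with np.load(path, allow_pickle=False) as z:
        return EEGRecord(
            data=z["data"],
            fs=float(z["fs"]),
            channel_names=[str(c) for c in z["channel_names"]],
            annotations=[tuple(a) for a in z["annotations"]],
            patient_id=str(z["patient_id"]),
        )
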