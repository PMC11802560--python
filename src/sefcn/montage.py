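"""Bipolar 10-20 montage handling.

The network operates on a fixed 32-row canonical channel layout: the
23 CHB-MIT-style bipolar derivations first, then nine zero-padding
slots named ``PAD_0`` ... ``PAD_8``.  Keeping the layout fixed lets a
model trained on one cohort be applied to any record whose channels are
a subset of the canonical list, and makes channel-importance reports
comparable across records.
"""

from __future__ import annotations

import re
import warnings

#: Default 23 bipolar derivations (CHB-MIT common montage, distinct labels).
#: CHB-MIT's native list repeats "T8-P8"; a duplicate label cannot live in a
#: name->row map, so the slot is filled with the midline-adjacent "FC1-FC2".
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8",
    "FC1-FC2",
)

N_MODEL_ROWS = 32

#: Canonical 32-row order fed to the network: real channels then padding.
CANONICAL_32: tuple[str, ...] = DEFAULT_CHANNELS + tuple(
    f"PAD_{k}" for k in range(N_MODEL_ROWS - len(DEFAULT_CHANNELS))
)

PAD_PATTERN = re.compile(r"^PAD_\d+$")

_ELECTRODE_PATTERN = re.compile(r"^(FP|FT|FC|CP|TP|PO|F|T|C|P|O|A)(\d+|Z)$", re.I)

#: Electrode-name prefix -> cortical region (10-20 nomenclature).
_REGIONS = {
    "FP": "frontopolar",
    "F": "frontal",
    "FT": "frontotemporal",
    "FC": "frontocentral",
    "T": "temporal",
    "TP": "temporoparietal",
    "C": "central",
    "CP": "centroparietal",
    "P": "parietal",
    "PO": "parietooccipital",
    "O": "occipital",
    "A": "auricular",
}


def is_padding(label: str) -> bool:
    """True for synthetic zero-padding row labels (``PAD_k``)."""
    return PAD_PATTERN.match(label) is not None


def split_bipolar(label: str) -> tuple[str, str] | None:
    """Split a bipolar derivation label ``"A-B"`` into its two electrodes.

    Returns ``None`` (with a warning) when the label is not parseable as a
    pair of 10-20 electrode names, e.g. for padding rows.
    """
    parts = label.upper().split("-")
    if len(parts) != 2 or not all(_ELECTRODE_PATTERN.match(p) for p in parts):
        warnings.warn(f"channel label {label!r} is not a bipolar 10-20 pair; skipped")
        return None
    return parts[0], parts[1]


def electrode_region(electrode: str) -> str:
    """Cortical region of a single 10-20 electrode name (e.g. FZ -> frontal)."""
    m = _ELECTRODE_PATTERN.match(electrode.upper())
    if not m:
        raise ValueError(f"unrecognized 10-20 electrode name: {electrode!r}")
    prefix = m.group(1).upper()
    side = m.group(2).upper()
    region = _REGIONS[prefix]
    if side == "Z":
        lat = "midline"
    else:
        lat = "left" if int(side) % 2 == 1 else "right"
    return f"{lat} {region}"
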