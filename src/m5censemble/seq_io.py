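"""Reading, validation and numeric encoding of fixed-length RNA windows.

The pipeline operates on 41-nt RNA windows centered on a candidate
cytosine (position 21, 1-based). Windows arrive as FASTA records; binary
labels (1 = m5C site, 0 = non-site) come either from a ``|label=`` header
suffix or from a two-column sidecar TSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("m5censemble")

WINDOW_LENGTH = 41
CENTER_POSITION = 21  # 1-based; must be C for a candidate m5C window
ALPHABET = "ACGU"
#: pinned numeric encoding, alphabetical over {A, C, G, U}
ENCODING = {"A": 1, "C": 2, "G": 3, "U": 4}
DECODING = {v: k for k, v in ENCODING.items()}


@dataclass(frozen=True)
class SequenceWindow:
    """One labeled 41-nt RNA window.

    Parameters
    ----------
    id : str
        Unique record identifier.
    sequence : str
        41 characters over {A, C, G, U}.
    label : int or None
        1 for an m5C site, 0 for a non-site, None when unlabeled
        (prediction mode).
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(
                f"window {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )


@dataclass
class LabeledDataset:
    """An ordered collection of windows with unique ids."""

    windows: list[SequenceWindow]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        ids = [w.id for w in self.windows]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate window id {dup!r}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def labels(self) -> np.ndarray:
        """Label vector; raises if any window is unlabeled."""
        if any(w.label is None for w in self.windows):
            raise ValueError("dataset contains unlabeled windows")
        return np.array([w.label for w in self.windows], dtype=int)


def validate_window(sequence: str, center_check: bool = True) -> list[str]:
    """Return all rule violations of a window sequence (empty list = valid).

    Checks length (41), alphabet ({A,C,G,U}, no ambiguity codes) and,
    when ``center_check`` is on, that position 21 (1-based) is C.
    """
    violations: list[str] = []
    if len(sequence) != WINDOW_LENGTH:
        violations.append(
            f"length: expected {WINDOW_LENGTH}, got {len(sequence)}"
        )
    bad = sorted({c for c in sequence if c not in ALPHABET})
    if bad:
        violations.append(
            "alphabet: invalid character(s) " + ", ".join(repr(c) for c in bad)
        )
    if (
        center_check
        and len(sequence) == WINDOW_LENGTH
        and sequence[CENTER_POSITION - 1] != "C"
    ):
        violations.append(
            f"center: position {CENTER_POSITION} must be C, "
            f"got {sequence[CENTER_POSITION - 1]!r}"
        )
    return violations


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if "T" in seq:
        logger.debug("record %s: converting T to U (DNA alphabet)", record_id)
        seq = seq.replace("T", "U")
    return seq


def _parse_header_label(description: str) -> int | None:
    for field in description.split("|")[1:]:
        if field.startswith("label="):
            value = field[len("label="):].strip()
            if value not in ("0", "1"):
                raise ValueError(
                    f"header label must be 0 or 1, got {value!r} "
                    f"in {description!r}"
                )
            return int(value)
    return None


def read_sidecar_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) TSV of window labels."""
    labels: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row_num, row in enumerate(csv.reader(handle, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if row_num == 1 and row[0].lower() == "id":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {row_num}: expected 2 columns")
            if row[1] not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {row_num}: label must be 0 or 1, "
                    f"got {row[1]!r}"
                )
            labels[row[0]] = int(row[1])
    return labels


def read_fasta(
    path: str | Path,
    label_source: str = "header",
    sidecar: str | Path | None = None,
    center_check: bool = True,
) -> LabeledDataset:
    """Read labeled windows from a FASTA file.

    Parameters
    ----------
    path : path
        FASTA file of 41-nt windows. T is transparently converted to U.
    label_source : {"header", "sidecar", "none"}
        "header" parses a ``|label=0/1`` suffix from record descriptions;
        "sidecar" reads labels from the TSV at ``sidecar``; "none" leaves
        all windows unlabeled (prediction mode).
    center_check : bool
        Require C at position 21 (default on).
    """
    if label_source not in ("header", "sidecar", "none"):
        raise ValueError(f"unknown label_source {label_source!r}")
    sidecar_labels: dict[str, int] = {}
    if label_source == "sidecar":
        if sidecar is None:
            raise ValueError("label_source='sidecar' requires a sidecar path")
        sidecar_labels = read_sidecar_labels(sidecar)

    windows: list[SequenceWindow] = []
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id.split("|")[0]
        seq = _normalize_sequence(str(record.seq), rid)
        violations = validate_window(seq, center_check=center_check)
        if violations:
            raise ValueError(
                f"{path}: record {rid!r}: " + "; ".join(violations)
            )
        label: int | None = None
        if label_source == "header":
            label = _parse_header_label(record.description)
        elif label_source == "sidecar":
            label = sidecar_labels.get(rid)
        windows.append(SequenceWindow(id=rid, sequence=seq, label=label))
    return LabeledDataset(windows=windows, provenance=str(path))


def write_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    """Write windows as FASTA with ``|label=`` header suffixes (UTF-8, LF)."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for w in dataset.windows:
            header = w.id if w.label is None else f"{w.id}|label={w.label}"
            handle.write(f">{header}\n{w.sequence}\n")


def encode_numeric(window: SequenceWindow | str) -> np.ndarray:
    """Encode a window as integers with A=1, C=2, G=3, U=4."""
    seq = window.sequence if isinstance(window, SequenceWindow) else window
    try:
        return np.array([ENCODING[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence")


def decode_numeric(encoded: Sequence[int]) -> str:
    """Inverse of :func:`encode_numeric`."""
    return "".join(DECODING[int(v)] for v in encoded)


def write_feature_table(
    dataset: LabeledDataset,
    vectors: Iterable,
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write one feature row per window: id, [label,] named features.

    Column order is the pinned feature-assembly order; output is
    deterministic (byte-identical across runs on identical input).
    """
    vectors = list(vectors)
    if len(vectors) != len(dataset.windows):
        raise ValueError(
            f"{len(vectors)} vectors for {len(dataset.windows)} windows"
        )
    names: list[str] | None = None
    for v in vectors:
        if names is None:
            names = list(v.names)
        elif list(v.names) != names:
            raise ValueError("feature vectors disagree on feature names")
    labeled = bool(dataset.windows) and all(
        w.label is not None for w in dataset.windows
    )
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        header = ["id"] + (["label"] if labeled else []) + (names or [])
        handle.write(delimiter.join(header) + "\n")
        for w, v in zip(dataset.windows, vectors):
            row = [w.id] + ([str(w.label)] if labeled else [])
            row += [_format_value(x) for x in v.values]
            handle.write(delimiter.join(row) + "\n")


def _format_value(x: float) -> str:
    # integers print without a trailing .0; floats at 12 significant digits
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{float(x):.12g}"
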