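"""Reading, validating and writing fixed-length RNA windows.

The prediction unit throughout the package is a 41-nt RNA window centred on
the candidate 2'-O-methylation site (position 21, 1-based, for L=41).
Sequences arrive as FASTA; DNA-style ``T`` is silently mapped to ``U`` and
lowercase is uppercased. Any other ambiguity code (N, R, Y, ...) is rejected
rather than imputed, because imputation would distort frequency-based
encoders downstream.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = ("A", "C", "G", "U")
_VALID = frozenset(ALPHABET)

DEFAULT_LENGTH = 41


class SequenceError(ValueError):
    """A sequence violates the window contract (length or alphabet)."""


@dataclass(frozen=True)
class RnaRecord:
    """One validated fixed-length RNA window.

    Attributes
    ----------
    id : str
        FASTA identifier.
    seq : str
        Uppercase sequence over {A, C, G, U}, length ``L``.
    label : int or None
        1 for a 2'-O-methylation (Nm) site, 0 for a non-site, None if unknown.
    center_index : int
        1-based position of the candidate site, ``ceil(L / 2)``.
    """

    id: str
    seq: str
    label: Optional[int] = None
    center_index: int = field(default=0)

    def __post_init__(self) -> None:
        bad = [(i + 1, c) for i, c in enumerate(self.seq) if c not in _VALID]
        if bad:
            pos, char = bad[0]
            raise SequenceError(
                f"record {self.id!r}: invalid character {char!r} at position {pos}"
            )
        expected_center = math.ceil(len(self.seq) / 2)
        if self.center_index == 0:
            object.__setattr__(self, "center_index", expected_center)
        elif self.center_index != expected_center:
            raise SequenceError(
                f"record {self.id!r}: center_index {self.center_index} != "
                f"ceil(L/2) = {expected_center}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise SequenceError(f"record {self.id!r}: label must be 0/1")


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase and map T->U; reject anything outside {A,C,G,U,T}."""
    seq = raw.strip().upper().replace("T", "U")
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise SequenceError(
                f"record {record_id!r}: invalid character {c!r} at position {i + 1}"
            )
    return seq


def read_fasta(
    path: str | Path,
    expected_length: int = DEFAULT_LENGTH,
    policy: Literal["strict", "lenient"] = "strict",
    label: Optional[int] = None,
) -> list[RnaRecord]:
    """Read fixed-length RNA windows from a FASTA file.

    Parameters
    ----------
    path : path to a (multi-record) FASTA file.
    expected_length : required window length L (>= 5).
    policy : "strict" raises on a wrong-length record; "lenient" skips it
        with a logged warning. Alphabet violations always raise.
    label : optional class label attached to every record (positive /
        negative sequences are conventionally supplied in separate files).

    Returns records in file order.
    """
    if expected_length < 5:
        raise ValueError("expected_length must be >= 5")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[RnaRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq), entry.id)
        if len(seq) != expected_length:
            msg = (
                f"record {entry.id!r}: length {len(seq)} != expected "
                f"{expected_length}"
            )
            if policy == "strict":
                raise SequenceError(msg)
            logger.warning("skipping %s", msg)
            continue
        records.append(RnaRecord(id=entry.id, seq=seq, label=label))
    return records


def write_fasta(records: Iterable[RnaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_label_manifest(path: str | Path) -> dict[str, int]:
    """Two-column CSV ``id,label`` -> mapping. A header row is optional."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            if row[0] == "id" and row[1] == "label":
                continue
            labels[row[0]] = int(row[1])
    return labels


def write_predictions(
    records: Sequence[RnaRecord],
    scores: Sequence[float],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    """Write a prediction table: ``predicted_label,probability,sequence``."""
    if not (len(records) == len(scores) == len(labels)):
        raise ValueError(
            f"length mismatch: {len(records)} records, {len(scores)} scores, "
            f"{len(labels)} labels"
        )
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"probability {s} outside [0, 1]")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["predicted_label", "probability", "sequence"])
        for rec, score, lab in zip(records, scores, labels):
            writer.writerow([int(lab), f"{score:.6f}", rec.seq])


def read_predictions(path: str | Path) -> tuple[list[int], list[float], list[str]]:
    """Re-parse a prediction table written by :func:`write_predictions`."""
    labels: list[int] = []
    scores: list[float] = []
    seqs: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["predicted_label", "probability", "sequence"]:
            raise ValueError(f"unexpected header {header!r}")
        for row in reader:
            labels.append(int(row[0]))
            scores.append(float(row[1]))
            seqs.append(row[2])
    return labels, scores, seqs
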