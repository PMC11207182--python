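"""Synthetic benchmark generator for Nm-site window classification.

Real Nm benchmarks are 41-nt windows centred on the candidate site, with
balanced positive/negative classes and a positive-class enrichment of
A, G, A, U immediately 3' of the site (positions 22-25, 1-based). The
generator reproduces exactly that statistical skeleton: negatives are pure
background draws; positives are background draws with each motif base
planted at its position with probability ``enrich_prob``, independently
per position.

It deliberately does not mimic real RNA-type composition, redundancy
structure, or genome context — it exists so the full encoder / baseline /
stacking pipeline can be exercised and calibrated offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import ALPHABET, RnaRecord


@dataclass(frozen=True)
class MotifSpec:
    """Positive-class positional enrichment specification."""

    positions: tuple[int, ...] = (22, 23, 24, 25)  # 1-based
    bases: tuple[str, ...] = ("A", "G", "A", "U")
    enrich_prob: float = 0.7
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.bases):
            raise ValueError("positions and bases must have equal length")
        if not 0.0 <= self.enrich_prob <= 1.0:
            raise ValueError("enrich_prob must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background distribution must sum to 1")


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[RnaRecord, ...]
    spec: MotifSpec
    seed: int
    n_pos: int
    n_neg: int

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])


def generate(
    n_pos: int,
    n_neg: int,
    L: int = 41,
    spec: Optional[MotifSpec] = None,
    seed: int = 0,
    center_base: Optional[str] = None,
) -> SyntheticDataset:
    """Draw a balanced (or arbitrary-count) labelled synthetic dataset.

    ``center_base`` optionally fixes the central nucleotide in both classes,
    emulating the nucleotide-specific (Am/Cm/Gm/Um) benchmark variants.
    Deterministic for a fixed seed. Positives come first, then negatives.
    """
    spec = spec or MotifSpec()
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be non-negative")
    if spec.positions and max(spec.positions) > L:
        raise ValueError(f"motif position {max(spec.positions)} exceeds L={L}")
    rng = np.random.default_rng(seed)
    center = (L + 1) // 2
    records: list[RnaRecord] = []
    for label, count in ((1, n_pos), (0, n_neg)):
        for i in range(count):
            chars = list(rng.choice(list(ALPHABET), size=L, p=spec.background))
            if label == 1:
                for pos, base in zip(spec.positions, spec.bases):
                    if rng.random() < spec.enrich_prob:
                        chars[pos - 1] = base
            if center_base is not None:
                chars[center - 1] = center_base
            records.append(
                RnaRecord(id=f"{'pos' if label else 'neg'}_{i}", seq="".join(chars),
                          label=label)
            )
    return SyntheticDataset(tuple(records), spec, seed, n_pos, n_neg)


def train_test_split(
    dataset: SyntheticDataset, test_fraction: float = 0.3, seed: int = 0
) -> tuple[list[RnaRecord], list[RnaRecord]]:
    """Class-balanced shuffle split into training and test record lists."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[RnaRecord] = []
    test: list[RnaRecord] = []
    for label in (1, 0):
        group = [r for r in dataset.records if r.label == label]
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test
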