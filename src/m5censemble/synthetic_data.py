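"""Synthetic labeled window generator.

Emulates the structure of m5C benchmark sets: balanced classes of
41-nt windows with a fixed C at position 21, whose positive class
deviates from the negative background by per-position nucleotide
enrichment — the pattern a two-sample logo of real data shows around
the modified cytosine. Each position is sampled independently from a
class-specific 41 x 4 probability table.

The default model uses a uniform background and shifts a fraction
``effect`` of the probability mass toward G at eight flanking
positions (17-20 and 22-25) in positives, so the per-position G
probability there is 0.25 + 0.75 * effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import (
    ALPHABET,
    CENTER_POSITION,
    WINDOW_LENGTH,
    LabeledDataset,
    SequenceWindow,
)

#: flanking positions (1-based) carrying the positive-class enrichment
DEFAULT_ENRICHED_POSITIONS = (17, 18, 19, 20, 22, 23, 24, 25)
DEFAULT_ENRICHED_BASE = "G"


@dataclass(frozen=True)
class LogoModel:
    """Per-position nucleotide distributions of the two classes.

    pos_table / neg_table are 41 x 4 row-stochastic matrices (columns
    ordered A, C, G, U); position 21 is a deterministic C in both.
    """

    pos_table: np.ndarray
    neg_table: np.ndarray
    effect: float
    seed: int

    def __post_init__(self) -> None:
        for name, table in (("pos", self.pos_table), ("neg", self.neg_table)):
            if table.shape != (WINDOW_LENGTH, len(ALPHABET)):
                raise ValueError(f"{name}_table must be 41x4")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name}_table rows must sum to 1")


def default_logo(
    effect: float,
    seed: int = 0,
    enriched_positions: tuple[int, ...] = DEFAULT_ENRICHED_POSITIONS,
    enriched_base: str = DEFAULT_ENRICHED_BASE,
) -> LogoModel:
    """Uniform background with G-enrichment at 8 flanking positions.

    At each enriched position the positive-class distribution is
    (1 - effect) * uniform + effect * point-mass(enriched_base); at
    effect = 1 those positions are deterministically the enriched base.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must be in [0, 1]")
    uniform = np.full(len(ALPHABET), 1.0 / len(ALPHABET))
    neg = np.tile(uniform, (WINDOW_LENGTH, 1))
    center_row = np.zeros(len(ALPHABET))
    center_row[ALPHABET.index("C")] = 1.0
    neg[CENTER_POSITION - 1] = center_row
    pos = neg.copy()
    base_idx = ALPHABET.index(enriched_base)
    point = np.zeros(len(ALPHABET))
    point[base_idx] = 1.0
    for position in enriched_positions:
        pos[position - 1] = (1.0 - effect) * uniform + effect * point
    return LogoModel(pos_table=pos, neg_table=neg, effect=effect, seed=seed)


def generate(
    n_pos: int, n_neg: int, logo: LogoModel
) -> LabeledDataset:
    """Sample a labeled dataset of n_pos positive + n_neg negative windows.

    Sequences are drawn i.i.d. per position from the class table;
    reproducible (byte-identical) for a fixed logo seed.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be non-negative")
    rng = np.random.default_rng(logo.seed)
    alphabet = np.array(list(ALPHABET))
    windows: list[SequenceWindow] = []
    for label, n, table, tag in (
        (1, n_pos, logo.pos_table, "pos"),
        (0, n_neg, logo.neg_table, "neg"),
    ):
        # one draw per (window, position), vectorized by position
        draws = np.empty((n, WINDOW_LENGTH), dtype=int)
        for position in range(WINDOW_LENGTH):
            draws[:, position] = rng.choice(
                len(alphabet), size=n, p=table[position]
            )
        for i in range(n):
            windows.append(
                SequenceWindow(
                    id=f"{tag}_{i:05d}",
                    sequence="".join(alphabet[draws[i]]),
                    label=label,
                )
            )
    return LabeledDataset(windows=windows, provenance="synthetic")
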