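"""Bout-to-bout transition analysis and cosine divergence from a baseline.

The sequence analysis is time-agnostic: an ethogram is reduced to the
ordered list of bout labels (inter-bout intervals and bout durations are
discarded), adjacent label pairs are counted into a square matrix over the
catalogue alphabet, counts are normalized per animal (removing inter-animal
variability in bout number), and each subject's matrix is compared to the
same subject's sated-baseline matrix by cosine distance of the row-major
flattened vectors.  Cosine distance ignores overall transition volume, so
subjects with different numbers of bouts remain comparable; for nonnegative
frequency vectors it lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ethogram import BoutSequence

logger = logging.getLogger(__name__)

MODES = ("conditional", "global")


def extract_label_sequence(b: BoutSequence) -> list[str]:
    """Project a bout sequence to its ordered labels, discarding all timing."""
    return [bout.label for bout in b.bouts]


@dataclass(frozen=True)
class TransitionCounts:
    """Raw adjacent-pair counts over an ordered alphabet.

    ``counts[i, j]`` is the number of times behavior ``alphabet[i]`` was
    immediately followed by ``alphabet[j]``; the total equals
    ``max(n_bouts - 1, 0)``.
    """

    alphabet: tuple[str, ...]
    counts: np.ndarray
    n_bouts: int

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the alphabet")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if int(self.counts.sum()) != max(self.n_bouts - 1, 0):
            raise ValueError("count total must equal max(n_bouts - 1, 0)")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionMatrix:
    """Normalized transition frequencies over an ordered alphabet.

    ``mode="conditional"``: each observed row (a behavior with at least one
    outgoing transition) is a probability distribution over the next
    behavior; unobserved rows are all-zero.  ``mode="global"``: entries are
    proportions of all transitions and sum to 1.  ``undefined`` marks a
    matrix built from fewer than two bouts (no transitions at all).
    """

    alphabet: tuple[str, ...]
    values: np.ndarray
    mode: str
    observed_rows: np.ndarray = field(repr=False)
    undefined: bool = False

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.values.shape != (n, n):
            raise ValueError("values must be square over the alphabet")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alphabet, columns=self.alphabet)


def count_transitions(
    seq: Sequence[str], alphabet: Sequence[str]
) -> TransitionCounts:
    """Count adjacent pairs ``(seq[k], seq[k+1])`` into a square matrix.

    Sequences of length 0 or 1 give an all-zero matrix.
    """
    alphabet = tuple(alphabet)
    index = {label: i for i, label in enumerate(alphabet)}
    bad = [l for l in seq if l not in index]
    if bad:
        raise ValueError(f"labels outside alphabet: {sorted(set(bad))}")
    counts = np.zeros((len(alphabet), len(alphabet)), dtype=np.int64)
    for a, b in zip(seq, seq[1:]):
        counts[index[a], index[b]] += 1
    return TransitionCounts(alphabet=alphabet, counts=counts, n_bouts=len(seq))


def normalize_transitions(
    c: TransitionCounts, mode: str = "conditional"
) -> TransitionMatrix:
    """Normalize counts within the animal.

    ``conditional`` divides each observed row by its row sum (row-stochastic
    result); ``global`` divides everything by the total transition count.
    With zero transitions the matrix is all-zero and flagged ``undefined``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    counts = c.counts.astype(float)
    row_sums = counts.sum(axis=1)
    observed = row_sums > 0
    values = np.zeros_like(counts)
    if c.total == 0:
        return TransitionMatrix(c.alphabet, values, mode, observed, undefined=True)
    if mode == "conditional":
        values[observed] = counts[observed] / row_sums[observed, None]
    else:
        values = counts / c.total
    return TransitionMatrix(c.alphabet, values, mode, observed, undefined=False)


def average_matrices(
    ms: Iterable[TransitionMatrix], skip_undefined: bool = True
) -> TransitionMatrix:
    """Elementwise mean of matrices sharing alphabet and mode.

    Undefined matrices (subjects with fewer than two bouts) are excluded
    from the group average by default, with the exclusion count logged.
    """
    ms = list(ms)
    if not ms:
        raise ValueError("no matrices to average")
    alphabet, mode = ms[0].alphabet, ms[0].mode
    for m in ms:
        if m.alphabet != alphabet or m.mode != mode:
            raise ValueError("matrices must share alphabet and mode")
    kept = [m for m in ms if not (skip_undefined and m.undefined)]
    if len(kept) < len(ms):
        logger.warning(
            "average_matrices: excluded %d undefined matrices of %d",
            len(ms) - len(kept),
            len(ms),
        )
    if not kept:
        raise ValueError("all matrices undefined; nothing to average")
    values = np.mean([m.values for m in kept], axis=0)
    observed = np.any([m.observed_rows for m in kept], axis=0)
    return TransitionMatrix(alphabet, values, mode, observed, undefined=False)


def flatten(m: TransitionMatrix) -> np.ndarray:
    """Row-major flattening to a length ``|alphabet|**2`` vector.

    The order is fixed by the catalogue's declared label order so vectors
    are elementwise comparable across subjects and conditions.
    """
    return m.values.reshape(-1).copy()


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - u.v / (||u|| ||v||)``; in [0, 1] for nonnegative vectors.

    Scale-invariant: multiplying either vector by a positive constant does
    not change the distance.  A zero-norm vector has no direction, so the
    distance is undefined and raises.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    d = 1.0 - float(np.dot(u, v) / (nu * nv))
    # Clip the negative-side rounding error for identical directions.
    return max(d, 0.0)


@dataclass(frozen=True)
class DivergenceResult:
    """Cosine distance of one subject's condition matrix from the baseline."""

    subject_id: str
    condition: str
    baseline: str
    distance: float


def baseline_divergence(
    per_condition: Mapping[str, TransitionMatrix],
    baseline: str = "Fed",
    subject_id: str = "subject",
) -> list[DivergenceResult]:
    """One cosine distance per non-baseline condition for one subject.

    Conditions whose matrix is undefined (fewer than two bouts) are skipped
    with a logged warning; an undefined baseline makes every comparison
    undefined and returns an empty list.
    """
    if baseline not in per_condition:
        raise ValueError(f"baseline condition {baseline!r} missing from input")
    base = per_condition[baseline]
    if base.undefined:
        logger.warning(
            "subject %s: baseline %s matrix undefined; divergences skipped",
            subject_id,
            baseline,
        )
        return []
    base_vec = flatten(base)
    results = []
    for condition, m in per_condition.items():
        if condition == baseline:
            continue
        if m.alphabet != base.alphabet or m.mode != base.mode:
            raise ValueError("matrices must share alphabet and mode")
        if m.undefined:
            logger.warning(
                "subject %s: condition %s matrix undefined; excluded",
                subject_id,
                condition,
            )
            continue
        results.append(
            DivergenceResult(
                subject_id=subject_id,
                condition=condition,
                baseline=baseline,
                distance=cosine_distance(base_vec, flatten(m)),
            )
        )
    return results


# -- matrix I/O --------------------------------------------------------------

def write_matrix_tsv(m: TransitionMatrix, path) -> None:
    """Write a labeled TSV (rows = source behavior, columns = destination)."""
    m.to_frame().to_csv(path, sep="\t", index_label="from")


def read_matrix_tsv(path, mode: str = "conditional") -> TransitionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    observed = values.sum(axis=1) > 0
    return TransitionMatrix(
        alphabet=tuple(df.columns),
        values=values,
        mode=mode,
        observed_rows=observed,
        undefined=not observed.any(),
    )
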