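"""Duration summaries, pairwise duration regressions, inter-rater agreement.

Covers the paradigm's between-behavior trade-off analyses (e.g. total
mating duration against food intake across subjects, fit by ordinary least
squares with a Pearson correlation and its t-transform p-value) and the
scorer-versus-scorer confusion matrix with percent coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalogue import NONE_LABEL
from .ethogram import Ethogram, segment_bouts


def behavior_durations(e: Ethogram) -> pd.DataFrame:
    """Total seconds and bout count per catalogue behavior.

    Seconds are per-second label occurrence counts; bout counts come from
    :func:`~ethoseq.ethogram.segment_bouts`.  Behaviors never expressed get
    zero rows, so tables align across subjects.
    """
    bouts = segment_bouts(e)
    rows = []
    for label in e.catalogue.labels:
        rows.append(
            {
                "behavior": label,
                "seconds": e.seconds_of(label),
                "bouts": sum(1 for b in bouts if b.label == label),
            }
        )
    return pd.DataFrame(rows)


def duration_table(ethograms) -> pd.DataFrame:
    """Long-format duration table over subjects x conditions x behaviors."""
    frames = []
    for e in ethograms:
        df = behavior_durations(e)
        df.insert(0, "subject_id", e.subject_id)
        df.insert(1, "condition", e.condition)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def duration_regression(x, y) -> RegressionResult:
    """OLS line with Pearson r and two-sided p from the t transform of r.

    Requires at least three paired points and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression p-value")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(x.size),
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Second-by-second cross-tabulation of two scorers' labels.

    Axes cover the catalogue alphabet plus NONE; ``counts.loc[a, b]`` is the
    number of seconds scorer 1 labeled ``a`` while scorer 2 labeled ``b``.
    """

    counts: pd.DataFrame

    @property
    def total_seconds(self) -> int:
        return int(self.counts.to_numpy().sum())


def interrater_confusion(a: Ethogram, b: Ethogram) -> ConfusionMatrix:
    """Cross-tabulate two scorings of the same trial, including NONE."""
    if a.duration_s != b.duration_s:
        raise ValueError("ethograms must have equal duration")
    if a.catalogue.labels != b.catalogue.labels:
        raise ValueError("ethograms must share a catalogue")
    axis = list(a.catalogue.labels) + [NONE_LABEL]
    ct = pd.crosstab(
        pd.Categorical(a.labels, categories=axis),
        pd.Categorical(b.labels, categories=axis),
        dropna=False,
    )
    ct.index = pd.Index(axis, name="scorer_1")
    ct.columns = pd.Index(axis, name="scorer_2")
    return ConfusionMatrix(counts=ct)


def coherence(c: ConfusionMatrix, include_none: bool = False) -> float:
    """Percent of seconds with identical labels (diagonal mass x 100).

    ``include_none=False`` (default) drops seconds both scorers left
    unscored from numerator and denominator: agreeing that nothing scorable
    happened would otherwise inflate agreement.
    """
    counts = c.counts.to_numpy(dtype=float)
    diag = float(np.trace(counts))
    total = float(counts.sum())
    if not include_none:
        none_none = float(c.counts.loc[NONE_LABEL, NONE_LABEL])
        diag -= none_none
        total -= none_none
    if total == 0:
        raise ValueError("no scored seconds; coherence undefined")
    return 100.0 * diag / total


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni-adjusted p-values (clipped at 1) and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(p * p.size, 1.0)
    return adj, adj < alpha
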