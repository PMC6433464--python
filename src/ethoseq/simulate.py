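"""Semi-Markov generator of synthetic behavioral barcodes and pellet logs.

No raw scored barcodes are publicly deposited for this paradigm, so testing
and parameter-recovery experiments run on synthetic data with the structure
the sequence analysis assumes: behavior follows a bout-level Markov chain
(the quantity the transition analysis estimates), bout and gap durations
are geometric (the discrete memoryless family, the minimal choice), and
pellet retrievals are a thinned point process inside eating bouts.

The generator is semi-Markov rather than per-second Markov because the
analysis is bout-based and observed same-behavior "self-transitions" only
exist as two bouts separated by an unscored (NONE) gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalogue import CONDITIONS, BehaviorCatalogue, NONE_LABEL, catalogue_preset
from .ethogram import Bout, Ethogram, TrialContext
from .feeding import PelletEvent, PelletLog
from .transitions import (
    TransitionMatrix,
    cosine_distance,
    count_transitions,
    flatten,
    normalize_transitions,
)

SCENARIOS = ("female_intruder", "male_intruder", "no_intruder")

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimKernel:
    """Generative parameters for one appetite condition x context.

    Parameters
    ----------
    alphabet
        Behavior labels; axis order of ``P``.
    P
        Row-stochastic bout-to-bout transition matrix.
    bout_mean_s
        Per-behavior mean bout duration, geometric on {1, 2, ...} seconds.
    gap_mean_s
        Mean NONE-gap duration, geometric on {0, 1, ...} seconds.
    gap_prob
        Probability a transition is mediated by a NONE gap.  Must be 1
        whenever ``P`` has positive diagonal mass: a same-behavior
        transition is only observable across a gap.
    initial
        Distribution of the first behavior.
    """

    alphabet: tuple[str, ...]
    P: np.ndarray
    bout_mean_s: np.ndarray
    gap_mean_s: float = 3.0
    gap_prob: float = 1.0
    initial: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        P = np.asarray(self.P, dtype=float)
        if P.shape != (n, n) or (P < 0).any():
            raise ValueError("P must be a nonnegative square matrix over the alphabet")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("P rows must sum to 1 (tolerance 1e-9)")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ValueError("gap_prob must be in [0, 1]")
        if n > 1 and (np.diag(P) > 0).any() and self.gap_prob != 1.0:
            # With one behavior there is nothing to transition to, so the
            # observability constraint is moot and a gapless kernel is legal.
            raise ValueError(
                "self-transitions (diagonal mass in P) require gap_prob=1: "
                "two same-behavior bouts are only distinct across a NONE gap"
            )
        bm = np.asarray(self.bout_mean_s, dtype=float)
        if bm.shape != (n,) or (bm < 1).any():
            raise ValueError("bout_mean_s must be per-behavior means >= 1 s")
        if self.gap_mean_s < 0:
            raise ValueError("gap_mean_s must be >= 0")
        if self.initial is not None:
            init = np.asarray(self.initial, dtype=float)
            if init.shape != (n,) or (init < 0).any() or not np.isclose(init.sum(), 1.0):
                raise ValueError("initial must be a distribution over the alphabet")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "bout_mean_s", bm)

    @property
    def initial_dist(self) -> np.ndarray:
        if self.initial is not None:
            return np.asarray(self.initial, dtype=float)
        return np.full(len(self.alphabet), 1.0 / len(self.alphabet))

    def to_matrix(self, mode: str = "conditional") -> TransitionMatrix:
        """The true kernel as a TransitionMatrix (every row observed)."""
        return TransitionMatrix(
            alphabet=self.alphabet,
            values=self.P.copy(),
            mode=mode,
            observed_rows=np.ones(len(self.alphabet), dtype=bool),
        )

    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet),
            "P": self.P.tolist(),
            "bout_mean_s": self.bout_mean_s.tolist(),
            "gap_mean_s": float(self.gap_mean_s),
            "gap_prob": float(self.gap_prob),
            "initial": None if self.initial is None else list(map(float, self.initial)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimKernel":
        return cls(
            alphabet=tuple(d["alphabet"]),
            P=np.asarray(d["P"], dtype=float),
            bout_mean_s=np.asarray(d["bout_mean_s"], dtype=float),
            gap_mean_s=float(d.get("gap_mean_s", 3.0)),
            gap_prob=float(d.get("gap_prob", 1.0)),
            initial=None if d.get("initial") is None else np.asarray(d["initial"]),
        )


def simulate_label_sequence(
    k: SimKernel, n_bouts: int, seed: RngLike
) -> list[str]:
    """Draw the bout-label Markov chain only (no durations)."""
    if n_bouts < 0:
        raise ValueError("n_bouts must be nonnegative")
    rng = _as_rng(seed)
    n = len(k.alphabet)
    if n_bouts == 0:
        return []
    states = np.empty(n_bouts, dtype=np.int64)
    states[0] = rng.choice(n, p=k.initial_dist)
    for i in range(1, n_bouts):
        states[i] = rng.choice(n, p=k.P[states[i - 1]])
    return [k.alphabet[s] for s in states]


def _draw_bout_duration(k: SimKernel, state: int, rng: np.random.Generator) -> int:
    return int(rng.geometric(1.0 / k.bout_mean_s[state]))


def _draw_gap(k: SimKernel, same_label: bool, rng: np.random.Generator) -> int:
    if k.gap_prob > 0 and rng.random() < k.gap_prob:
        gap = int(rng.geometric(1.0 / (1.0 + k.gap_mean_s))) - 1
    else:
        gap = 0
    if same_label and len(k.alphabet) > 1:
        # Adjacent same-label bouts would merge into one; force a 1 s gap so
        # every drawn self-transition stays observable.
        gap = max(gap, 1)
    return gap


def simulate_bouts(
    k: SimKernel, duration_s: int, seed: RngLike
) -> list[Bout]:
    """Draw the full semi-Markov process, truncated at *duration_s*."""
    if duration_s < 1:
        raise ValueError("duration must be at least 1 s")
    rng = _as_rng(seed)
    bouts: list[Bout] = []
    state = int(rng.choice(len(k.alphabet), p=k.initial_dist))
    t = 0
    while t < duration_s:
        d = _draw_bout_duration(k, state, rng)
        end = min(t + d, duration_s)
        if bouts and bouts[-1].end_s == t and bouts[-1].label == k.alphabet[state]:
            # Gapless same-label continuation (single-state kernels only):
            # one longer bout, not two.
            bouts[-1] = Bout(bouts[-1].start_s, end, bouts[-1].label)
        else:
            bouts.append(Bout(t, end, k.alphabet[state]))
        t = end
        if t >= duration_s:
            break
        nxt = int(rng.choice(len(k.alphabet), p=k.P[state]))
        t += _draw_gap(k, nxt == state, rng)
        state = nxt
    return bouts


def simulate_ethogram(
    k: SimKernel,
    duration_s: int = 1200,
    seed: RngLike = 0,
    **metadata,
) -> Ethogram:
    """Simulate one per-second barcode.  Identical seed, identical output."""
    bouts = simulate_bouts(k, duration_s, seed)
    labels = [NONE_LABEL] * duration_s
    for b in bouts:
        for sec in range(b.start_s, b.end_s):
            labels[sec] = b.label
    catalogue = metadata.pop("catalogue", None)
    if catalogue is None:
        catalogue = BehaviorCatalogue(
            labels=k.alphabet,
            roles={l: "individual" for l in k.alphabet},
            colors={l: "gray" for l in k.alphabet},
        )
    return Ethogram(labels=tuple(labels), catalogue=catalogue, **metadata)


def simulate_pellet_log(
    e: Ethogram,
    pellets_per_eating_second: float,
    seed: RngLike,
    eating_label: str = "eating",
    pellet_mass_g: float = 0.02,
) -> PelletLog:
    """Couple pellet retrievals to eating bouts.

    Each eating-labeled second independently yields a pellet with
    probability *pellets_per_eating_second* (a Bernoulli thinning; rate 1
    keeps every eating second).  Event times fall inside their second; all
    events are confirmed and attributed to the ethogram's subject.
    """
    if not 0.0 <= pellets_per_eating_second <= 1.0:
        raise ValueError("pellet rate must be in [0, 1]")
    rng = _as_rng(seed)
    events = []
    for sec, label in enumerate(e.labels):
        if label == eating_label and rng.random() < pellets_per_eating_second:
            events.append(
                PelletEvent(
                    time_s=sec + float(rng.random()),
                    consumer_id=e.subject_id,
                    confirmed=True,
                )
            )
    return PelletLog(events=tuple(events), pellet_mass_g=pellet_mass_g)


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------

#: Hunger intensity per appetite condition, on [0, 1].  Zero is sated;
#: fasting and AgRP photostimulation escalate it.  Concurrent stimulation
#: (CS) is strongest; pre-stimulation (PS) leaves a moderate residual drive.
HUNGER_LEVEL = {
    "Fed": 0.0,
    "Fasted18": 0.35,
    "Fasted48": 0.70,
    "FedAgRP_CS": 0.85,
    "FedAgRP_PS": 0.45,
}

#: Baseline attraction weight and mean bout duration (s) per behavior slot.
_BASE_WEIGHT = {
    "interactive_primary": 0.20,   # mounting / attack / receptivity ...
    "interactive_secondary": 0.20, # pursuit / chasing / escape ...
    "anogenital_investigation": 0.15,
    "nose_to_nose": 0.15,
    "drinking": 0.06,
    "grooming": 0.12,
    "eating": 0.06,
}
_BASE_BOUT_MEAN = {
    "interactive_primary": 5.0,
    "interactive_secondary": 3.0,
    "anogenital_investigation": 4.0,
    "nose_to_nose": 3.0,
    "drinking": 3.0,
    "grooming": 8.0,
    "eating": 4.0,
}

_SCENARIO_CATALOGUE = {
    "female_intruder": "resident_vs_female",
    "male_intruder": "resident_vs_male",
}

#: Per eating-labeled second, probability a pellet is retrieved.  At the
#: sated baseline this yields on the order of five pellets per 20 min trial.
PELLET_RATE = 0.06


def _slot(label: str, catalogue: BehaviorCatalogue) -> str:
    if label in _BASE_WEIGHT:
        return label
    interactive = [l for l in catalogue.labels if catalogue.roles[l] == "interactive"]
    return "interactive_primary" if interactive.index(label) == 0 else "interactive_secondary"


def _make_kernel(
    catalogue: BehaviorCatalogue,
    hunger: float,
    food_present: bool,
    gap_mean_s: float = 3.0,
) -> SimKernel:
    labels = catalogue.labels
    slots = [_slot(l, catalogue) for l in labels]
    weights = np.array([_BASE_WEIGHT[s] for s in slots], dtype=float)
    bout_means = np.array([_BASE_BOUT_MEAN[s] for s in slots], dtype=float)
    for i, label in enumerate(labels):
        if label == "eating":
            # Caloric need escalates the pull toward food and lengthens
            # feeding bouts.
            weights[i] = 0.06 + 0.9 * hunger
            bout_means[i] = 4.0 + 12.0 * hunger
        elif catalogue.roles[label] == "interactive":
            # Hunger crowds out social drive when food competes for
            # expression; without food the social repertoire barely shifts.
            weights[i] *= (1.0 - 0.75 * hunger) if food_present else (1.0 - 0.10 * hunger)
    # Row i: shared attraction weights with a self-transition boost, strong
    # for eating (feeding recurs in runs of bouts), mild otherwise.
    n = len(labels)
    P = np.tile(weights, (n, 1))
    for i, label in enumerate(labels):
        P[i, i] *= (1.0 + 3.0 * hunger) if label == "eating" else 0.5
    P /= P.sum(axis=1, keepdims=True)
    return SimKernel(
        alphabet=labels,
        P=P,
        bout_mean_s=bout_means,
        gap_mean_s=gap_mean_s,
        gap_prob=1.0,
    )


@dataclass(frozen=True)
class ConditionPresetBank:
    """One generative kernel plus pellet-coupling rate per appetite condition."""

    scenario: str
    food_present: bool
    catalogue: BehaviorCatalogue
    kernels: dict[str, SimKernel] = field(repr=False)
    pellet_rate: dict[str, float] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "food_present": self.food_present,
            "kernels": {c: k.to_dict() for c, k in self.kernels.items()},
            "pellet_rate": dict(self.pellet_rate),
        }


def make_condition_presets(
    scenario: str, food_present: bool = True
) -> ConditionPresetBank:
    """Build the five appetite-condition kernels for one scenario.

    Scenarios: ``female_intruder`` and ``male_intruder`` use the matching
    seven-behavior resident catalogue; ``no_intruder`` keeps only the
    individual behaviors (eating, drinking, grooming).  Food-absent banks
    drop ``eating``, leaving the remaining six behaviors.

    By construction, eating self-transition mass and eating bout duration
    increase Fed -> Fasted18 -> Fasted48 while interactive mass decreases.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "no_intruder":
        full = catalogue_preset("resident_vs_female")
        interactive = [l for l in full.labels if full.roles[l] == "interactive"]
        catalogue = full.drop(interactive)
    else:
        catalogue = catalogue_preset(_SCENARIO_CATALOGUE[scenario])
    if not food_present:
        if scenario == "no_intruder":
            raise ValueError("no_intruder scenario requires food (nothing to score otherwise)")
        catalogue = catalogue.drop(["eating"])

    # Without an intruder the scored repertoire is only the three individual
    # behaviors; long unscored stretches (locomotion, rest) keep the sated
    # baseline near the ~5-pellet homeostatic level.
    gap_mean_s = 12.0 if scenario == "no_intruder" else 3.0
    kernels = {
        cond: _make_kernel(catalogue, HUNGER_LEVEL[cond], food_present, gap_mean_s)
        for cond in CONDITIONS
        if cond in HUNGER_LEVEL
    }
    rates = {cond: (PELLET_RATE if food_present else 0.0) for cond in kernels}

    if food_present and "eating" in catalogue.labels:
        i = catalogue.index("eating")
        for lo, hi in (("Fed", "Fasted18"), ("Fasted18", "Fasted48")):
            assert kernels[lo].P[i, i] < kernels[hi].P[i, i]
            assert kernels[lo].bout_mean_s[i] < kernels[hi].bout_mean_s[i]
    return ConditionPresetBank(
        scenario=scenario,
        food_present=food_present,
        catalogue=catalogue,
        kernels=kernels,
        pellet_rate=rates,
    )


def simulate_cohort(
    scenario: str,
    n_subjects: int = 16,
    duration_s: int = 1200,
    seed: int = 0,
    food_present: bool = True,
    conditions: Optional[Sequence[str]] = None,
) -> dict[tuple[str, str], tuple[Ethogram, PelletLog]]:
    """Simulate a within-subject cohort: every subject in every condition.

    One master seed spawns an independent stream per subject x condition, so
    cohorts are reproducible subject-by-subject.  Returns
    ``(subject_id, condition) -> (Ethogram, PelletLog)``.
    """
    bank = make_condition_presets(scenario, food_present)
    conds = list(conditions) if conditions is not None else list(bank.kernels)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_subjects * len(conds))
    intruder = {"female_intruder": "female", "male_intruder": "male", "no_intruder": None}
    out: dict[tuple[str, str], tuple[Ethogram, PelletLog]] = {}
    for si in range(n_subjects):
        subject = f"sub{si:02d}"
        for ci, cond in enumerate(conds):
            ss = streams[si * len(conds) + ci]
            rng_etho, rng_fed = (np.random.default_rng(s) for s in ss.spawn(2))
            e = simulate_ethogram(
                bank.kernels[cond],
                duration_s=duration_s,
                seed=rng_etho,
                catalogue=bank.catalogue,
                subject_id=subject,
                condition=cond,
                context=TrialContext(
                    food_present=food_present, intruder=intruder[scenario]
                ),
                phase="trial",
            )
            log = simulate_pellet_log(e, bank.pellet_rate[cond], rng_fed)
            out[(subject, cond)] = (e, log)
    return out


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def l1_error(estimate: TransitionMatrix, truth: np.ndarray) -> float:
    """Mean absolute elementwise error over the estimate's observed rows.

    Rows never visited in the sample carry no information about the kernel
    and are excluded rather than scored as all-zero estimates.
    """
    obs = estimate.observed_rows
    if not obs.any():
        raise ValueError("no observed rows; error undefined")
    return float(np.abs(estimate.values[obs] - np.asarray(truth)[obs]).mean())


def recovery_experiment(
    k: SimKernel, lengths: Sequence[int], seed: RngLike
) -> pd.DataFrame:
    """Estimate the kernel from simulated sequences of increasing length.

    For each length (number of bouts): simulate the label chain, count and
    row-normalize transitions, and report the mean absolute elementwise
    error and the cosine distance between the flattened estimate and the
    flattened true kernel.
    """
    if list(lengths) != sorted(lengths):
        raise ValueError("lengths must be increasing")
    rng = _as_rng(seed)
    rows = []
    for n_bouts in lengths:
        seq = simulate_label_sequence(k, n_bouts, rng)
        est = normalize_transitions(count_transitions(seq, k.alphabet), "conditional")
        rows.append(
            {
                "length": int(n_bouts),
                "l1_error": l1_error(est, k.P),
                "cosine_distance": cosine_distance(flatten(est), k.P.reshape(-1)),
            }
        )
    return pd.DataFrame(rows)
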