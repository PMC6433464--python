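"""Behavior catalogues and appetite-condition registry.

A catalogue is the ordered alphabet of scorable behaviors for one animal
role in the resident-intruder paradigm.  Its declared order is load-bearing:
it fixes the axis order of every transition matrix and the layout of every
flattened transition vector, so matrices from different subjects are
comparable elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: Reserved token for an unscored second.  Never a catalogue label and never
#: a transition state; it only separates bouts.
NONE_LABEL = "NONE"

VALID_ROLES = ("interactive", "individual")

#: Registry of appetite conditions: a sated baseline, two fasting durations,
#: and two artificial (AgRP-neuron photostimulation) hunger states --
#: concurrent stimulation (CS) and pre-stimulation (PS).
CONDITIONS: list[str] = ["Fed", "Fasted18", "Fasted48", "FedAgRP_CS", "FedAgRP_PS"]


def register_condition(name: str) -> None:
    """Add an appetite condition to the registry (idempotent)."""
    if name not in CONDITIONS:
        CONDITIONS.append(name)


def validate_condition(name: str) -> str:
    if name not in CONDITIONS:
        raise ValueError(
            f"unknown appetite condition {name!r}; registered: {CONDITIONS}"
        )
    return name


@dataclass(frozen=True)
class BehaviorCatalogue:
    """Ordered alphabet of behaviors with per-label role and display color.

    Parameters
    ----------
    labels
        Unique behavior names; order defines matrix axis order.
    roles
        ``label -> "interactive" | "individual"``.
    colors
        ``label -> matplotlib color`` (name or hex), used for rasters.
    """

    labels: tuple[str, ...]
    roles: Mapping[str, str] = field(repr=False)
    colors: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("catalogue must contain at least one label")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValueError(f"duplicate labels in catalogue: {dupes}")
        if NONE_LABEL in self.labels:
            raise ValueError(f"{NONE_LABEL!r} is reserved and cannot be a label")
        for label in self.labels:
            role = self.roles.get(label)
            if role not in VALID_ROLES:
                raise ValueError(f"label {label!r} has invalid role {role!r}")
            if label not in self.colors:
                raise ValueError(f"label {label!r} has no display color")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def drop(self, labels: Iterable[str]) -> "BehaviorCatalogue":
        """Return a catalogue without *labels* (e.g. no ``eating`` when no
        food is present), preserving the declared order of the rest."""
        drop = set(labels)
        missing = drop - set(self.labels)
        if missing:
            raise ValueError(f"cannot drop labels not in catalogue: {sorted(missing)}")
        kept = tuple(l for l in self.labels if l not in drop)
        return BehaviorCatalogue(
            labels=kept,
            roles={l: self.roles[l] for l in kept},
            colors={l: self.colors[l] for l in kept},
        )


def build_catalogue(role_spec: Mapping[str, tuple[str, str]]) -> BehaviorCatalogue:
    """Build a catalogue from ``label -> (role, color)``.

    The mapping's iteration order becomes the catalogue order.

    Raises
    ------
    ValueError
        On an empty spec, a duplicate label, or an unknown role.
    """
    if not role_spec:
        raise ValueError("role_spec is empty")
    labels = tuple(role_spec)
    roles = {l: rc[0] for l, rc in role_spec.items()}
    colors = {l: rc[1] for l, rc in role_spec.items()}
    return BehaviorCatalogue(labels=labels, roles=roles, colors=colors)


# The four scored-role presets of the resident-intruder paradigm.  Each has
# seven behaviors: four interactive (role-specific) and three individual
# (drinking, grooming, eating), with the conventional raster colors.
_COMMON_INDIVIDUAL = {
    "drinking": ("individual", "blue"),
    "grooming": ("individual", "purple"),
    "eating": ("individual", "black"),
}

_PRESETS: dict[str, dict[str, tuple[str, str]]] = {
    # Male resident confronted with a receptive female intruder.
    "resident_vs_female": {
        "mount_intromission": ("interactive", "red"),
        "pursuit_attempted_mount": ("interactive", "gold"),
        "anogenital_investigation": ("interactive", "orange"),
        "nose_to_nose": ("interactive", "green"),
        **_COMMON_INDIVIDUAL,
    },
    # Female intruder in a male resident's territory.
    "female_intruder": {
        "receptivity": ("interactive", "red"),
        "non_receptivity": ("interactive", "gold"),
        "anogenital_investigation": ("interactive", "orange"),
        "nose_to_nose": ("interactive", "green"),
        **_COMMON_INDIVIDUAL,
    },
    # Male resident confronted with a subordinate male intruder.
    "resident_vs_male": {
        "attack": ("interactive", "red"),
        "chasing": ("interactive", "gold"),
        "anogenital_investigation": ("interactive", "orange"),
        "nose_to_nose": ("interactive", "green"),
        **_COMMON_INDIVIDUAL,
    },
    # Male intruder in a dominant resident's territory.
    "male_intruder": {
        "defensive_posture": ("interactive", "red"),
        "flight": ("interactive", "gold"),
        "anogenital_investigation": ("interactive", "orange"),
        "nose_to_nose": ("interactive", "green"),
        **_COMMON_INDIVIDUAL,
    },
}


def catalogue_preset(name: str) -> BehaviorCatalogue:
    """Return one of the built-in seven-behavior catalogues.

    Presets: ``resident_vs_female``, ``female_intruder``,
    ``resident_vs_male``, ``male_intruder``.
    """
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown catalogue preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return build_catalogue(spec)
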