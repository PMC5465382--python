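"""Instrument definitions and scoring rules for the four mood questionnaires.

The package analyses four self-assessment instruments commonly used in
longitudinal mood monitoring of bipolar disorder (BD), borderline personality
disorder (BPD) and healthy controls (HC):

``MZ``
    Mood Zoom: 6 mood adjectives (anxious, elated, sad, angry, irritable,
    energetic), each rated 1-7.  MZ is a pure vector instrument: it defines
    no total score and no clinical bands.
``ASRM``
    Altman Self-Rating Mania scale: 5 items rated 0-4, total 0-20, with a
    published manic-episode cut-off of 5.5.
``QIDS``
    Quick Inventory of Depressive Symptomatology (self-report, 16 items
    rated 0-3).  The 16 items collapse onto 9 DSM-IV symptom domains; each
    domain is the maximum over its item subset (most domains are single
    items) and the total is the sum of the 9 domain scores, 0-27.
``GAD7``
    Generalized Anxiety Disorder 7-item scale: 7 items rated 0-3, total
    0-21, with severity cut-offs at 5, 10 and 15.

A :class:`QuestionnaireSpec` is a frozen description of one instrument.  The
four shipped defaults are available through :func:`get_spec` /
:data:`DEFAULT_SPECS`; alternative definitions (e.g. a different QIDS
domain grouping) can be loaded from a YAML file with
:meth:`QuestionnaireSpec.from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .exceptions import (
    IncompleteResponseError,
    UnsupportedOperationError,
    ValidationError,
)

__all__ = [
    "QuestionnaireSpec",
    "DEFAULT_SPECS",
    "get_spec",
    "total_score",
    "qids_domain_scores",
    "clinical_band",
]


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Immutable definition of a self-assessment instrument.

    Parameters
    ----------
    name : str
        Instrument identifier (``MZ``, ``ASRM``, ``QIDS``, ``GAD7`` or a
        user-defined label).
    items : tuple of str
        Ordered, unique item identifiers.
    scale_min, scale_max : int
        Inclusive per-item response bounds (``scale_min < scale_max``).
    domain_map : tuple of (str, tuple of str), optional
        Ordered domain definitions.  When present, the total score is the
        sum over domains of the maximum item response within each domain.
        Used by QIDS (9 domains over 16 items).
    bands : tuple of (int, str), optional
        Clinical severity bands as ``(upper_threshold_inclusive, label)``
        pairs with strictly increasing thresholds; a total ``t`` maps to the
        first band with ``t <= threshold``.
    """

    name: str
    items: tuple[str, ...]
    scale_min: int
    scale_max: int
    domain_map: tuple[tuple[str, tuple[str, ...]], ...] | None = None
    bands: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValidationError(
                f"{self.name}: scale_min ({self.scale_min}) must be < "
                f"scale_max ({self.scale_max})"
            )
        if not self.items:
            raise ValidationError(f"{self.name}: items must be non-empty")
        if len(set(self.items)) != len(self.items):
            raise ValidationError(f"{self.name}: items must be unique")
        if self.domain_map is not None:
            covered = {i for _, subset in self.domain_map for i in subset}
            missing = set(self.items) - covered
            if missing:
                raise ValidationError(
                    f"{self.name}: items {sorted(missing)} appear in no domain"
                )
            unknown = covered - set(self.items)
            if unknown:
                raise ValidationError(
                    f"{self.name}: domain_map references unknown items "
                    f"{sorted(unknown)}"
                )
        thresholds = [t for t, _ in self.bands]
        if thresholds != sorted(set(thresholds)):
            raise ValidationError(
                f"{self.name}: band thresholds must be strictly increasing"
            )

    # -- derived properties -------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        """Largest attainable total score."""
        if self.domain_map is not None:
            return len(self.domain_map) * self.scale_max
        return len(self.items) * self.scale_max

    @property
    def min_total(self) -> int:
        if self.domain_map is not None:
            return len(self.domain_map) * self.scale_min
        return len(self.items) * self.scale_min

    @property
    def matrix_columns(self) -> tuple[str, ...]:
        """Column names of the analysis matrix: domain names when a domain
        map is defined (QIDS), raw item names otherwise."""
        if self.domain_map is not None:
            return tuple(name for name, _ in self.domain_map)
        return self.items

    # -- validation helpers -------------------------------------------------

    def validate_response(self, response: Mapping[str, int]) -> None:
        """Check a response is complete and in range; raise otherwise."""
        missing = [i for i in self.items if i not in response]
        if missing:
            raise IncompleteResponseError(
                f"{self.name}: response missing items {missing}"
            )
        for item in self.items:
            value = response[item]
            if value != int(value) or not (
                self.scale_min <= value <= self.scale_max
            ):
                raise ValidationError(
                    f"{self.name}: item {item!r} value {value!r} outside "
                    f"[{self.scale_min}, {self.scale_max}]"
                )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "items": list(self.items),
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
        }
        if self.domain_map is not None:
            d["domain_map"] = [
                {"domain": name, "items": list(subset)}
                for name, subset in self.domain_map
            ]
        if self.bands:
            d["bands"] = [
                {"threshold": t, "label": label} for t, label in self.bands
            ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuestionnaireSpec":
        domain_map = None
        if "domain_map" in d and d["domain_map"] is not None:
            domain_map = tuple(
                (entry["domain"], tuple(entry["items"]))
                for entry in d["domain_map"]
            )
        bands = tuple(
            (entry["threshold"], entry["label"]) for entry in d.get("bands", [])
        )
        return cls(
            name=d["name"],
            items=tuple(d["items"]),
            scale_min=int(d["scale_min"]),
            scale_max=int(d["scale_max"]),
            domain_map=domain_map,
            bands=bands,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "QuestionnaireSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------

MZ_SPEC = QuestionnaireSpec(
    name="MZ",
    items=("anxious", "elated", "sad", "angry", "irritable", "energetic"),
    scale_min=1,
    scale_max=7,
)

ASRM_SPEC = QuestionnaireSpec(
    name="ASRM",
    items=("happy", "confident", "sleepy", "talkative", "active"),
    scale_min=0,
    scale_max=4,
    bands=((5, "below cut-off"), (20, "above manic-episode cut-off")),
)

# Standard QIDS-SR16 domain grouping: sleep is the max over the four sleep
# items, appetite/weight the max over the four appetite/weight items (only
# one of decreased/increased can apply per administration), psychomotor the
# max over slowing and restlessness; the remaining seven domains are single
# items.  The grouping is configuration, not code: alternative groupings can
# be supplied via a custom spec.
QIDS_SPEC = QuestionnaireSpec(
    name="QIDS",
    items=(
        "falling_asleep",       # 1
        "sleep_during_night",   # 2
        "waking_early",         # 3
        "sleeping_too_much",    # 4
        "sad",                  # 5
        "appetite_decrease",    # 6
        "appetite_increase",    # 7
        "weight_decrease",      # 8
        "weight_increase",      # 9
        "concentration",        # 10
        "self_view",            # 11
        "suicide",              # 12
        "interest",             # 13
        "energy",               # 14
        "slowed_down",          # 15
        "restless",             # 16
    ),
    scale_min=0,
    scale_max=3,
    domain_map=(
        ("sleep", ("falling_asleep", "sleep_during_night", "waking_early",
                   "sleeping_too_much")),
        ("sad", ("sad",)),
        ("appetite_weight", ("appetite_decrease", "appetite_increase",
                             "weight_decrease", "weight_increase")),
        ("concentration", ("concentration",)),
        ("self_view", ("self_view",)),
        ("suicide", ("suicide",)),
        ("interest", ("interest",)),
        ("energy", ("energy",)),
        ("psychomotor", ("slowed_down", "restless")),
    ),
    bands=(
        (5, "normal"),
        (10, "mild"),
        (15, "moderate"),
        (20, "severe"),
        (27, "very severe"),
    ),
)

GAD7_SPEC = QuestionnaireSpec(
    name="GAD7",
    items=("nervous", "control_worries", "worried", "relaxed", "restless",
           "irritable", "afraid"),
    scale_min=0,
    scale_max=3,
    bands=((4, "minimal"), (9, "mild"), (14, "moderate"), (21, "severe")),
)

DEFAULT_SPECS: dict[str, QuestionnaireSpec] = {
    s.name: s for s in (MZ_SPEC, ASRM_SPEC, QIDS_SPEC, GAD7_SPEC)
}


def get_spec(name: str) -> QuestionnaireSpec:
    """Return the shipped default spec for an instrument name."""
    try:
        return DEFAULT_SPECS[name]
    except KeyError:
        raise ValidationError(
            f"unknown instrument {name!r}; known: {sorted(DEFAULT_SPECS)}"
        ) from None


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def qids_domain_scores(
    response: Mapping[str, int], spec: QuestionnaireSpec | None = None
) -> tuple[int, ...]:
    """Collapse a complete 16-item QIDS response onto its 9 symptom domains.

    Each domain score is the maximum response over the domain's item subset
    (singleton domains pass the item through unchanged).

    Returns the 9 domain scores in the spec's domain order, each in
    ``[scale_min, scale_max]``.
    """
    spec = spec if spec is not None else QIDS_SPEC
    if spec.domain_map is None:
        raise UnsupportedOperationError(
            f"{spec.name} defines no domain map"
        )
    spec.validate_response(response)
    return tuple(
        max(int(response[item]) for item in subset)
        for _, subset in spec.domain_map
    )


def total_score(spec: QuestionnaireSpec, response: Mapping[str, int]) -> int:
    """Total score of a complete response under the instrument's rule.

    ASRM and GAD-7 totals are plain item sums; the QIDS total is the sum of
    the 9 domain scores (max-mapping).  MZ defines no total and raises
    :class:`UnsupportedOperationError`.
    """
    if spec.name == "MZ":
        raise UnsupportedOperationError(
            "MZ is a vector instrument and defines no total score"
        )
    spec.validate_response(response)
    if spec.domain_map is not None:
        return int(sum(qids_domain_scores(response, spec)))
    return int(sum(int(response[item]) for item in spec.items))


def clinical_band(spec: QuestionnaireSpec, total: int) -> str:
    """Map a total score onto the instrument's clinical severity band."""
    if not spec.bands:
        raise UnsupportedOperationError(
            f"{spec.name} defines no clinical bands"
        )
    if not (spec.min_total <= total <= spec.max_total):
        raise ValidationError(
            f"{spec.name}: total {total} outside "
            f"[{spec.min_total}, {spec.max_total}]"
        )
    for threshold, label in spec.bands:
        if total <= threshold:
            return label
    # Unreachable if the last threshold equals max_total (validated ranges).
    raise ValidationError(
        f"{spec.name}: total {total} exceeds the last band threshold"
    )
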