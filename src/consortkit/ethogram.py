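"""Behavior catalog (ethogram) used to interpret focal event logs.

An ethogram assigns every recordable behavior a code, a category, a
recording mode (instantaneous *event* vs durational *state*) and the set of
modifiers it may carry.  Two derived subsets drive the downstream duration
accounting: ``consort_behavior_codes`` (behaviors whose presence counts a
pair as "in consort", entering the pair-consort-duration union) and
``ibc_codes`` (the intensive-body-contact subset: full-surface, mutually
maintained contact such as huddling and embracing — grooming and contact
sitting are deliberately excluded because the contact they involve is
partial or passively maintained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import yaml

CATEGORIES = frozenset(
    {
        "mount",
        "intensive_body_contact",
        "contact_sitting",
        "grooming",
        "other_affiliative",
        "proximity",
        "separation",
    }
)
MODES = frozenset({"event", "state"})

#: modifier recording whether a mount involved rubbing/grinding/thrusting
PELVIC_MOVEMENT = "pelvic_movement"


class EthogramError(ValueError):
    """Raised when an ethogram document fails validation."""


@dataclass(frozen=True)
class BehaviorDef:
    """One behavior in the catalog."""

    code: str
    label: str
    category: str
    mode: str
    modifiers: frozenset[str] = frozenset()
    directional: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise EthogramError(
                f"behavior {self.code!r}: unknown category {self.category!r}"
            )
        if self.mode not in MODES:
            raise EthogramError(f"behavior {self.code!r}: unknown mode {self.mode!r}")
        if PELVIC_MOVEMENT in self.modifiers and self.category != "mount":
            raise EthogramError(
                f"behavior {self.code!r}: {PELVIC_MOVEMENT} modifier is only "
                "meaningful on mount behaviors"
            )


@dataclass(frozen=True)
class EthogramCatalog:
    """A validated behavior catalog.

    Parameters
    ----------
    behaviors
        Behavior definitions; codes must be unique.
    consort_behavior_codes
        Codes whose occurrence counts the pair as being in consort.
    ibc_codes
        Intensive-body-contact subset; must be contained in the consort set.
    proximity_radius_m
        Radius (meters) of the observer-recorded spatial-proximity state.
        The default of 3 m is the conventional individual-tolerance distance
        for Japanese macaques.
    """

    behaviors: tuple[BehaviorDef, ...]
    consort_behavior_codes: frozenset[str]
    ibc_codes: frozenset[str]
    proximity_radius_m: float = 3.0

    def __post_init__(self) -> None:
        codes = [b.code for b in self.behaviors]
        seen: set[str] = set()
        for c in codes:
            if c in seen:
                raise EthogramError(f"duplicate behavior code {c!r}")
            seen.add(c)
        unknown = (self.consort_behavior_codes | self.ibc_codes) - seen
        if unknown:
            raise EthogramError(f"codes referenced but not defined: {sorted(unknown)}")
        missing = self.ibc_codes - self.consort_behavior_codes
        if missing:
            raise EthogramError(
                f"ibc codes missing from consort set: {sorted(missing)}"
            )
        if self.proximity_radius_m <= 0:
            raise EthogramError("proximity_radius_m must be positive")
        extra_ibc = {
            c
            for c in self.ibc_codes
            if self.by_code(c).category != "intensive_body_contact"
        }
        if extra_ibc:
            warnings.warn(
                "ibc_codes include behaviors outside the intensive_body_contact "
                f"category ({sorted(extra_ibc)}); this departs from the standard "
                "definition (full-surface contact only: huddling, embracing)",
                stacklevel=2,
            )

    def by_code(self, code: str) -> BehaviorDef:
        for b in self.behaviors:
            if b.code == code:
                return b
        raise KeyError(code)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(b.code for b in self.behaviors)

    def is_state(self, code: str) -> bool:
        return self.by_code(code).mode == "state"

    @property
    def mount_codes(self) -> frozenset[str]:
        return frozenset(b.code for b in self.behaviors if b.category == "mount")

    @property
    def grooming_codes(self) -> frozenset[str]:
        return frozenset(b.code for b in self.behaviors if b.category == "grooming")

    @property
    def separation_codes(self) -> frozenset[str]:
        return frozenset(b.code for b in self.behaviors if b.category == "separation")


_DEFAULT_BEHAVIORS = (
    BehaviorDef("mount", "sexual mount (any posture)", "mount", "event",
                frozenset({PELVIC_MOVEMENT}), directional=True),
    BehaviorDef("embrace", "ventral embrace", "intensive_body_contact", "state"),
    BehaviorDef("huddle", "full-surface huddle", "intensive_body_contact", "state"),
    BehaviorDef("contact_sit", "sitting in body contact", "contact_sitting", "state"),
    BehaviorDef("groom", "social grooming", "grooming", "state", directional=True),
    BehaviorDef("cofeed", "feeding together", "other_affiliative", "state"),
    BehaviorDef("travel_together", "coordinated travel", "other_affiliative", "state"),
    BehaviorDef("mutual_follow", "mutual following", "other_affiliative", "state"),
    BehaviorDef("proximity_3m", "within 3 m spatial proximity", "proximity", "state"),
    BehaviorDef("separation", "pair separates beyond proximity radius",
                "separation", "event"),
)

_DEFAULT_CONSORT = frozenset(
    {"mount", "embrace", "contact_sit", "huddle", "groom", "cofeed",
     "travel_together", "mutual_follow", "proximity_3m"}
)
_DEFAULT_IBC = frozenset({"huddle", "embrace"})


def default_catalog() -> EthogramCatalog:
    """The built-in catalog covering the behaviors of a macaque consort.

    Mounting is an instantaneous directional event carrying an optional
    pelvic-movement modifier; contact behaviors, grooming, cofeeding,
    travel and the 3 m proximity state are durational; huddling and
    embracing form the intensive-body-contact subset.
    """
    return EthogramCatalog(
        behaviors=_DEFAULT_BEHAVIORS,
        consort_behavior_codes=_DEFAULT_CONSORT,
        ibc_codes=_DEFAULT_IBC,
    )


def _catalog_to_dict(catalog: EthogramCatalog) -> dict:
    return {
        "behaviors": [
            {
                "code": b.code,
                "label": b.label,
                "category": b.category,
                "mode": b.mode,
                "modifiers": sorted(b.modifiers),
                "directional": b.directional,
            }
            for b in catalog.behaviors
        ],
        "consort_behavior_codes": sorted(catalog.consort_behavior_codes),
        "ibc_codes": sorted(catalog.ibc_codes),
        "proximity_radius_m": catalog.proximity_radius_m,
    }


def load_ethogram(source) -> EthogramCatalog:
    """Load and validate a catalog from a YAML/JSON document.

    ``source`` may be a mapping, a path, or an open text stream.  The
    special string ``"default"`` (or ``None``) returns the built-in catalog.
    """
    if source is None or source == "default":
        return default_catalog()
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "behaviors" not in doc:
        raise EthogramError("ethogram document must be a mapping with 'behaviors'")
    behaviors = tuple(
        BehaviorDef(
            code=str(b["code"]),
            label=str(b.get("label", b["code"])),
            category=str(b["category"]),
            mode=str(b["mode"]),
            modifiers=frozenset(b.get("modifiers", ())),
            directional=bool(b.get("directional", False)),
        )
        for b in doc["behaviors"]
    )
    return EthogramCatalog(
        behaviors=behaviors,
        consort_behavior_codes=frozenset(doc.get("consort_behavior_codes", ())),
        ibc_codes=frozenset(doc.get("ibc_codes", ())),
        proximity_radius_m=float(doc.get("proximity_radius_m", 3.0)),
    )


def write_ethogram(catalog: EthogramCatalog, path) -> None:
    """Serialize a catalog to YAML such that :func:`load_ethogram` round-trips.

    ``path`` may be a filesystem path or an open text stream.
    """
    if hasattr(path, "write"):
        yaml.safe_dump(_catalog_to_dict(catalog), path, sort_keys=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_catalog_to_dict(catalog), fh, sort_keys=False)
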