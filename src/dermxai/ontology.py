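"""The explanatory ontology of melanoma and nevus criteria.

Dermatologists using pattern analysis describe a lesion through a fixed
catalogue of dermoscopic characteristics. The catalogue used here contains
10 melanoma criteria and 8 nevus criteria; some apply only at particular
body sites (acral, facial) or after excision, and one nevus criterion —
the *melanoma simulator* — marks benign lesions that visually mimic
melanoma. The ordering of the catalogue is fixed and defines the axis of
every multi-hot label vector and attention-map stack in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable


class DiagnosisClass(str, Enum):
    """Class a criterion argues for."""

    MELANOMA = "melanoma"
    NEVUS = "nevus"


#: applicability flags — informational only, never enforced against metadata
APPLICABILITY_FLAGS = frozenset({"acral_only", "facial_only", "post_excision_only"})


@dataclass(frozen=True)
class Criterion:
    """One dermoscopic characteristic of the explanatory catalogue.

    Parameters
    ----------
    id :
        Stable snake-case key, used in label tables and mask filenames.
    display_text :
        Human-readable wording shown in textual explanations.
    class_association :
        Whether the criterion argues for melanoma or for nevus.
    applicability :
        Site/context restrictions (informational flags).
    is_simulator :
        True only for the "melanoma simulator" nevus criterion.
    """

    id: str
    display_text: str
    class_association: DiagnosisClass
    applicability: frozenset = frozenset()
    is_simulator: bool = False

    def __post_init__(self):
        if not isinstance(self.class_association, DiagnosisClass):
            object.__setattr__(
                self, "class_association", DiagnosisClass(self.class_association)
            )
        bad = set(self.applicability) - APPLICABILITY_FLAGS
        if bad:
            raise ValueError(f"unknown applicability flags: {sorted(bad)}")


class UnknownCriterionError(KeyError):
    """Lookup of a criterion id that is not in the ontology."""


@dataclass
class Ontology:
    """Ordered, immutable-by-convention catalogue of criteria.

    The order of ``criteria`` is the canonical class axis: melanoma block
    first, then the nevus block, top-to-bottom as in the catalogue.
    """

    criteria: list[Criterion] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("criterion ids must be unique")
        n_sim = sum(c.is_simulator for c in self.criteria)
        if n_sim > 1:
            raise ValueError("at most one criterion may be the melanoma simulator")
        self._index = {c.id: i for i, c in enumerate(self.criteria)}

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.criteria)

    def __iter__(self):
        return iter(self.criteria)

    def __contains__(self, cid: str) -> bool:
        return cid in self._index

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.criteria]

    def index_of(self, cid: str) -> int:
        """Position of a criterion on the label axis."""
        try:
            return self._index[cid]
        except KeyError:
            raise UnknownCriterionError(cid) from None

    def get(self, cid: str) -> Criterion:
        return self.criteria[self.index_of(cid)]

    def ids_of_class(self, klass: DiagnosisClass | str) -> list[str]:
        klass = DiagnosisClass(klass)
        return [c.id for c in self.criteria if c.class_association is klass]

    # -- JSON round trip ----------------------------------------------
    def to_json(self) -> str:
        payload = [
            {
                "id": c.id,
                "display_text": c.display_text,
                "class_association": c.class_association.value,
                "applicability": sorted(c.applicability),
                "is_simulator": c.is_simulator,
            }
            for c in self.criteria
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Ontology":
        payload = json.loads(text)
        return cls(
            [
                Criterion(
                    id=d["id"],
                    display_text=d["display_text"],
                    class_association=DiagnosisClass(d["class_association"]),
                    applicability=frozenset(d.get("applicability", [])),
                    is_simulator=d.get("is_simulator", False),
                )
                for d in payload
            ]
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Ontology":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------
# the default catalogue
# ---------------------------------------------------------------------

_MELANOMA_CRITERIA = [
    ("thick_reticular_lines", "Thick reticular or branched lines", frozenset()),
    (
        "eccentric_structureless_area",
        "Eccentrically located structureless area "
        "(any colour except skin colour, white and grey)",
        frozenset(),
    ),
    ("grey_patterns", "Grey patterns", frozenset()),
    ("polymorphous_vessels", "Polymorphous vessels", frozenset()),
    (
        "radial_lines_partial",
        "Pseudopods or radial lines at the lesion margin that do not occupy "
        "the entire lesional circumference",
        frozenset(),
    ),
    (
        "peripheral_black_dots",
        "Black dots or globules in the periphery of the lesion",
        frozenset(),
    ),
    ("white_lines", "White lines or white structureless area", frozenset()),
    (
        "parallel_ridges",
        "Parallel lines on ridges (acral lesions only)",
        frozenset({"acral_only"}),
    ),
    (
        "pigmentation_beyond_scar",
        "Pigmentation extends beyond the area of the scar (only after excision)",
        frozenset({"post_excision_only"}),
    ),
    (
        "follicle_pigmentation",
        "Pigmentation invades the openings of hair follicles (facial lesions)",
        frozenset({"facial_only"}),
    ),
]

_NEVUS_CRITERIA = [
    ("one_pattern_one_colour", "Only one pattern and only one colour", frozenset()),
    (
        "symmetric_patterns",
        "Symmetrical combination of patterns and/or colours",
        frozenset(),
    ),
    ("monomorphic_vessels", "Monomorphic vascular pattern", frozenset()),
    (
        "radial_lines_circumferential",
        "Pseudopods or radial lines at the lesional margin involving the "
        "entire lesional circumference",
        frozenset(),
    ),
    (
        "parallel_furrows",
        "Parallel lines in the furrows (acral lesions only)",
        frozenset({"acral_only"}),
    ),
    (
        "pigmentation_within_scar",
        "Pigmentation does not extend beyond the area of the scar "
        "(only after excision)",
        frozenset({"post_excision_only"}),
    ),
    (
        "asymmetric_patterns_benign",
        "Asymmetric combination of multiple patterns and/or colours in the "
        "absence of other melanoma criteria",
        frozenset(),
    ),
    ("melanoma_simulator", "Melanoma simulator", frozenset()),
]


def default_ontology() -> Ontology:
    """Build the fixed 18-criterion catalogue (10 melanoma + 8 nevus).

    Idempotent; the returned ordering (melanoma block first) is stable
    across calls and releases.
    """
    crits = [
        Criterion(cid, text, DiagnosisClass.MELANOMA, flags)
        for cid, text, flags in _MELANOMA_CRITERIA
    ]
    crits += [
        Criterion(cid, text, DiagnosisClass.NEVUS, flags, is_simulator=(cid == "melanoma_simulator"))
        for cid, text, flags in _NEVUS_CRITERIA
    ]
    return Ontology(crits)


def criterion_class(ontology: Ontology, cid: str) -> DiagnosisClass:
    """Class association (melanoma/nevus) of a criterion id."""
    return ontology.get(cid).class_association


# ---------------------------------------------------------------------
# findings and text rendering
# ---------------------------------------------------------------------


@dataclass
class Findings:
    """Criteria reported in an explanation, split by evidence level."""

    strong: set = field(default_factory=set)
    some: set = field(default_factory=set)

    def validate(self, ontology: Ontology) -> None:
        overlap = self.strong & self.some
        if overlap:
            raise ValueError(f"criteria in both evidence levels: {sorted(overlap)}")
        for cid in self.strong | self.some:
            if cid not in ontology:
                raise UnknownCriterionError(cid)

    def all_ids(self) -> set:
        return self.strong | self.some


class EmptyFindingsError(ValueError):
    """Nothing to render — assembly must supply a fallback finding first."""


def render_textual_explanation(findings: Findings, ontology: Ontology) -> str:
    """Render the textual explanation for a set of findings.

    Strong-evidence criteria are listed under a "strong evidence" phrase and
    the remaining ones under a "some evidence" phrase, each using the
    catalogue's display wording exactly once. Criteria are listed in
    ontology order, so output is deterministic given the findings.
    """
    findings.validate(ontology)
    if not findings.strong and not findings.some:
        raise EmptyFindingsError("no findings to render")

    def _block(header: str, ids: set) -> str:
        ordered = [c.display_text for c in ontology if c.id in ids]
        bullets = "\n".join(f"  - {t}" for t in ordered)
        return f"{header}\n{bullets}"

    parts = []
    if findings.strong:
        parts.append(_block("The classifier found strong evidence of characteristic(s):", findings.strong))
    if findings.some:
        parts.append(_block("The classifier found some evidence of characteristic(s):", findings.some))
    return "\n".join(parts)


def slug_ids(ontology: Ontology, ids: Iterable[str]) -> list[str]:
    """Normalise an iterable of ids to ontology order (helper for reports)."""
    wanted = set(ids)
    return [cid for cid in ontology.ids if cid in wanted]
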