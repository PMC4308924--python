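"""Variant records, predictor transformations and conservation categories.

A variant is described at the protein level: its gene, the referring
syndrome, one of three coding-consequence classes (radical, inframe indel,
missense substitution) and, for missense variants, the standard scores
(Grantham, SIFT, PolyPhen/HumVar) plus a cross-species conservation
category.  This module owns the covariate encoding used by every model in
the network:

* control-database presence as a binary frequency indicator,
* SIFT flipped to ``1 - SIFT`` so that larger means more damaging,
* Grantham rescaled by 1/205 into [0, 1] (entered as linear + quadratic),
* PolyPhen entered as linear + quadratic,
* conservation simplified to three levels encoded as two indicators
  (conserved in primates, conserved in all species; not conserved is the
  reference state).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

SYNDROMES = ("LQTS", "BrS", "HCM")
VARIANT_CLASSES = ("radical", "inframe", "missense")
LABELS = ("pathogenic", "benign")

#: Five-level conservation categories, deepest (widest) clade first.
CONSERVATION_LEVELS = (
    "all_species",
    "vertebrates",
    "mammals",
    "primates",
    "not_conserved",
)

#: Three-level simplification used by the missense linear predictor.
CONSERVATION_SIMPLE = ("not_conserved", "conserved_primates", "conserved_all")

#: Default mapping from the five-level category to the three-level one.
#: Mammal- and vertebrate-level conservation both collapse onto the
#: primate indicator; only conservation across all species earns the
#: ``conserved_all`` indicator.
DEFAULT_SIMPLIFY_MAP = {
    "all_species": "conserved_all",
    "vertebrates": "conserved_primates",
    "mammals": "conserved_primates",
    "primates": "conserved_primates",
    "not_conserved": "not_conserved",
}

#: Nested clades, innermost first; each clade contains the previous one.
CLADES = ("primates", "mammals", "vertebrates", "all_70")

GRANTHAM_MAX = 205.0

CLASS_GROUPS = {"radical": "radical", "inframe": "non_radical", "missense": "non_radical"}


class AnnotationError(ValueError):
    """A variant record is missing or violates a required annotation."""


class MissingEvidenceError(AnnotationError):
    """Conservation evidence carries no informative species."""


@dataclass
class VariantRecord:
    """A single rare coding variant with its predictor annotations.

    Missense-only fields (``grantham``, ``sift``, ``polyphen``,
    ``conservation``) must be absent (``None``) for radical and inframe
    records.  ``label`` is only present for training variants; ``lod`` is
    an optional segregation log10 likelihood ratio.
    """

    variant_id: str
    gene: str
    syndrome: str
    variant_class: str
    domain: str | None = None
    grantham: int | None = None
    sift: float | None = None
    polyphen: float | None = None
    conservation: str | None = None
    in_control_db: int | None = None
    label: str | None = None
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.syndrome not in SYNDROMES:
            raise AnnotationError(
                f"{self.variant_id}: unknown syndrome {self.syndrome!r}; "
                f"expected one of {SYNDROMES}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise AnnotationError(
                f"{self.variant_id}: unknown variant_class {self.variant_class!r}; "
                f"expected one of {VARIANT_CLASSES}"
            )
        if self.label is not None and self.label not in LABELS:
            raise AnnotationError(
                f"{self.variant_id}: unknown label {self.label!r}; expected one of {LABELS}"
            )
        if self.variant_class != "missense":
            for fname in ("grantham", "sift", "polyphen", "conservation"):
                if getattr(self, fname) is not None:
                    raise AnnotationError(
                        f"{self.variant_id}: field {fname!r} is missense-only but "
                        f"variant_class is {self.variant_class!r}"
                    )
        if self.grantham is not None and self.grantham < 0:
            raise AnnotationError(f"{self.variant_id}: grantham must be non-negative")
        for fname in ("sift", "polyphen"):
            value = getattr(self, fname)
            if value is not None and not 0.0 <= value <= 1.0:
                raise AnnotationError(f"{self.variant_id}: {fname} must lie in [0, 1]")
        if self.conservation is not None and self.conservation not in CONSERVATION_SIMPLE:
            raise AnnotationError(
                f"{self.variant_id}: conservation {self.conservation!r} not in "
                f"{CONSERVATION_SIMPLE}"
            )
        if self.in_control_db is not None and self.in_control_db not in (0, 1):
            raise AnnotationError(f"{self.variant_id}: in_control_db must be 0 or 1")

    @property
    def class_group(self) -> str:
        """Burden-table class group: radical, or non_radical (missense + inframe)."""
        return CLASS_GROUPS[self.variant_class]

    @property
    def freq_indicator(self) -> int:
        """Binary control-database presence; missing treated as absent (0)."""
        return 0 if self.in_control_db is None else int(self.in_control_db)


@dataclass
class ConservationEvidence:
    """Per-species residue match flags grouped into nested clades.

    ``species`` maps a species name to a status in {``same_residue``,
    ``different_residue``, ``disregard``}; ``clade`` maps each species to
    the innermost clade it belongs to (one of :data:`CLADES`).  Clades are
    nested: a primate also counts for mammals, vertebrates and all_70.
    Alignment gaps and low-quality residues (X) arrive as ``disregard``
    and carry no evidence.
    """

    species: dict[str, str]
    clade: dict[str, str]

    def __post_init__(self) -> None:
        for sp, status in self.species.items():
            if status not in ("same_residue", "different_residue", "disregard"):
                raise AnnotationError(f"species {sp!r}: unknown status {status!r}")
            if self.clade.get(sp) not in CLADES:
                raise AnnotationError(f"species {sp!r}: unknown or missing clade")


def categorize_conservation(evidence: ConservationEvidence) -> str:
    """Assign the five-level conservation category for a residue.

    Returns the widest nested clade within which every informative
    (non-disregarded) species carries the same residue:
    ``all_species`` > ``vertebrates`` > ``mammals`` > ``primates``; if even
    the primate clade contains a differing residue the residue is
    ``not_conserved``.  A clade that would be claimed with zero informative
    species raises :class:`MissingEvidenceError`.
    """
    informative = {
        sp: status for sp, status in evidence.species.items() if status != "disregard"
    }
    if not informative:
        raise MissingEvidenceError("all species disregarded; no conservation evidence")

    level_by_clade = {
        "primates": "primates",
        "mammals": "mammals",
        "vertebrates": "vertebrates",
        "all_70": "all_species",
    }
    clade_rank = {c: i for i, c in enumerate(CLADES)}

    best: str | None = None
    for i, clade in enumerate(CLADES):
        members = [sp for sp in informative if clade_rank[evidence.clade[sp]] <= i]
        if any(informative[sp] == "different_residue" for sp in members):
            break
        if not members:
            # vacuous claim: conserved "within" a clade we have no data for
            break
        best = level_by_clade[clade]
    if best is None:
        first = [sp for sp in informative if evidence.clade[sp] == "primates"]
        if not first and all(s == "different_residue" for s in informative.values()):
            return "not_conserved"
        if not first:
            raise MissingEvidenceError(
                "no informative primate species; cannot claim any conservation level"
            )
        return "not_conserved"
    return best


def simplify_conservation(
    category: str, mapping: dict[str, str] | None = None
) -> tuple[int, int]:
    """Collapse a five-level category to the two binary indicators.

    Returns ``(cons_primates, cons_all)`` with not-conserved the reference
    state ``(0, 0)``.  The collapse map is configurable; the default sends
    primate/mammal/vertebrate conservation to the primate indicator and
    all-species conservation to the all-species indicator.
    """
    mapping = DEFAULT_SIMPLIFY_MAP if mapping is None else mapping
    if category not in mapping:
        raise AnnotationError(f"unknown conservation category {category!r}")
    simple = mapping[category]
    return {
        "not_conserved": (0, 0),
        "conserved_primates": (1, 0),
        "conserved_all": (0, 1),
    }[simple]


_SIMPLE_TO_INDICATORS = {
    "not_conserved": (0, 0),
    "conserved_primates": (1, 0),
    "conserved_all": (0, 1),
}


@dataclass
class DesignVector:
    """Encoded covariates feeding one class-specific linear predictor.

    All transformed scores lie in [0, 1]; quadratic fields are exact
    squares of their linear counterparts.  Radical vectors carry only the
    frequency indicator and the radical-class gene log-prior term; inframe
    vectors add the domain label; missense vectors carry everything.
    """

    variant_class: str
    gene: str
    syndrome: str
    freq_indicator: int
    log_prior_odds: float
    domain: str | None = None
    sift_t: float | None = None
    grantham_t: float | None = None
    grantham_t_sq: float | None = None
    polyphen: float | None = None
    polyphen_sq: float | None = None
    cons_primates: int | None = None
    cons_all: int | None = None


def _require(variant: VariantRecord, fname: str):
    value = getattr(variant, fname)
    if value is None:
        raise AnnotationError(
            f"{variant.variant_id}: missing required annotation {fname!r} "
            f"for a {variant.variant_class} variant"
        )
    return value


def build_design_vector(variant: VariantRecord, priors) -> DesignVector:
    """Encode a variant against a fitted :class:`~cardiobayes.priors.PriorOddsTable`.

    Raises :class:`AnnotationError` naming the missing field when a
    class-required annotation is absent, and KeyError (with guidance) when
    the gene/syndrome pair has no prior odds.
    """
    odds = priors.lookup(variant.gene, variant.syndrome, variant.class_group)
    log_odds = math.log(odds)
    common = dict(
        variant_class=variant.variant_class,
        gene=variant.gene,
        syndrome=variant.syndrome,
        freq_indicator=variant.freq_indicator,
        log_prior_odds=log_odds,
    )
    if variant.variant_class == "radical":
        return DesignVector(**common)
    if variant.variant_class == "inframe":
        return DesignVector(**common, domain=variant.domain)

    grantham = _require(variant, "grantham")
    sift = _require(variant, "sift")
    polyphen = _require(variant, "polyphen")
    conservation = _require(variant, "conservation")

    grantham_t = grantham / GRANTHAM_MAX
    if grantham_t > 1.0:
        warnings.warn(
            f"{variant.variant_id}: Grantham {grantham} exceeds {GRANTHAM_MAX:.0f}; "
            "clamping rescaled value to 1.0",
            stacklevel=2,
        )
        grantham_t = 1.0
    cons_primates, cons_all = _SIMPLE_TO_INDICATORS[conservation]
    return DesignVector(
        **common,
        domain=variant.domain,
        sift_t=1.0 - sift,
        grantham_t=grantham_t,
        grantham_t_sq=grantham_t**2,
        polyphen=polyphen,
        polyphen_sq=polyphen**2,
        cons_primates=cons_primates,
        cons_all=cons_all,
    )
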