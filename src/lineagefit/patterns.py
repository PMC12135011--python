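"""Degenerate barcode templates and genotype-class assignment.

Lineage barcodes are engineered with a handful of "constant" bases embedded
among random positions so that the genetic background a lineage came from
(wild type vs the ivermectin-resistant GluCl triple mutant) can be read
directly off the barcode sequence.  A template is written in the usual
degenerate-base notation: literal A/C/G/T at constant positions, ``N`` at
random positions.  An observed barcode belongs to a class when it has the
template's length and agrees with every literal slot; barcodes matching no
template are treated as sequencing/preparation errors and excluded rather
than error-corrected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "GenotypeClass",
    "DegeneratePattern",
    "parse_pattern",
    "classify_barcode",
    "MUTANT_PATTERN",
    "WILDTYPE_PATTERN",
    "WILDTYPE_PATTERN_PRINTED_14",
    "default_patterns",
]

_ALPHABET = frozenset("ACGTN")
_BASES = frozenset("ACGT")


class GenotypeClass(str, enum.Enum):
    """Genetic background of a barcoded lineage."""

    WILD_TYPE = "wild_type"
    MUTANT = "mutant"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PatternError(ValueError):
    """Raised for invalid degenerate-pattern strings."""


class AmbiguousClassificationError(RuntimeError):
    """Raised when a barcode matches two supposedly disjoint patterns."""


@dataclass(frozen=True)
class DegeneratePattern:
    """A constant-base/wildcard barcode template.

    Parameters
    ----------
    slots
        Ordered template symbols, each one of A/C/G/T (a constant base that
        must be present) or N (any base).
    label
        Genotype-class name this template identifies.
    """

    slots: tuple[str, ...]
    label: str
    literal_positions: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.slots) < 1:
            raise PatternError("pattern must have at least one slot")
        for i, sym in enumerate(self.slots):
            if sym not in _ALPHABET:
                raise PatternError(
                    f"invalid symbol {sym!r} at position {i + 1} "
                    "(allowed: A, C, G, T, N)"
                )
        literals = tuple(i for i, sym in enumerate(self.slots) if sym in _BASES)
        if not literals:
            raise PatternError(
                "pattern has no literal slot and cannot discriminate classes"
            )
        object.__setattr__(self, "literal_positions", literals)

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def text(self) -> str:
        return "".join(self.slots)

    def matches(self, barcode: str) -> bool:
        """True iff ``barcode`` has this length and agrees at every literal slot.

        Matching is case-insensitive; any non-ACGT character in the barcode
        makes the result False (such reads are rejected upstream).
        """
        bc = barcode.upper()
        if len(bc) != len(self.slots):
            return False
        if not _BASES.issuperset(bc):
            return False
        return all(bc[i] == self.slots[i] for i in self.literal_positions)


def parse_pattern(text: str, label: str) -> DegeneratePattern:
    """Parse a degenerate template string such as ``"NANNNTNTNNCNNNN"``.

    Raises :class:`PatternError` naming the offending position for characters
    outside {A, C, G, T, N} (IUPAC ambiguity codes beyond N are deliberately
    not supported), and for templates with no literal slot.
    """
    if not text:
        raise PatternError("empty pattern")
    return DegeneratePattern(slots=tuple(text.upper()), label=label)


#: Mutant (GluCl triple knockout) barcode template: constant bases
#: A2, T6, T8, C11 (1-based).
MUTANT_PATTERN = parse_pattern("NANNNTNTNNCNNNN", GenotypeClass.MUTANT.value)

#: Wild-type barcode template, 15-slot form: constant bases C4, T7, T9, A11.
#: Disjoint from the mutant template at position 11 (A vs C), so no barcode
#: can match both.
WILDTYPE_PATTERN = parse_pattern("NNNCNNTNTNANNNN", GenotypeClass.WILD_TYPE.value)

#: The 14-symbol form of the wild-type template as sometimes written; the
#: known wild-type exemplar barcodes are 15 bases and match the 15-slot form
#: above, which is therefore the default.
WILDTYPE_PATTERN_PRINTED_14 = parse_pattern(
    "NNNCNNTNTNANNN", GenotypeClass.WILD_TYPE.value
)


def default_patterns() -> list[DegeneratePattern]:
    """The two default class templates (wild type 15-slot form, mutant)."""
    return [WILDTYPE_PATTERN, MUTANT_PATTERN]


def classify_barcode(
    barcode: str, patterns: list[DegeneratePattern] | None = None
) -> GenotypeClass:
    """Assign a barcode to the unique matching template's class.

    Returns :attr:`GenotypeClass.UNCLASSIFIED` when no template matches.
    Raises :class:`AmbiguousClassificationError` when more than one matches:
    templates are required to be pairwise disjoint, and a tie means the
    supplied templates violate that, which must not be silently broken.
    """
    if patterns is None:
        patterns = default_patterns()
    hits = [p for p in patterns if p.matches(barcode)]
    if len(hits) > 1:
        raise AmbiguousClassificationError(
            f"barcode {barcode!r} matches multiple patterns: "
            + ", ".join(p.label for p in hits)
        )
    if not hits:
        return GenotypeClass.UNCLASSIFIED
    return GenotypeClass(hits[0].label)
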