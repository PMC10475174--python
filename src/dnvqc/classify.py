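"""Variant classification from REF/ALT alleles.

Classes are a pure function of allele lengths (VCF-anchored alleles):
equal length 1 -> SNV, equal length > 1 -> MNV, REF longer -> deletion,
ALT longer -> insertion.  Transitions are the purine<->purine (A<->G) and
pyrimidine<->pyrimidine (C<->T) substitutions; the other eight ordered
single-base changes are transversions.
"""

from __future__ import annotations

from enum import Enum

from .errors import ContractError, ValidationError
from .io_dnv import VALID_BASES, DNVTable


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    MNV = "MNV"


_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


def _check_allele(allele: str, label: str) -> None:
    if not allele or not set(allele) <= VALID_BASES:
        raise ValidationError(f"invalid {label} allele {allele!r}")


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a (ref, alt) pair as SNV, insertion, deletion, or MNV."""
    _check_allele(ref, "ref")
    _check_allele(alt, "alt")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref!r}); not a variant")
    if len(ref) == len(alt):
        return VariantClass.SNV if len(ref) == 1 else VariantClass.MNV
    return VariantClass.DELETION if len(ref) > len(alt) else VariantClass.INSERTION


def is_transition(ref: str, alt: str) -> bool:
    """True iff the single-base change ref->alt is a transition."""
    _check_allele(ref, "ref")
    _check_allele(alt, "alt")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValidationError(f"not a single-base change: {ref!r}->{alt!r}")
    return frozenset((ref, alt)) in _TRANSITION_PAIRS


def indel_length(ref: str, alt: str) -> int:
    """Net number of inserted/deleted bases, |len(ref) - len(alt)|.

    The shared anchor base is excluded, so a 1-bp insertion has length 1.
    """
    cls = classify_variant(ref, alt)
    if cls not in (VariantClass.INSERTION, VariantClass.DELETION):
        raise ContractError(f"indel_length called on {cls.value} ({ref!r}->{alt!r})")
    return abs(len(ref) - len(alt))


def mnv_length(ref: str, alt: str) -> int:
    """Length of a multi-nucleotide variant (== len(ref) == len(alt))."""
    cls = classify_variant(ref, alt)
    if cls is not VariantClass.MNV:
        raise ContractError(f"mnv_length called on {cls.value} ({ref!r}->{alt!r})")
    return len(ref)


def non_anchored_indel_count(table: DNVTable) -> int:
    """Diagnostic: number of indel rows whose REF and ALT do not share a
    first base.  Non-zero values suggest a callset in a non-VCF-anchored
    (or non-left-normalized) representation, where the pure length rule
    used here may misread complex substitutions."""
    n = 0
    for r in table:
        cls = classify_variant(r.ref, r.alt)
        if cls in (VariantClass.INSERTION, VariantClass.DELETION) and r.ref[0] != r.alt[0]:
            n += 1
    return n
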