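"""Subsetting DNV tables by individual, variant class, and chromosome group.

Every operation here is a pure, order-preserving, idempotent filter:
the output records are a subsequence of the input and each table notes the
applied filter in its provenance.
"""

from __future__ import annotations

import warnings
from typing import Iterable

from .classify import VariantClass, classify_variant
from .errors import ContractError, DNVWarning
from .io_dnv import DNVTable

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: accepted values for class-based extraction; "INDEL" covers both
#: insertions and deletions, mirroring the usual callset vocabulary
CLASS_GROUPS: dict[str, frozenset[VariantClass]] = {
    "SNV": frozenset({VariantClass.SNV}),
    "INDEL": frozenset({VariantClass.INSERTION, VariantClass.DELETION}),
    "INSERTION": frozenset({VariantClass.INSERTION}),
    "DELETION": frozenset({VariantClass.DELETION}),
    "MNV": frozenset({VariantClass.MNV}),
}


def extract_individuals(table: DNVTable, ids: str | Iterable[str]) -> DNVTable:
    """Records belonging to one or more sample ids, order preserved.

    Ids absent from the table are reported in a warning; an empty id set is
    a contract error.
    """
    if isinstance(ids, str):
        ids = [ids]
    wanted = set(ids)
    if not wanted:
        raise ContractError("extract_individuals requires at least one sample id")
    present = {r.sample_id for r in table}
    missing = sorted(wanted - present)
    if missing:
        warnings.warn(
            f"sample id(s) not present in table: {', '.join(missing)}",
            DNVWarning,
            stacklevel=2,
        )
    out = tuple(r for r in table if r.sample_id in wanted)
    return DNVTable(out, table.provenance).with_provenance(
        f"individuals={','.join(sorted(wanted))}"
    )


def extract_by_class(table: DNVTable, cls: str | VariantClass) -> DNVTable:
    """Records of a given variant class: "SNV", "INDEL" (insertions plus
    deletions), "MNV", or a single :class:`VariantClass`."""
    key = cls.value if isinstance(cls, VariantClass) else str(cls).upper()
    if key not in CLASS_GROUPS:
        raise ContractError(
            f"unknown variant class {cls!r}; expected one of {sorted(CLASS_GROUPS)}"
        )
    group = CLASS_GROUPS[key]
    out = tuple(r for r in table if classify_variant(r.ref, r.alt) in group)
    return DNVTable(out, table.provenance).with_provenance(f"class={key}")


def extract_autosomes(table: DNVTable) -> DNVTable:
    """Records on chromosomes 1-22; sex, mitochondrial, and unplaced/alt
    contigs are all excluded."""
    out = tuple(r for r in table if r.chrom in AUTOSOMES)
    return DNVTable(out, table.provenance).with_provenance("region=autosomes")


def extract_sex_chromosome(table: DNVTable, which: str) -> DNVTable:
    """Records on chromosome X or Y (case-insensitive, chr-prefix agnostic)."""
    target = str(which).upper()
    if target not in ("X", "Y"):
        raise ContractError(f"which must be 'X' or 'Y', got {which!r}")
    out = tuple(r for r in table if r.chrom == target)
    return DNVTable(out, table.provenance).with_provenance(f"region={target}")


def chromosome_partition(table: DNVTable) -> dict[str, int]:
    """Counts of records on autosomes, X, Y, and everything else.

    The four groups always sum to ``len(table)``; "other" collects
    mitochondrial, unplaced, alt, and decoy contigs.
    """
    counts = {"autosomes": 0, "X": 0, "Y": 0, "other": 0}
    for r in table:
        if r.chrom in AUTOSOMES:
            counts["autosomes"] += 1
        elif r.chrom in ("X", "Y"):
            counts[r.chrom] += 1
        else:
            counts["other"] += 1
    return counts
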