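"""CpG-site maps and CpG annotation of SNVs.

A CpG site is either base of a "CG" dinucleotide on the reference forward
strand; methylated CpG cytosines are hypermutable, so the fraction of de
novo SNVs at CpG is a standard quality/biology signal.  Maps are built
directly from a reference FASTA and exchanged as BED3 (0-based half-open);
both the C and the G position of each dinucleotide are recorded, a choice
isolated in ``_cpg_positions`` so it can be flipped by one constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from pyfaidx import Fasta

from .errors import ContractError, DNVWarning, ParseError
from .io_dnv import DNVTable, normalize_chrom
from .subset import extract_by_class

#: offsets (relative to the C of each CG) recorded as CpG sites;
#: (0, 1) = both bases, (0,) would record only the C position
_CPG_OFFSETS = (0, 1)


@dataclass
class CpGMap:
    """Per-chromosome sorted, unique 1-based positions lying on a CpG."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)
    genome_label: str = ""

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CpGMap):
            return NotImplemented
        if set(self.positions) != set(other.positions):
            return False
        return all(
            np.array_equal(self.positions[c], other.positions[c])
            for c in self.positions
        )

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self.positions.get(normalize_chrom(chrom))
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        return bool(i < len(arr) and arr[i] == pos)


@dataclass
class CpGAnnotationSummary:
    n_snvs: int
    n_at_cpg: int
    percent_at_cpg: float | None  # 100 * n_at_cpg / n_snvs; None when no SNVs


def _cpg_positions(seq: str) -> np.ndarray:
    """Sorted unique 1-based CpG positions in one sequence.

    The scan is case-insensitive; characters outside A/C/G/T (e.g. N)
    never participate in a CG pair.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    c_idx = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    if len(c_idx) == 0:
        return np.empty(0, dtype=np.int64)
    pos = np.concatenate([c_idx + 1 + off for off in _CPG_OFFSETS])
    return np.unique(pos.astype(np.int64))


def build_cpg_map_from_seqs(
    seqs: Mapping[str, str], genome_label: str = ""
) -> CpGMap:
    """Build a :class:`CpGMap` from in-memory chromosome sequences."""
    positions = {
        normalize_chrom(name): _cpg_positions(seq) for name, seq in seqs.items()
    }
    return CpGMap(positions, genome_label)


def build_cpg_map(fasta_path: str | Path, genome_label: str | None = None) -> CpGMap:
    """Scan a reference FASTA for CpG dinucleotides and return the map."""
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise OSError(f"FASTA not found: {fasta_path}")
    fa = Fasta(str(fasta_path), rebuild=True, build_index=True)
    names = list(fa.keys())
    if not names:
        raise OSError(f"empty FASTA: {fasta_path}")
    label = genome_label if genome_label is not None else fasta_path.stem
    return build_cpg_map_from_seqs(
        {name: str(fa[name][:]) for name in names}, label
    )


# ---------------------------------------------------------------------------
# BED3 serialization (replaces a binary per-genome distribution format)


def write_cpg_bed(cpg_map: CpGMap, path: str | Path) -> None:
    """Write the map as BED3, one line per CpG position (chrom, pos-1, pos),
    sorted by chromosome then start."""

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    with open(path, "w") as fh:
        for chrom in sorted(cpg_map.positions, key=chrom_key):
            for pos in cpg_map.positions[chrom]:
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")


def read_cpg_bed(path: str | Path, genome_label: str = "") -> CpGMap:
    """Read a CpG map from BED3.  Intervals wider than one base (merged
    runs) are accepted and expanded to per-base positions."""
    path = Path(path)
    per_chrom: dict[str, list[np.ndarray]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"expected at least 3 BED columns: {line!r}", lineno)
            chrom = normalize_chrom(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"non-integer BED coordinates: {line!r}", lineno)
            if start < 0 or end <= start:
                raise ParseError(f"invalid BED interval [{start}, {end})", lineno)
            per_chrom.setdefault(chrom, []).append(
                np.arange(start + 1, end + 1, dtype=np.int64)
            )
    positions = {
        chrom: np.unique(np.concatenate(chunks))
        for chrom, chunks in per_chrom.items()
    }
    return CpGMap(positions, genome_label)


# ---------------------------------------------------------------------------
# annotation


def annotate_cpg(
    table: DNVTable, cpg_map: CpGMap
) -> tuple[DNVTable, CpGAnnotationSummary]:
    """Annotate the SNVs of ``table`` for CpG overlap.

    Returns a table containing only SNVs, each with ``at_cpg`` set to
    whether its position falls on either base of a reference CpG, plus a
    summary (SNV count, count at CpG, percent at CpG).  Chromosomes absent
    from the map draw a warning and annotate as False.
    """
    if cpg_map.n_sites == 0:
        raise ContractError("annotate_cpg requires a non-empty CpG map")
    snvs = extract_by_class(table, "SNV")
    missing_chroms: set[str] = set()
    annotated = []
    n_at_cpg = 0
    for r in snvs:
        if r.chrom not in cpg_map.positions:
            missing_chroms.add(r.chrom)
            hit = False
        else:
            hit = cpg_map.contains(r.chrom, r.pos)
        n_at_cpg += hit
        annotated.append(replace(r, at_cpg=hit))
    for chrom in sorted(missing_chroms):
        warnings.warn(
            f"chromosome {chrom!r} absent from CpG map; its SNVs annotated "
            "at_cpg=FALSE",
            DNVWarning,
            stacklevel=2,
        )
    n_snvs = len(annotated)
    if n_snvs == 0:
        warnings.warn("no SNVs to annotate", DNVWarning, stacklevel=2)
        percent = None
    else:
        percent = 100.0 * n_at_cpg / n_snvs
    out = DNVTable(tuple(annotated), table.provenance).with_provenance(
        f"cpg_annotated({cpg_map.genome_label or 'map'})"
    )
    return out, CpGAnnotationSummary(n_snvs, n_at_cpg, percent)
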