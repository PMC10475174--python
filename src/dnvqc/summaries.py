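"""Callset summary statistics: SNV change spectrum and Ti/Tv ratio,
deletion/insertion ratio, indel and MNV length spectra, and per-individual
DNV counts.

The Ti/Tv ratio (transitions / transversions) sits near 2 for genuine
genome-wide human variation and is a standard callset-quality signal, as is
the deletion/insertion ratio for indels.  Ratios are stored at full
precision; display rounding to one decimal is left to formatting.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import VariantClass, indel_length, is_transition, mnv_length
from .errors import ContractError, DNVWarning
from .io_dnv import DNVTable
from .subset import extract_by_class

#: the 12 ordered single-base changes, in a fixed display order
SNV_CHANGES = tuple(
    f"{a}>{b}" for a, b in itertools.permutations("ACGT", 2)
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TiTvResult:
    n_transitions: int
    n_transversions: int
    ratio: float | None
    #: counts of each ordered ref>alt change (barplot data, all 12 keys)
    change_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_snvs(self) -> int:
        return self.n_transitions + self.n_transversions


@dataclass
class IndelRatioResult:
    n_deletions: int
    n_insertions: int
    ratio: float | None


@dataclass
class LengthSpectrum:
    cls: VariantClass
    #: length (bp) -> count, keys in ascending order (barplot data)
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class IndividualCounts:
    per_sample: dict[str, int]
    mean: float
    sd: float
    #: kernel-density curve over the counts (x grid, density values)
    density: tuple[list[float], list[float]] | None = None


def titv(table: DNVTable) -> TiTvResult:
    """Transition/transversion summary over the SNVs in ``table``.

    Non-SNV records are excluded internally, so the table may mix classes.
    With zero transversions the ratio is undefined (None) and a warning is
    raised rather than dividing by zero.
    """
    snvs = extract_by_class(table, "SNV")
    changes = {c: 0 for c in SNV_CHANGES}
    n_ti = 0
    for r in snvs:
        changes[f"{r.ref}>{r.alt}"] += 1
        if is_transition(r.ref, r.alt):
            n_ti += 1
    n_tv = len(snvs) - n_ti
    if n_tv == 0:
        warnings.warn(
            "no transversions: Ti/Tv ratio undefined", DNVWarning, stacklevel=2
        )
        ratio = None
    else:
        ratio = n_ti / n_tv
    return TiTvResult(n_ti, n_tv, ratio, changes)


def collapse_change_spectrum(change_counts: dict[str, int]) -> dict[str, int]:
    """Strand-collapsed 6-type view of the change spectrum.

    Each change is folded onto its pyrimidine-reference representative
    (e.g. A>G is counted as T>C), the convention of mutational-signature
    displays.
    """
    out = {c: 0 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")}
    for change, n in change_counts.items():
        ref, alt = change.split(">")
        if ref in ("A", "G"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        out[f"{ref}>{alt}"] += n
    return out


def deletion_insertion_ratio(table: DNVTable) -> IndelRatioResult:
    """Deletion/insertion summary over the indels in ``table``."""
    indels = extract_by_class(table, "INDEL")
    n_del = sum(1 for r in indels if len(r.ref) > len(r.alt))
    n_ins = len(indels) - n_del
    if n_ins == 0:
        warnings.warn(
            "no insertions: deletion/insertion ratio undefined",
            DNVWarning,
            stacklevel=2,
        )
        ratio = None
    else:
        ratio = n_del / n_ins
    return IndelRatioResult(n_del, n_ins, ratio)


def length_spectrum(table: DNVTable, cls: str | VariantClass) -> LengthSpectrum:
    """Histogram of variant lengths for one class (insertion, deletion,
    or MNV), ordered by ascending length.  Empty spectra are allowed."""
    key = cls.value if isinstance(cls, VariantClass) else str(cls).upper()
    if key not in ("INSERTION", "DELETION", "MNV"):
        raise ContractError(
            f"length spectrum defined for INSERTION/DELETION/MNV, got {cls!r}"
        )
    vclass = VariantClass(key)
    sub = extract_by_class(table, vclass)
    measure = mnv_length if vclass is VariantClass.MNV else indel_length
    hist: dict[int, int] = {}
    for r in sub:
        length = measure(r.ref, r.alt)
        hist[length] = hist.get(length, 0) + 1
    return LengthSpectrum(vclass, dict(sorted(hist.items())))


def counts_per_individual(
    table: DNVTable,
    roster: list[str] | None = None,
    bandwidth: str | float = "scott",
    grid_points: int = 256,
) -> IndividualCounts:
    """Per-sample DNV counts with their mean, sample standard deviation
    (n-1 denominator), and a Gaussian kernel-density curve of the counts.

    Only samples present in the table are counted unless ``roster`` adds
    known samples with zero DNVs (a variant table cannot attest absent
    samples on its own).  With a single sample the SD is undefined (NaN).
    """
    if len(table) == 0 and not roster:
        raise ContractError("counts_per_individual requires a non-empty table")
    per_sample: dict[str, int] = {s: 0 for s in (roster or [])}
    for r in table:
        per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
    values = np.array(list(per_sample.values()), dtype=float)
    mean = float(values.mean())
    if len(values) < 2:
        warnings.warn(
            "single sample: standard deviation undefined", DNVWarning, stacklevel=2
        )
        sd = math.nan
    else:
        sd = float(values.std(ddof=1))
    density = None
    if len(values) >= 2 and values.std() > 0:
        kde = stats.gaussian_kde(values, bw_method=bandwidth)
        pad = 3 * kde.factor * values.std(ddof=1)
        grid = np.linspace(values.min() - pad, values.max() + pad, grid_points)
        density = (grid.tolist(), kde(grid).tolist())
    return IndividualCounts(per_sample, mean, sd, density)
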