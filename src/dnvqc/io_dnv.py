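"""Reading and writing de novo variant (DNV) tables and companion tables.

All exchange formats are tab-separated text with a header row:

* DNV tables: columns ``sample``, ``chrom``, ``pos``, ``ref``, ``alt``
  (plus an optional ``at_cpg`` column written by the CpG annotator).
* Per-sample count tables: ``sample``, ``dnm_counts``.
* Parental-age tables: ``sample``, ``fatherAge``, ``motherAge`` and, for a
  pre-joined modelling table, ``dnm_counts`` as well.

Chromosome names are normalized on read (a leading ``chr`` prefix is
stripped case-insensitively; sex/mito contigs are upper-cased) while the
original spelling is preserved for output.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DNVWarning, ParseError, ValidationError

VALID_BASES = frozenset("ACGT")

DNV_COLUMNS = ("sample", "chrom", "pos", "ref", "alt")

_SPECIAL_CHROMS = {"X", "Y", "M", "MT"}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip any leading ``chr`` prefixes
    (case-insensitive) and upper-case sex/mitochondrial contigs.

    Idempotent: ``normalize_chrom(normalize_chrom(x)) == normalize_chrom(x)``.
    """
    s = str(name).strip()
    while s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in _SPECIAL_CHROMS:
        s = s.upper()
    return s


@dataclass(frozen=True)
class DNVRecord:
    """One de novo variant: sample, locus, and REF/ALT alleles.

    ``pos`` is the 1-based reference coordinate of the first REF base
    (VCF-style anchoring for indels).  ``at_cpg`` is a tri-state: ``None``
    until the CpG annotator sets it, then True/False.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    chrom_original: str = ""
    at_cpg: bool | None = None

    def __post_init__(self):
        if not self.chrom_original:
            object.__setattr__(self, "chrom_original", self.chrom)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not self.sample_id:
            raise ValidationError("empty sample id")
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not isinstance(self.pos, int) or self.pos < 1:
            raise ValidationError(f"pos must be an integer >= 1, got {self.pos!r}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele:
                raise ValidationError(f"empty {label} allele")
            if not set(allele) <= VALID_BASES:
                raise ValidationError(
                    f"{label} allele {allele!r} contains characters outside A/C/G/T"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}); not a variant")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class DNVTable:
    """Ordered collection of :class:`DNVRecord`; the currency of every
    subsetting and summary operation.  Iteration order equals input order."""

    records: tuple[DNVRecord, ...] = ()
    provenance: str = ""

    def __post_init__(self):
        self.records = tuple(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DNVRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, DNVTable) and self.records == other.records

    def duplicate_count(self) -> int:
        """Number of surplus rows sharing a (sample, chrom, pos, ref, alt) key."""
        counts = Counter(r.key for r in self.records)
        return sum(c - 1 for c in counts.values() if c > 1)

    def with_provenance(self, note: str) -> "DNVTable":
        prov = f"{self.provenance} | {note}" if self.provenance else note
        return DNVTable(self.records, prov)

    def samples(self) -> list[str]:
        """Distinct sample ids in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        annotated = any(r.at_cpg is not None for r in self.records)
        rows = []
        for r in self.records:
            row = {
                "sample": r.sample_id,
                "chrom": r.chrom_original,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
            }
            if annotated:
                row["at_cpg"] = (
                    "" if r.at_cpg is None else ("TRUE" if r.at_cpg else "FALSE")
                )
            rows.append(row)
        cols = list(DNV_COLUMNS) + (["at_cpg"] if annotated else [])
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ParentalAgeRecord:
    """Per-sample DNV count joined with parental ages at birth (years)."""

    sample: str
    dnm_counts: int
    fatherAge: float
    motherAge: float

    def validate(self) -> None:
        if not self.sample:
            raise ValidationError("empty sample id")
        if not isinstance(self.dnm_counts, int) or self.dnm_counts < 0:
            raise ValidationError(
                f"dnm_counts must be a non-negative integer, got {self.dnm_counts!r}"
            )
        for label, age in (("fatherAge", self.fatherAge), ("motherAge", self.motherAge)):
            if not math.isnan(age) and age < 0:
                raise ValidationError(f"{label} must be >= 0, got {age!r}")


# ---------------------------------------------------------------------------
# DNV tables


def _resolve_columns(
    header: Sequence[str],
    required: Sequence[str],
    column_map: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map canonical column names to actual header names.

    Matching is case-insensitive; ``column_map`` binds canonical names to
    arbitrary header dialects (e.g. ``{"chrom": "CHROM", "sample": "ID"}``).
    """
    lower = {h.lower(): h for h in header}
    resolved = {}
    for canon in required:
        wanted = (column_map or {}).get(canon, canon)
        if wanted in header:
            resolved[canon] = wanted
        elif wanted.lower() in lower:
            resolved[canon] = lower[wanted.lower()]
        else:
            raise ConfigurationError(
                f"required column {wanted!r} (for {canon!r}) not found in header: "
                f"{list(header)}"
            )
    return resolved


def _parse_at_cpg(raw: str, line: int) -> bool | None:
    s = raw.strip().upper()
    if s in ("", "NA", "NONE"):
        return None
    if s == "TRUE":
        return True
    if s == "FALSE":
        return False
    raise ParseError(f"unrecognized at_cpg value {raw!r}", line)


def read_dnv_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    permissive: bool = False,
) -> DNVTable:
    """Read a tab-separated DNV table into a validated :class:`DNVTable`.

    In the default strict mode the first invalid row aborts with a
    :class:`ParseError` naming its 1-based line number; with
    ``permissive=True`` invalid rows are skipped and counted in a warning.
    Duplicate records are retained but reported.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, DNV_COLUMNS, column_map)
    has_cpg = "at_cpg" in {c.lower() for c in df.columns}
    cpg_col = next((c for c in df.columns if c.lower() == "at_cpg"), None)

    records: list[DNVRecord] = []
    rejected = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based; header is line 1
        row_d = dict(zip(df.columns, row))
        try:
            raw_pos = row_d[cols["pos"]].strip()
            try:
                pos = int(raw_pos)
            except ValueError:
                raise ValidationError(f"non-integer pos {raw_pos!r}") from None
            raw_chrom = row_d[cols["chrom"]].strip()
            rec = DNVRecord(
                sample_id=row_d[cols["sample"]].strip(),
                chrom=normalize_chrom(raw_chrom),
                pos=pos,
                ref=row_d[cols["ref"]].strip().upper(),
                alt=row_d[cols["alt"]].strip().upper(),
                chrom_original=raw_chrom,
                at_cpg=_parse_at_cpg(row_d[cpg_col], line) if has_cpg else None,
            )
            rec.validate()
        except (ValidationError, ParseError) as exc:
            if permissive:
                rejected += 1
                continue
            if isinstance(exc, ParseError):
                raise
            raise ParseError(str(exc), line) from exc
        records.append(rec)

    if not records and rejected == 0:
        warnings.warn(f"{path}: no data rows (header only)", DNVWarning, stacklevel=2)
    if rejected:
        warnings.warn(
            f"{path}: skipped {rejected} invalid row(s) in permissive mode",
            DNVWarning,
            stacklevel=2,
        )
    table = DNVTable(tuple(records), provenance=str(path))
    ndup = table.duplicate_count()
    if ndup:
        warnings.warn(
            f"{path}: {ndup} duplicate record(s) (same sample/chrom/pos/ref/alt); "
            "retained",
            DNVWarning,
            stacklevel=2,
        )
    return table


def write_dnv_table(table: DNVTable, path: str | Path) -> None:
    """Write ``table`` as TSV; an ``at_cpg`` column (TRUE/FALSE) is emitted
    iff any record carries an annotation.  ``read_dnv_table`` round-trips
    the result record-for-record."""
    table.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count / age tables


def _read_numeric_table(
    path: str | Path, required: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, required, None)
    return df, cols


def _parse_float(raw: str, label: str, line: int) -> float:
    s = raw.strip()
    if s.upper() in ("", "NA", "NAN"):
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"non-numeric {label} {raw!r}", line) from None


def _parse_count(raw: str, label: str, line: int) -> int:
    s = raw.strip()
    try:
        return int(s)
    except ValueError:
        raise ParseError(f"non-integer {label} {raw!r}", line) from None


def _check_unique_samples(samples: Iterable[str], path: Path) -> None:
    counts = Counter(samples)
    dups = sorted(s for s, c in counts.items() if c > 1)
    if dups:
        raise ParseError(f"{path}: duplicated sample id(s): {', '.join(dups)}")


def read_count_table(path: str | Path) -> dict[str, int]:
    """Read a per-sample DNV count table (columns sample, dnm_counts)."""
    path = Path(path)
    df, cols = _read_numeric_table(path, ("sample", "dnm_counts"))
    out: dict[str, int] = {}
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row_d = dict(zip(df.columns, row))
        sample = row_d[cols["sample"]].strip()
        count = _parse_count(row_d[cols["dnm_counts"]], "dnm_counts", line)
        if count < 0:
            raise ParseError(f"negative dnm_counts {count}", line)
        samples.append(sample)
        out[sample] = count
    _check_unique_samples(samples, path)
    return out


def read_age_table(path: str | Path) -> pd.DataFrame:
    """Read a parental-age table (columns sample, fatherAge, motherAge)."""
    path = Path(path)
    df, cols = _read_numeric_table(path, ("sample", "fatherAge", "motherAge"))
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row_d = dict(zip(df.columns, row))
        rows.append(
            {
                "sample": row_d[cols["sample"]].strip(),
                "fatherAge": _parse_float(row_d[cols["fatherAge"]], "fatherAge", line),
                "motherAge": _parse_float(row_d[cols["motherAge"]], "motherAge", line),
            }
        )
    out = pd.DataFrame(rows, columns=["sample", "fatherAge", "motherAge"])
    _check_unique_samples(out["sample"], path)
    return out


def read_parental_age_table(path: str | Path) -> list[ParentalAgeRecord]:
    """Read a pre-joined modelling table with columns sample, dnm_counts,
    fatherAge, motherAge (case-insensitive header match)."""
    path = Path(path)
    df, cols = _read_numeric_table(
        path, ("sample", "dnm_counts", "fatherAge", "motherAge")
    )
    records: list[ParentalAgeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row_d = dict(zip(df.columns, row))
        rec = ParentalAgeRecord(
            sample=row_d[cols["sample"]].strip(),
            dnm_counts=_parse_count(row_d[cols["dnm_counts"]], "dnm_counts", line),
            fatherAge=_parse_float(row_d[cols["fatherAge"]], "fatherAge", line),
            motherAge=_parse_float(row_d[cols["motherAge"]], "motherAge", line),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ParseError(str(exc), line) from exc
        records.append(rec)
    _check_unique_samples((r.sample for r in records), path)
    return records


def write_count_table(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(counts), "dnm_counts": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


def write_age_table(ages: pd.DataFrame, path: str | Path) -> None:
    ages[["sample", "fatherAge", "motherAge"]].to_csv(path, sep="\t", index=False)


def write_parental_age_table(
    records: Sequence[ParentalAgeRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "sample": r.sample,
                "dnm_counts": r.dnm_counts,
                "fatherAge": r.fatherAge,
                "motherAge": r.motherAge,
            }
            for r in records
        ],
        columns=["sample", "dnm_counts", "fatherAge", "motherAge"],
    ).to_csv(path, sep="\t", index=False)
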