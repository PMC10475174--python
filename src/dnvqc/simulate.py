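"""Reproducible synthetic fixtures: toy reference genomes, DNV callsets
with controlled composition, and parental-age datasets with known slopes.

The default :class:`SimConfig` emulates a human trio-WGS de novo callset:
~70 DNVs per child across ~139 children, a class mix of ~87.9% SNVs,
~6.6% insertions and ~5.5% deletions, an expected Ti/Tv of 2.0, ~20% of
SNVs at CpG sites, and counts that rise by 1.0 per year of father's age
and 0.7 per year of mother's age around an intercept of 20.  All
generators are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cpg import _cpg_positions
from .errors import ValidationError
from .io_dnv import DNVRecord, DNVTable

BASES = ("A", "C", "G", "T")

#: transition partner of each base
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: the two transversion partners of each base
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

_MAX_INDEL = 10
_MAX_MNV = 3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    ``class_weights`` are proportions over (SNV, insertion, deletion, MNV);
    ``age_model`` is (intercept, beta_father, beta_mother, noise_sd) on the
    count scale with ages in years; ``age_ranges`` are the (father, mother)
    uniform sampling intervals in years.
    """

    seed: int = 1
    n_samples: int = 139
    mean_dnvs_per_sample: float = 70.0
    class_weights: tuple[float, float, float, float] = (
        8558 / 9741,
        643 / 9741,
        540 / 9741,
        0.0,
    )
    titv_target: float = 2.0
    cpg_fraction: float = 0.2
    age_model: tuple[float, float, float, float] = (20.0, 1.0, 0.7, 20.0)
    age_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (20.0, 45.0),
        (20.0, 40.0),
    )

    def validate(self) -> None:
        if abs(sum(self.class_weights) - 1.0) > 1e-9 or min(self.class_weights) < 0:
            raise ValidationError(
                f"class_weights must be non-negative and sum to 1, got "
                f"{self.class_weights}"
            )
        if (
            self.n_samples < 1
            or self.mean_dnvs_per_sample < 0
            or self.titv_target < 0
            or not (0.0 <= self.cpg_fraction <= 1.0)
            or self.age_model[3] < 0
        ):
            raise ValidationError("all rates must be >= 0 and cpg_fraction in [0,1]")


PRESETS: dict[str, SimConfig] = {"human-wgs": SimConfig()}


def simulate_reference(seed: int, n_chroms: int = 2, length: int = 10_000) -> dict[str, str]:
    """Random A/C/G/T chromosome sequences, keyed "1".."n_chroms"."""
    if length < 2:
        raise ValidationError(f"chromosome length must be >= 2, got {length}")
    rng = np.random.default_rng(seed)
    return {
        str(i + 1): "".join(rng.choice(BASES, size=length))
        for i in range(n_chroms)
    }


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, width) + "\n")


def _draw_snv(rng, seq: str, cpg_sites: np.ndarray, cpg_set: set, cfg: SimConfig):
    at_cpg = len(cpg_sites) > 0 and rng.random() < cfg.cpg_fraction
    if at_cpg:
        pos = int(cpg_sites[rng.integers(len(cpg_sites))])
    else:
        while True:
            pos = int(rng.integers(1, len(seq) + 1))
            if pos not in cpg_set:
                break
    ref = seq[pos - 1]
    p_ti = cfg.titv_target / (1.0 + cfg.titv_target)
    if rng.random() < p_ti:
        alt = TRANSITION[ref]
    else:
        alt = TRANSVERSIONS[ref][rng.integers(2)]
    return pos, ref, alt


def _draw_indel_length(rng) -> int:
    return int(min(rng.geometric(0.5), _MAX_INDEL))


def simulate_dnv_table(config: SimConfig, reference: Mapping[str, str]) -> DNVTable:
    """Simulate a DNV callset against ``reference``.

    Per-sample counts are Poisson(mean_dnvs_per_sample); classes follow
    ``class_weights``; SNV substitutions are transitions with probability
    titv_target / (1 + titv_target) so the expected Ti/Tv equals the
    target; SNVs land on CpG sites with probability ``cpg_fraction``.
    Indel and MNV alleles are taken from the reference in VCF-anchored
    form, so every record passes validation against it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = list(reference)
    min_len = _MAX_INDEL + 2
    for name, seq in reference.items():
        if len(seq) < min_len:
            raise ValidationError(
                f"reference chromosome {name!r} too small to place variants "
                f"(need >= {min_len} bp, got {len(seq)})"
            )
    cpg = {name: _cpg_positions(seq) for name, seq in reference.items()}
    cpg_sets = {name: set(arr.tolist()) for name, arr in cpg.items()}
    if (
        config.cpg_fraction > 0
        and config.class_weights[0] > 0
        and all(len(p) == 0 for p in cpg.values())
    ):
        raise ValidationError("reference contains no CpG sites to place SNVs on")

    weights = np.asarray(config.class_weights, dtype=float)
    records: list[DNVRecord] = []
    counts = rng.poisson(config.mean_dnvs_per_sample, size=config.n_samples)
    for i, n_var in enumerate(counts):
        sample = f"s{i + 1:04d}"
        classes = rng.choice(4, size=n_var, p=weights)
        for cls in classes:
            chrom = chroms[rng.integers(len(chroms))]
            seq = reference[chrom]
            if cls == 0:  # SNV
                pos, ref, alt = _draw_snv(
                    rng, seq, cpg[chrom], cpg_sets[chrom], config
                )
            elif cls == 1:  # insertion
                pos = int(rng.integers(1, len(seq) + 1))
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice(BASES, size=_draw_indel_length(rng)))
            elif cls == 2:  # deletion
                length = _draw_indel_length(rng)
                pos = int(rng.integers(1, len(seq) - length + 1))
                ref = seq[pos - 1 : pos + length]
                alt = ref[0]
            else:  # MNV
                length = int(rng.integers(2, _MAX_MNV + 1))
                pos = int(rng.integers(1, len(seq) - length + 2))
                ref = seq[pos - 1 : pos - 1 + length]
                alt = "".join(
                    rng.choice([b for b in BASES if b != base]) for base in ref
                )
            rec = DNVRecord(sample, chrom, pos, ref, alt)
            rec.validate()
            records.append(rec)
    return DNVTable(tuple(records), provenance=f"simulated(seed={config.seed})")


def simulate_parental_ages(
    config: SimConfig,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Simulate (counts table, ages table) with a known linear age effect.

    Ages are uniform over the configured ranges; counts are
    round(intercept + beta_father*fatherAge + beta_mother*motherAge +
    Gaussian noise), floored at 1 so exponential-model fixtures are always
    valid.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    intercept, beta_f, beta_m, noise_sd = config.age_model
    (f_lo, f_hi), (m_lo, m_hi) = config.age_ranges
    samples = [f"s{i + 1:04d}" for i in range(config.n_samples)]
    father = rng.uniform(f_lo, f_hi, size=config.n_samples)
    mother = rng.uniform(m_lo, m_hi, size=config.n_samples)
    noise = rng.normal(0.0, noise_sd, size=config.n_samples) if noise_sd > 0 else 0.0
    raw = intercept + beta_f * father + beta_m * mother + noise
    counts = np.maximum(np.rint(raw), 1).astype(int)
    ages = pd.DataFrame(
        {"sample": samples, "fatherAge": father, "motherAge": mother}
    )
    return dict(zip(samples, counts.tolist())), ages


def simulate_fixed_composition(
    seed: int,
    n_transitions: int,
    n_transversions: int,
    n_deletions: int,
    n_insertions: int,
    n_mnvs: int = 0,
    n_samples: int = 100,
) -> DNVTable:
    """Synthetic callset with an exactly specified composition.

    Unlike :func:`simulate_dnv_table`, the class and transition counts are
    deterministic (only alleles, positions, and sample assignments are
    random), which makes the table a by-construction oracle for
    end-to-end summary checks.
    """
    rng = np.random.default_rng(seed)
    variants: list[tuple[str, str]] = []
    for _ in range(n_transitions):
        ref = BASES[rng.integers(4)]
        variants.append((ref, TRANSITION[ref]))
    for _ in range(n_transversions):
        ref = BASES[rng.integers(4)]
        variants.append((ref, TRANSVERSIONS[ref][rng.integers(2)]))
    for _ in range(n_deletions):
        anchor = BASES[rng.integers(4)]
        tail = "".join(rng.choice(BASES, size=_draw_indel_length(rng)))
        variants.append((anchor + tail, anchor))
    for _ in range(n_insertions):
        anchor = BASES[rng.integers(4)]
        tail = "".join(rng.choice(BASES, size=_draw_indel_length(rng)))
        variants.append((anchor, anchor + tail))
    for _ in range(n_mnvs):
        length = int(rng.integers(2, _MAX_MNV + 1))
        ref = "".join(rng.choice(BASES, size=length))
        alt = "".join(rng.choice([b for b in BASES if b != base]) for base in ref)
        variants.append((ref, alt))
    order = rng.permutation(len(variants))
    records = []
    for idx in order:
        ref, alt = variants[idx]
        sample = f"s{int(rng.integers(n_samples)) + 1:04d}"
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1, 1_000_000))
        rec = DNVRecord(sample, chrom, pos, ref, alt)
        rec.validate()
        records.append(rec)
    return DNVTable(tuple(records), provenance=f"simulated_fixed(seed={seed})")
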