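"""Haplotype calling at locus-binned reads and multi-allelic coding.

Reads are pre-assigned to loci (in the synthetic pipeline via the
generator truth table); per individual and locus the two most frequent
read sequences form the haplotype call subject to a minimum read
coverage, and loci are then filtered by how many populations, and what
fraction of individuals within each, carry a call.  Surviving haplotypes
are densely integer-coded per locus for the Bayesian clustering input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def call_individual_haplotypes(
    reads: list[str],
    read_cov_min: int = 6,
    minor_fraction: float = 0.25,
) -> tuple[str, str] | None:
    """Call an unordered haplotype pair from one individual's reads.

    Reads containing undefined (N) bases are discarded first.  The call
    is missing when fewer than ``read_cov_min`` reads remain.  The two
    most frequent sequences form a heterozygote when the second's count
    reaches ``ceil(minor_fraction * total)``; otherwise the call is
    homozygous for the top sequence.  Ties rank lexicographically for
    determinism.
    """
    clean = [r for r in reads if "N" not in r]
    total = len(clean)
    if total < read_cov_min:
        return None
    counts: dict[str, int] = {}
    for r in clean:
        counts[r] = counts.get(r, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[0][0]
    if len(ranked) > 1 and ranked[1][1] >= math.ceil(minor_fraction * total):
        second = ranked[1][0]
        return tuple(sorted((top, second)))  # type: ignore[return-value]
    return (top, top)


@dataclass
class HaplotypeTable:
    """Loci x individuals haplotype-sequence calls (None = missing)."""

    calls: dict[str, dict[str, tuple[str, str] | None]]  # locus -> individual -> pair
    individuals: list[str]
    pop_map: dict[str, str] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return list(self.calls)

    @classmethod
    def from_binned_reads(
        cls,
        bins: dict[str, dict[str, list[str]]],
        pop_map: dict[str, str] | None = None,
        read_cov_min: int = 6,
        minor_fraction: float = 0.25,
    ) -> "HaplotypeTable":
        """``bins``: locus -> individual -> read sequences."""
        individuals = sorted({ind for locus in bins.values() for ind in locus})
        calls = {
            locus: {
                ind: call_individual_haplotypes(
                    reads.get(ind, []), read_cov_min, minor_fraction
                )
                for ind in individuals
                for reads in (bins[locus],)
            }
            for locus in sorted(bins)
        }
        return cls(calls, individuals, dict(pop_map or {}))


def _coverage_ok(
    called: dict[str, bool],
    pop_map: dict[str, str],
    pop_cov_min: int,
    intra_cov_min: float,
) -> bool:
    pops: dict[str, list[bool]] = {}
    for ind, ok in called.items():
        pop = pop_map.get(ind)
        if pop is None:
            raise ValueError(f"individual {ind!r} missing from population map")
        pops.setdefault(pop, []).append(ok)
    if any(len(v) == 0 for v in pops.values()) or not pops:
        raise ValueError("empty population")
    n_covered = sum(
        1 for members in pops.values() if sum(members) / len(members) >= intra_cov_min
    )
    return n_covered >= pop_cov_min


def filter_loci(
    table: HaplotypeTable,
    pop_map: dict[str, str] | None = None,
    pop_cov_min: int = 3,
    intra_cov_min: float = 0.7,
) -> HaplotypeTable:
    """Keep loci called in >= ``intra_cov_min`` of individuals within at
    least ``pop_cov_min`` populations (boundaries inclusive)."""
    pop_map = pop_map or table.pop_map
    kept = {
        locus: cells
        for locus, cells in table.calls.items()
        if _coverage_ok(
            {ind: cells[ind] is not None for ind in table.individuals},
            pop_map, pop_cov_min, intra_cov_min,
        )
    }
    return HaplotypeTable(kept, list(table.individuals), dict(pop_map))


def stacks_style_locus_filter(
    snp_table: pd.DataFrame,
    pop_map: dict[str, str],
    min_frac: float = 0.4,
    min_pops: int = 3,
) -> pd.DataFrame:
    """SNP-level presence filter: a locus (column) survives when genotyped
    in >= ``min_frac`` of individuals within each of >= ``min_pops``
    populations.  Missing cells are NaN or './.'."""
    present = snp_table.notna() & (snp_table != "./.")
    keep = []
    for locus in snp_table.columns:
        pops: dict[str, list[bool]] = {}
        for ind in snp_table.index:
            pop = pop_map.get(str(ind))
            if pop is None:
                raise ValueError(f"individual {ind!r} missing from population map")
            pops.setdefault(pop, []).append(bool(present.loc[ind, locus]))
        n_ok = sum(1 for v in pops.values() if v and sum(v) / len(v) >= min_frac)
        if n_ok >= min_pops:
            keep.append(locus)
    return snp_table[keep]


def encode_multiallelic(
    table: HaplotypeTable,
) -> tuple[GenotypeMatrix, dict[str, dict[str, int]]]:
    """Integer-code haplotype sequences as dense multi-allelic loci.

    Per locus, distinct haplotype sequences map to integers 0..k-1 in
    order of first appearance over individuals (missing = -9).  Returns
    the GenotypeMatrix and the per-locus decoding dictionaries.
    """
    loci = table.loci
    inds = table.individuals
    arr = np.full((len(inds), len(loci), 2), MISSING, dtype=np.int64)
    dictionaries: dict[str, dict[str, int]] = {}
    for j, locus in enumerate(loci):
        mapping: dict[str, int] = {}
        for i, ind in enumerate(inds):
            pair = table.calls[locus].get(ind)
            if pair is None:
                continue
            codes = []
            for h in pair:
                if h not in mapping:
                    mapping[h] = len(mapping)
                codes.append(mapping[h])
            arr[i, j] = sorted(codes)
        dictionaries[locus] = mapping
    geno = GenotypeMatrix(arr, list(inds), list(loci), dict(table.pop_map))
    return geno, dictionaries
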