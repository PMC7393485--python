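"""Synthetic mtDNA control-region haplotype references and samples.

The reference table pairs haplotype names with synthetic control-region
sequences; loggerhead-style names (CC-*) and hawksbill-style names (Ei-*)
carry the maternal-species information the classifier uses.  Sequences
are random but mutually distant, so nearest-haplotype assignment has an
unambiguous truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_BASES = np.array(list("ACGT"))

#: haplotype name -> maternal species (A = loggerhead-style, B = hawksbill-style)
DEFAULT_HAPLOTYPES = {
    "CC-A4.1": "A",
    "CC-A4.2": "A",
    "Ei-A01": "B",
    "Ei-A49": "B",
}


def make_mtdna_references(
    config_or_seed, length: int = 380, haplotypes: dict[str, str] | None = None
) -> pd.DataFrame:
    """Reference table with columns haplotype, species, sequence."""
    if hasattr(config_or_seed, "rng"):
        rng = config_or_seed.rng("mtdna")
    else:
        rng = np.random.default_rng(config_or_seed)
    haplotypes = haplotypes or dict(DEFAULT_HAPLOTYPES)
    base = "".join(_BASES[rng.integers(0, 4, size=length)])
    rows = []
    for k, (name, species) in enumerate(sorted(haplotypes.items())):
        seq = list(base)
        # >= 20 private substitutions per haplotype keeps references far apart
        positions = rng.choice(length, size=20, replace=False)
        for p in positions:
            seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
        rows.append({"haplotype": name, "species": species, "sequence": "".join(seq)})
    return pd.DataFrame(rows)


def sample_mtdna(
    references: pd.DataFrame, haplotype: str, n_mutations: int, rng
) -> str:
    """A sampled control-region sequence: a named reference plus noise."""
    row = references.loc[references["haplotype"] == haplotype]
    if row.empty:
        raise KeyError(f"unknown haplotype {haplotype!r}")
    seq = list(row["sequence"].iloc[0])
    if n_mutations:
        for p in rng.choice(len(seq), size=n_mutations, replace=False):
            seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
    return "".join(seq)
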