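"""Genotype containers shared across the pipeline.

Alleles are small non-negative integers; at species-diagnostic loci allele 0
is the species-A-typical allele.  Missing calls are stored as -9 (the
STRUCTURE convention) in both cells of the allele pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -9


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of unordered allele pairs.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Missing
        genotypes have both entries equal to :data:`MISSING`.
    individuals
        Sample identifiers, one per row.
    loci
        Locus identifiers, one per column.
    """

    alleles: np.ndarray
    individuals: list[str]
    loci: list[str]
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if self.alleles.shape[0] != len(self.individuals):
            raise ValueError("row count does not match number of individuals")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("column count does not match number of loci")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing genotypes."""
        return (self.alleles == MISSING).any(axis=2)

    def select_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.alleles[:, index, :],
            list(self.individuals),
            [self.loci[i] for i in index],
            dict(self.populations),
        )

    def select_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        inds = [self.individuals[i] for i in index]
        return GenotypeMatrix(
            self.alleles[index, :, :],
            inds,
            list(self.loci),
            {i: p for i, p in self.populations.items() if i in inds},
        )

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame of 'a/b' strings ('./.' when missing)."""
        cells = np.empty((self.n_individuals, self.n_loci), dtype=object)
        for i in range(self.n_individuals):
            for j in range(self.n_loci):
                a, b = self.alleles[i, j]
                cells[i, j] = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
        return pd.DataFrame(cells, index=self.individuals, columns=self.loci)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        arr = np.full((df.shape[0], df.shape[1], 2), MISSING, dtype=np.int64)
        for i, (_, row) in enumerate(df.iterrows()):
            for j, cell in enumerate(row):
                cell = str(cell)
                if cell in ("./.", "nan", "", "-9/-9"):
                    continue
                a, b = cell.split("/")
                arr[i, j] = (int(a), int(b))
        return cls(arr, [str(x) for x in df.index], [str(c) for c in df.columns])

    def to_structure(self, path_or_buf) -> None:
        """Write the two-rows-per-individual integer format used by
        population-clustering software (missing = -9)."""
        buf = io.StringIO()
        buf.write("\t".join(["individual", "pop"] + list(self.loci)) + "\n")
        for i, ind in enumerate(self.individuals):
            pop = self.populations.get(ind, "0")
            for copy in range(2):
                vals = [str(int(a)) for a in self.alleles[i, :, copy]]
                buf.write("\t".join([ind, str(pop)] + vals) + "\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)
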