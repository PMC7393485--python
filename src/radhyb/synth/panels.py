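"""Parental reference panels and pedigree-class genotype simulation.

Two divergent species are described by per-locus allele-frequency vectors.
The leading ``n_diagnostic`` loci are fixed for different alleles (allele 0
species-A-typical, allele 1 species-B-typical); each remaining locus is
fixed-different with probability ``divergence`` and otherwise shares one
frequency vector between the species (an undifferentiated locus).

Crosses are simulated by explicit gamete sampling with unlinked loci:
an F1 gamete picks its species of origin per locus with probability 1/2,
which is what makes a first-generation backcross homospecific at any one
diagnostic locus with probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .. import hybrid_classes as hc
from ..genotypes import GenotypeMatrix
from .config import SimConfig


@dataclass
class SyntheticPanels:
    """True parental frequencies plus sampled panel genotypes."""

    freqs_a: np.ndarray  # (n_loci, n_alleles), rows sum to 1
    freqs_b: np.ndarray
    diagnostic: np.ndarray  # bool per locus
    loci: list[str]
    panel_a: GenotypeMatrix
    panel_b: GenotypeMatrix

    @property
    def n_loci(self) -> int:
        return self.freqs_a.shape[0]


@dataclass
class Pedigree:
    """Ground truth for a simulated cohort."""

    individuals: list[str]
    class_labels: list[str]
    expected_h: np.ndarray  # per-individual expected hybrid index
    realized_h: np.ndarray  # realized fraction of species-B gene copies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individuals,
                "class": self.class_labels,
                "expected_h": self.expected_h,
                "realized_h": self.realized_h,
            }
        )


def _hw_draw(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """Hardy-Weinberg genotypes: two independent allele draws per locus."""
    n_loci, n_alleles = freqs.shape
    out = np.empty((n, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        out[:, l, :] = rng.choice(n_alleles, size=(n, 2), p=freqs[l])
    return out


def make_reference_panels(config: SimConfig) -> SyntheticPanels:
    """Draw species frequency vectors and sample the parental panels."""
    config.validate()
    rng = config.rng("panels")
    L, K = config.n_loci, config.n_alleles

    freqs_a = np.zeros((L, K))
    freqs_b = np.zeros((L, K))
    diagnostic = np.zeros(L, dtype=bool)
    diagnostic[: config.n_diagnostic] = True

    fixed_extra = rng.random(L) < config.divergence
    fixed_extra[: config.n_diagnostic] = False

    for l in range(L):
        if diagnostic[l] or fixed_extra[l]:
            freqs_a[l, 0] = 1.0
            freqs_b[l, 1] = 1.0
        else:
            shared = rng.dirichlet(np.ones(K))
            freqs_a[l] = shared
            freqs_b[l] = shared
    diagnostic |= fixed_extra

    loci = [f"L{l:05d}" for l in range(L)]
    ids_a = [f"A{i + 1}" for i in range(config.n_panel)]
    ids_b = [f"B{i + 1}" for i in range(config.n_panel)]
    panel_a = GenotypeMatrix(
        _hw_draw(rng, freqs_a, config.n_panel), ids_a, loci,
        {i: "species_A" for i in ids_a},
    )
    panel_b = GenotypeMatrix(
        _hw_draw(rng, freqs_b, config.n_panel), ids_b, loci,
        {i: "species_B" for i in ids_b},
    )
    return SyntheticPanels(freqs_a, freqs_b, diagnostic, loci, panel_a, panel_b)


def _gametes(
    rng: np.random.Generator, panels: SyntheticPanels, origin: np.ndarray
) -> np.ndarray:
    """Draw one gamete per (individual, locus) given species of origin.

    origin : bool array (n, L), True where the gene copy comes from B.
    """
    n, L = origin.shape
    K = panels.freqs_a.shape[1]
    out = np.empty((n, L), dtype=np.int64)
    for l in range(L):
        a_draw = rng.choice(K, size=n, p=panels.freqs_a[l])
        b_draw = rng.choice(K, size=n, p=panels.freqs_b[l])
        out[:, l] = np.where(origin[:, l], b_draw, a_draw)
    return out


def _origin_for_class(
    rng: np.random.Generator, label: str, n: int, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Species-of-origin masks (copy1, copy2); True = from species B."""
    half = rng.random((n, L)) < 0.5  # an F1 parent's per-locus meiosis
    half2 = rng.random((n, L)) < 0.5
    zeros = np.zeros((n, L), dtype=bool)
    ones = np.ones((n, L), dtype=bool)
    if label == hc.PURE_A:
        return zeros, zeros.copy()
    if label == hc.PURE_B:
        return ones, ones.copy()
    if label == hc.F1:
        return zeros, ones
    if label == hc.F2:
        return half, half2
    if label == hc.BX_A:
        return zeros, half
    if label == hc.BX_B:
        return ones, half
    raise ValueError(f"unknown hybrid class label: {label!r}")


def simulate_cross(
    panels: SyntheticPanels,
    class_label: str,
    n: int,
    seed: int | np.random.Generator,
) -> tuple[GenotypeMatrix, Pedigree]:
    """Simulate ``n`` individuals of one pedigree class."""
    if class_label not in hc.CLASSES:
        raise ValueError(f"unknown hybrid class label: {class_label!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    L = panels.n_loci
    o1, o2 = _origin_for_class(rng, class_label, n, L)
    g1 = _gametes(rng, panels, o1)
    g2 = _gametes(rng, panels, o2)
    alleles = np.stack([g1, g2], axis=2)
    # unordered pair: sort the two copies for a canonical representation
    alleles.sort(axis=2)

    ids = [f"{class_label}_{i + 1}" for i in range(n)]
    realized = (o1.sum(axis=1) + o2.sum(axis=1)) / (2 * L) if L else np.zeros(n)
    ped = Pedigree(
        ids,
        [class_label] * n,
        np.full(n, hc.EXPECTED_HYBRID_INDEX[class_label]),
        realized,
    )
    geno = GenotypeMatrix(alleles, ids, list(panels.loci), {i: class_label for i in ids})
    return geno, ped


def simulate_cohort(
    panels: SyntheticPanels, config: SimConfig
) -> tuple[GenotypeMatrix, Pedigree]:
    """All six classes, ``n_per_class`` individuals each, one shared stream."""
    rng = config.rng("cross")
    genos, peds = [], []
    for label in hc.CLASSES:
        g, p = simulate_cross(panels, label, config.n_per_class, rng)
        genos.append(g)
        peds.append(p)
    alleles = np.concatenate([g.alleles for g in genos], axis=0)
    individuals = [i for g in genos for i in g.individuals]
    pops = {}
    for g in genos:
        pops.update(g.populations)
    ped = Pedigree(
        individuals,
        [c for p in peds for c in p.class_labels],
        np.concatenate([p.expected_h for p in peds]),
        np.concatenate([p.realized_h for p in peds]),
    )
    return GenotypeMatrix(alleles, individuals, list(panels.loci), pops), ped
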