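"""Configuration for the synthetic-data generators.

One global integer seed deterministically expands into independent
per-generator streams, so a composite run (panels + crosses + reads +
nests) is reproducible as a whole and each generator is reproducible on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# fixed stream indices: changing these would silently change all outputs
_STREAMS = {
    "panels": 11,
    "cross": 23,
    "genome": 37,
    "reads": 41,
    "nests": 53,
    "mtdna": 67,
}

DEFAULT_BARCODES = {
    "S1": "ACGTACT",
    "S2": "CTGACTG",
    "S3": "GACTGAC",
    "S4": "TGCAGTA",
}


@dataclass
class ReadParams:
    """3RAD library structure knobs.

    ``size_window`` is the genomic digestion-fragment window in bp (the
    study's Blue Pippin selection); ``read_len`` is per-mate read length;
    ``duplicate_rate`` is the per-pair probability of emitting one extra
    PCR copy (same i5 tag, same sequences).
    """

    read_len: int = 150
    size_window: tuple[int, int] = (350, 450)
    duplicate_rate: float = 0.1
    barcode_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    depth: int = 8
    base_quality: int = 38
    i5_len: int = 8

    def validate(self) -> None:
        lo, hi = self.size_window
        if not lo < hi:
            raise ValueError("size window low must be < high")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")
        if self.read_len < 100:
            raise ValueError("read_len below the 100 bp duplicate-key window")
        if not self.barcode_map:
            raise ValueError("barcode map must be non-empty")


@dataclass
class NestGroupParams:
    clutch_mean: float = 113.7
    clutch_sd: float = 24.8
    hatch_prob: float = 0.568
    incubation_mean: float = 52.6
    incubation_sd: float = 3.5
    n_nests: int = 31

    def validate(self) -> None:
        if not 0.0 <= self.hatch_prob <= 1.0:
            raise ValueError("hatch probability must be in [0, 1]")
        if self.clutch_mean <= 0 or self.clutch_sd < 0:
            raise ValueError("invalid clutch-size parameters")
        if self.n_nests < 0:
            raise ValueError("n_nests must be >= 0")


def default_nest_params() -> dict[str, NestGroupParams]:
    # group means/SDs follow the study's reported loggerhead vs hybrid
    # reproductive output (hatching success 56.8% vs 27%, clutch size
    # 113.7 vs 137, incubation 52.6 vs 55 days)
    return {
        "loggerhead": NestGroupParams(),
        "hybrid": NestGroupParams(
            clutch_mean=137.0,
            clutch_sd=20.06,
            hatch_prob=0.27,
            incubation_mean=55.0,
            incubation_sd=3.06,
            n_nests=16,
        ),
    }


@dataclass
class SimConfig:
    """Top-level synthetic-study configuration.

    ``divergence`` is the per-locus probability that a non-diagnostic
    locus is fixed for different alleles between the two species; the
    ``n_diagnostic`` leading loci are always fixed-different.
    """

    n_loci: int = 300
    n_diagnostic: int = 6
    divergence: float = 0.2
    n_alleles: int = 2
    n_panel: int = 5
    n_per_class: int = 10
    seed: int = 0
    read_params: ReadParams = field(default_factory=ReadParams)
    nest_params: dict[str, NestGroupParams] = field(default_factory=default_nest_params)

    def validate(self) -> None:
        if self.n_diagnostic > self.n_loci:
            raise ValueError("n_diagnostic cannot exceed n_loci")
        if min(self.n_loci, self.n_diagnostic, self.n_panel, self.n_per_class) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.n_alleles < 2:
            raise ValueError("need at least two alleles per locus")
        self.read_params.validate()
        for params in self.nest_params.values():
            params.validate()

    def rng(self, stream: str) -> np.random.Generator:
        """Named, deterministic child stream of the global seed."""
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])
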