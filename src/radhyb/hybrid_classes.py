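"""The six two-generation hybrid classes and their ancestry-pair model.

Each class is characterised by the distribution of the per-locus ancestry
pair z -- the species-of-origin of an individual's two gene copies: both
from species A (``AA``), one from each (``AB``), or both from B (``BB``).
The rows are the standard Mendelian expectations for two generations of
hybridization with unlinked loci.
"""

from __future__ import annotations

import numpy as np

PURE_A = "PURE_A"
PURE_B = "PURE_B"
F1 = "F1"
F2 = "F2"
BX_A = "BX_A"
BX_B = "BX_B"

CLASSES: tuple[str, ...] = (PURE_A, PURE_B, F1, F2, BX_A, BX_B)

#: expected hybrid index (proportion of species-B gene copies) per class
EXPECTED_HYBRID_INDEX: dict[str, float] = {
    PURE_A: 0.0,
    PURE_B: 1.0,
    F1: 0.5,
    F2: 0.5,
    BX_A: 0.25,
    BX_B: 0.75,
}

#: per-class ancestry-pair proportions over z = (AA, AB, BB)
ANCESTRY_PROPORTIONS: dict[str, tuple[float, float, float]] = {
    PURE_A: (1.0, 0.0, 0.0),
    PURE_B: (0.0, 0.0, 1.0),
    F1: (0.0, 1.0, 0.0),
    F2: (0.25, 0.5, 0.25),
    BX_A: (0.5, 0.5, 0.0),
    BX_B: (0.0, 0.5, 0.5),
}


def ancestry_matrix() -> np.ndarray:
    """(6, 3) array of ancestry-pair proportions, rows ordered as CLASSES."""
    return np.array([ANCESTRY_PROPORTIONS[c] for c in CLASSES], dtype=float)
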