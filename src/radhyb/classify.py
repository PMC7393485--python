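"""Six-class hybrid-category assignment and diagnostic decision rules.

The genotype-frequency model: each of the six two-generation classes c
fixes a distribution G_c over the per-locus ancestry pair z (AA, AB, BB);
given z the genotype follows Hardy-Weinberg draws from the corresponding
parental frequency vectors.  With the parental frequencies treated as
fixed the class posterior is exact - a product over loci evaluated in
log space - so no MCMC is needed; an optional Gibbs mode re-samples the
panel frequencies from their Dirichlet posterior for parity checks
against samplers that integrate over frequency uncertainty.

Also here: the six-marker diagnostic decision table with mtDNA maternal
lineage, the back-calculated misassignment probability of a backcross
(0.5^k at k diagnostic loci: 1.56% at k = 6), nearest-haplotype mtDNA
assignment, and nest-level mother inference from hatchling labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hybrid_classes as hc
from .ancestry import ReferencePanel
from .genotypes import MISSING, GenotypeMatrix

HOM_A, HET, HOM_B, MISSING_CALL = "HOM_A", "HET", "HOM_B", "missing"

F2_OR_LATER = "F2_OR_LATER"
UNDETERMINED = "UNDETERMINED"


# ------------------------------------------------------------ likelihood
def _hw_prob(pair: tuple[int, int], freqs: np.ndarray, alleles: np.ndarray) -> float:
    ia = np.flatnonzero(alleles == pair[0])
    ib = np.flatnonzero(alleles == pair[1])
    if ia.size == 0 or ib.size == 0:
        return np.nan
    pa, pb = freqs[ia[0]], freqs[ib[0]]
    return float(pa * pb if pair[0] == pair[1] else 2.0 * pa * pb)


def _ab_prob(
    pair: tuple[int, int], fa: np.ndarray, fb: np.ndarray, alleles: np.ndarray
) -> float:
    ia = np.flatnonzero(alleles == pair[0])
    ib = np.flatnonzero(alleles == pair[1])
    if ia.size == 0 or ib.size == 0:
        return np.nan
    if pair[0] == pair[1]:
        return float(fa[ia[0]] * fb[ia[0]])
    return float(fa[ia[0]] * fb[ib[0]] + fa[ib[0]] * fb[ia[0]])


def genotype_prob_given_class(
    pair: tuple[int, int],
    locus_index: int,
    class_label: str,
    panel: ReferencePanel,
) -> float:
    """P(unordered genotype | hybrid class) at one locus.

    Mixture over the ancestry pair z: Hardy-Weinberg under p_A for z=AA,
    under p_B for z=BB, and one draw from each species for z=AB.
    """
    if class_label not in hc.CLASSES:
        raise ValueError(f"unknown hybrid class label: {class_label!r}")
    g = hc.ANCESTRY_PROPORTIONS[class_label]
    al = panel.alleles[locus_index]
    fa = panel.freqs_a[locus_index]
    fb = panel.freqs_b[locus_index]
    p_aa = _hw_prob(pair, fa, al)
    p_ab = _ab_prob(pair, fa, fb, al)
    p_bb = _hw_prob(pair, fb, al)
    if np.isnan(p_aa):
        return np.nan
    return g[0] * p_aa + g[1] * p_ab + g[2] * p_bb


def class_posterior(
    alleles_row: np.ndarray,
    panel: ReferencePanel,
    prior: np.ndarray | None = None,
    max_loci: int | None = None,
) -> pd.Series:
    """Exact posterior over the six classes for one individual."""
    prior = np.full(6, 1.0 / 6.0) if prior is None else np.asarray(prior, float)
    if prior.shape != (6,) or not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must be a length-6 probability vector")
    alleles_row = np.asarray(alleles_row)
    n_loci = alleles_row.shape[0] if max_loci is None else min(max_loci, alleles_row.shape[0])
    with np.errstate(divide="ignore"):
        logpost = np.log(prior)
    informative = 0
    valid = panel.valid
    for j in range(n_loci):
        pair = tuple(int(a) for a in alleles_row[j])
        if MISSING in pair or not valid[j]:
            continue
        probs = np.array(
            [genotype_prob_given_class(pair, j, c, panel) for c in hc.CLASSES]
        )
        if np.isnan(probs).any():
            warnings.warn(f"allele absent from both panels at locus {panel.loci[j]}; skipped")
            continue
        if np.allclose(probs, probs[0]):
            informative += 0  # uninformative locus: identical likelihood per class
        else:
            informative += 1
        with np.errstate(divide="ignore"):
            logpost += np.log(probs)
    if informative == 0:
        warnings.warn("all loci uninformative; returning the prior")
        return pd.Series(prior, index=hc.CLASSES)
    logpost -= logpost.max()
    post = np.exp(logpost)
    return pd.Series(post / post.sum(), index=hc.CLASSES)


# ---------------------------------------------------- model-style wrapper
class HybridClassifier:
    """Six-class assignment model over a genotype matrix.

    ``max_loci`` caps the analysis to the first ``max_loci`` loci (by
    locus order), mirroring locus-capped runs; ``random_loci`` instead
    samples that many loci with the given seed as a consistency check.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        panel: ReferencePanel,
        prior: np.ndarray | None = None,
        max_loci: int | None = None,
        random_loci: int | None = None,
    ):
        if genotypes.loci != panel.loci:
            raise ValueError("genotypes and panel must share the locus list")
        self.genotypes = genotypes
        self.panel = panel
        self.prior = np.full(6, 1.0 / 6.0) if prior is None else np.asarray(prior, float)
        self.max_loci = max_loci
        self.random_loci = random_loci

    def _locus_cap(self) -> int | None:
        return self.max_loci

    def fit(
        self,
        method: str = "exact",
        iterations: int = 50_000,
        burn_in: int = 10_000,
        seed: int | None = None,
    ) -> "HybridClassResults":
        geno = self.genotypes
        if self.random_loci is not None:
            rng = np.random.default_rng(seed)
            idx = np.sort(
                rng.choice(geno.n_loci, size=min(self.random_loci, geno.n_loci), replace=False)
            )
            geno = geno.select_loci(idx)
            panel = _subset_panel(self.panel, idx)
            cap = None
        else:
            panel = self.panel
            cap = self.max_loci
        if method == "exact":
            rows = [
                class_posterior(geno.alleles[i], panel, self.prior, cap)
                for i in range(geno.n_individuals)
            ]
        elif method == "gibbs":
            rows = _gibbs_posteriors(
                geno, panel, self.prior, cap, iterations, burn_in, seed
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        post = pd.DataFrame(rows, index=geno.individuals)
        return HybridClassResults(self, post, method)


def _subset_panel(panel: ReferencePanel, idx: np.ndarray) -> ReferencePanel:
    return ReferencePanel(
        [panel.loci[i] for i in idx],
        [panel.alleles[i] for i in idx],
        [panel.freqs_a[i] for i in idx],
        [panel.freqs_b[i] for i in idx],
        panel.n_called_a[idx],
        panel.n_called_b[idx],
        panel.pseudocount,
    )


def _gibbs_posteriors(geno, panel, prior, cap, iterations, burn_in, seed):
    """Average exact posteriors over Dirichlet re-draws of panel frequencies.

    Integrates over parental-frequency uncertainty: each sweep redraws
    every locus frequency vector from Dirichlet(count + pseudocount) and
    the per-sweep class posterior (exact given frequencies) is averaged
    over post-burn-in sweeps.  Sweeps are thinned to keep parity runs at
    the conventional iteration counts affordable.
    """
    rng = np.random.default_rng(seed)
    thin = max(1, (burn_in + iterations) // 200)
    acc = [np.zeros(6) for _ in range(geno.n_individuals)]
    n_used = 0
    counts_a, counts_b = [], []
    for j in range(len(panel.loci)):
        k = len(panel.alleles[j])
        ca = panel.freqs_a[j] * (2 * panel.n_called_a[j] + panel.pseudocount * k)
        cb = panel.freqs_b[j] * (2 * panel.n_called_b[j] + panel.pseudocount * k)
        counts_a.append(ca)
        counts_b.append(cb)
    for sweep in range(0, burn_in + iterations, thin):
        draw = _subset_panel(panel, np.arange(len(panel.loci)))
        draw.freqs_a = [rng.dirichlet(np.maximum(c, 1e-6)) for c in counts_a]
        draw.freqs_b = [rng.dirichlet(np.maximum(c, 1e-6)) for c in counts_b]
        if sweep < burn_in:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(geno.n_individuals):
                acc[i] += class_posterior(geno.alleles[i], draw, prior, cap).values
        n_used += 1
    return [pd.Series(a / n_used, index=hc.CLASSES) for a in acc]


class HybridClassResults:
    """Posterior class memberships; rows sum to one."""

    def __init__(self, model: HybridClassifier, posterior: pd.DataFrame, method: str):
        self.model = model
        self.posterior = posterior
        self.method = method

    @property
    def modal_class(self) -> pd.Series:
        return self.posterior.idxmax(axis=1).rename("modal_class")

    def summary(self) -> pd.DataFrame:
        df = self.posterior.copy()
        df["modal_class"] = self.modal_class
        df["modal_prob"] = self.posterior.max(axis=1)
        return df

    def plot(self, ax=None):
        """Stacked-bar class-membership plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.25 * len(self.posterior)), 3))
        bottom = np.zeros(len(self.posterior))
        x = np.arange(len(self.posterior))
        for cls in hc.CLASSES:
            vals = self.posterior[cls].values
            ax.bar(x, vals, bottom=bottom, label=cls, width=0.9)
            bottom += vals
        ax.set_ylabel("posterior probability")
        ax.set_xticks(x)
        ax.set_xticklabels(self.posterior.index, rotation=90, fontsize=6)
        ax.legend(fontsize=6, ncol=3)
        return ax


# ----------------------------------------------------- diagnostic rules
def backcross_error_rate(k: int) -> float:
    """P(a first-generation backcross is homospecific at all k loci).

    Each diagnostic locus in a backcross is homospecific or
    heterospecific with probability 1/2 and loci are unlinked, so the
    chance of missing the hybrid entirely is 0.5**k - 1.56% at the six
    diagnostic markers.
    """
    if not isinstance(k, (int, np.integer)) or k < 0:
        raise ValueError("k must be a non-negative integer")
    return 0.5 ** k


def categorize_diagnostic(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """HOM_A / HET / HOM_B / missing calls at diagnostic loci, assuming
    the allele-0 = species-A-typical convention."""
    cats = np.empty((genotypes.n_individuals, genotypes.n_loci), dtype=object)
    for i in range(genotypes.n_individuals):
        for j in range(genotypes.n_loci):
            a, b = sorted(genotypes.alleles[i, j])
            if a == MISSING or b == MISSING:
                cats[i, j] = MISSING_CALL
            elif a == 0 and b == 0:
                cats[i, j] = HOM_A
            elif a == 0:
                cats[i, j] = HET
            else:
                cats[i, j] = HOM_B
    return pd.DataFrame(cats, index=genotypes.individuals, columns=genotypes.loci)


@dataclass
class DiagnosticCall:
    label: str
    maternal_species: str | None = None
    n_informative: int = 0
    mtdna_haplotype: str | None = None


def diagnostic_assignment(
    calls: list[str],
    mtdna_species: str | None = None,
    mtdna_haplotype: str | None = None,
) -> DiagnosticCall:
    """Decision table over per-locus genotype categories.

    All homozygous-A -> pure A; all homozygous-B -> pure B; all
    heterozygous -> F1 with the maternal species given by the mtDNA
    lineage; heterozygous plus one homozygous class only -> backcross to
    that class; both homozygous classes present -> second generation or
    later.  All-missing input is undetermined.
    """
    informative = [c for c in calls if c != MISSING_CALL]
    n = len(informative)
    if n == 0:
        return DiagnosticCall(UNDETERMINED, None, 0, mtdna_haplotype)
    has = {c: c in informative for c in (HOM_A, HET, HOM_B)}
    if has[HOM_A] and has[HOM_B]:
        label = F2_OR_LATER
    elif has[HET]:
        if has[HOM_A]:
            label = hc.BX_A
        elif has[HOM_B]:
            label = hc.BX_B
        else:
            label = hc.F1
    elif has[HOM_A]:
        label = hc.PURE_A
    else:
        label = hc.PURE_B
    maternal = mtdna_species if label == hc.F1 else None
    return DiagnosticCall(label, maternal, n, mtdna_haplotype)


# --------------------------------------------------------------- nests
@dataclass
class MotherInference:
    mother: str  # PURE_A | PURE_B | F1_HYBRID | UNDETERMINED
    consistent: bool
    evidence: list[str] = field(default_factory=list)


def classify_nest(hatchling_calls: list[DiagnosticCall]) -> MotherInference:
    """Infer the mother's status from her hatchlings.

    A pure hatchling implies a pure mother of that species; a backcross
    or later-generation hatchling implies an F1 mother; an F1 hatchling
    implies a pure mother on its maternal (mtDNA) side.  Conflicting
    implications are flagged inconsistent.
    """
    if not hatchling_calls:
        return MotherInference(UNDETERMINED, True, [])
    implications: set[str] = set()
    evidence = []
    for call in hatchling_calls:
        if call.label == hc.PURE_A:
            implications.add(hc.PURE_A)
        elif call.label == hc.PURE_B:
            implications.add(hc.PURE_B)
        elif call.label in (hc.BX_A, hc.BX_B, F2_OR_LATER):
            implications.add("F1_HYBRID")
        elif call.label == hc.F1:
            if call.maternal_species == "A":
                implications.add(hc.PURE_A)
            elif call.maternal_species == "B":
                implications.add(hc.PURE_B)
            else:
                implications.add("PURE_UNKNOWN_SPECIES")
        evidence.append(call.label)
    concrete = implications - {"PURE_UNKNOWN_SPECIES"}
    if len(concrete) > 1:
        return MotherInference(UNDETERMINED, False, evidence)
    if concrete:
        return MotherInference(next(iter(concrete)), True, evidence)
    if "PURE_UNKNOWN_SPECIES" in implications:
        return MotherInference("PURE_UNKNOWN_SPECIES", True, evidence)
    return MotherInference(UNDETERMINED, True, evidence)


# --------------------------------------------------------------- mtDNA
@dataclass
class MtdnaAssignment:
    haplotype: str | None
    species: str | None
    distance: int
    ambiguous: bool
    candidates: list[str]


def assign_mtdna(
    sequence: str, reference_table: pd.DataFrame, max_len_diff: int = 5
) -> MtdnaAssignment:
    """Nearest-reference haplotype by Hamming distance.

    References and query are compared over their common aligned prefix;
    a length mismatch beyond ``max_len_diff`` raises.  Equidistant
    references are reported as ambiguous.
    """
    sequence = sequence.upper()
    best: list[tuple[str, str]] = []
    best_d: int | None = None
    for row in reference_table.itertuples():
        ref = row.sequence.upper()
        if abs(len(ref) - len(sequence)) > max_len_diff:
            raise ValueError(
                f"length mismatch beyond trim for haplotype {row.haplotype}"
            )
        n = min(len(ref), len(sequence))
        d = sum(1 for a, b in zip(sequence[:n], ref[:n]) if a != b)
        if best_d is None or d < best_d:
            best_d, best = d, [(row.haplotype, row.species)]
        elif d == best_d:
            best.append((row.haplotype, row.species))
    if best_d is None:
        raise ValueError("empty haplotype reference table")
    if len(best) > 1:
        return MtdnaAssignment(None, None, best_d, True, [b[0] for b in best])
    hap, species = best[0]
    return MtdnaAssignment(hap, species, best_d, False, [hap])
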