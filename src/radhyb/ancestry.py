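"""Bayesian hybrid-index estimation from parental reference panels.

The hybrid index h of an individual is the proportion of its allele
copies descending from parental species B.  With per-locus parental
allele-frequency vectors p_A and p_B (estimated from small reference
panels with a pseudocount and treated as fixed), each observed allele
copy a contributes likelihood (1-h)*p_A(a) + h*p_B(a); copies and loci
are independent.  Under a uniform prior, the posterior over h is sampled
by a reflected random-walk Metropolis chain on [0, 1] - 50,000 kept
iterations after a 10,000-iteration burn-in by default.  Run per
individual across a genotype matrix this doubles as a supervised
two-cluster admixture estimator (membership coefficients 1-h and h).

For fully diagnostic loci (parental frequencies fixed at 0/1) the
posterior is Beta(n_B + 1, n_A + 1) in closed form, which the test suite
uses as an independent oracle for the sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class ReferencePanel:
    """Per-locus parental allele-frequency vectors.

    Frequencies are pseudocounted so every allele observed in either
    panel has strictly positive frequency in both species.
    """

    loci: list[str]
    alleles: list[np.ndarray]  # per locus, the allele integers with frequencies
    freqs_a: list[np.ndarray]  # aligned with `alleles`, each sums to 1
    freqs_b: list[np.ndarray]
    n_called_a: np.ndarray
    n_called_b: np.ndarray
    pseudocount: float

    @property
    def valid(self) -> np.ndarray:
        """Loci usable downstream: called in both panels."""
        return (self.n_called_a > 0) & (self.n_called_b > 0)

    def swap(self) -> "ReferencePanel":
        """Exchange the two species (maps every hybrid index h -> 1-h)."""
        return ReferencePanel(
            list(self.loci), [a.copy() for a in self.alleles],
            [f.copy() for f in self.freqs_b], [f.copy() for f in self.freqs_a],
            self.n_called_b.copy(), self.n_called_a.copy(), self.pseudocount,
        )

    def lookup(self, locus_index: int, allele: int) -> tuple[float, float] | None:
        idx = np.flatnonzero(self.alleles[locus_index] == allele)
        if idx.size == 0:
            return None
        return (
            float(self.freqs_a[locus_index][idx[0]]),
            float(self.freqs_b[locus_index][idx[0]]),
        )


def _panel_counts(geno: GenotypeMatrix, j: int) -> dict[int, int]:
    counts: dict[int, int] = {}
    for a in geno.alleles[:, j, :].ravel():
        if a != MISSING:
            counts[int(a)] = counts.get(int(a), 0) + 1
    return counts


def estimate_allele_freqs(
    panel_a: GenotypeMatrix, panel_b: GenotypeMatrix, pseudocount: float = 0.5
) -> ReferencePanel:
    """Estimate parental frequencies from the two reference panels.

    frequency = (allele count + pseudocount) / (2 n_called + pseudocount * n_alleles),
    with the allele set per locus the union over both panels.  Loci with
    zero called individuals in a panel are flagged invalid and excluded
    downstream.
    """
    if panel_a.loci != panel_b.loci:
        raise ValueError("panels must share the locus list")
    if panel_a.n_individuals == 0 or panel_b.n_individuals == 0:
        raise ValueError("panels must be non-empty")
    loci = list(panel_a.loci)
    alleles, fa, fb = [], [], []
    n_a = np.zeros(len(loci), dtype=int)
    n_b = np.zeros(len(loci), dtype=int)
    for j in range(len(loci)):
        ca = _panel_counts(panel_a, j)
        cb = _panel_counts(panel_b, j)
        union = np.array(sorted(set(ca) | set(cb)), dtype=np.int64)
        n_a[j] = sum(ca.values()) // 2
        n_b[j] = sum(cb.values()) // 2
        k = len(union)
        if k == 0:
            alleles.append(union)
            fa.append(np.array([]))
            fb.append(np.array([]))
            continue
        counts_a = np.array([ca.get(int(a), 0) for a in union], dtype=float)
        counts_b = np.array([cb.get(int(a), 0) for a in union], dtype=float)
        denom_a = counts_a.sum() + pseudocount * k
        denom_b = counts_b.sum() + pseudocount * k
        fa.append((counts_a + pseudocount) / denom_a if denom_a > 0 else counts_a)
        fb.append((counts_b + pseudocount) / denom_b if denom_b > 0 else counts_b)
        alleles.append(union)
    return ReferencePanel(loci, alleles, fa, fb, n_a, n_b, pseudocount)


def _copy_probs(
    alleles_row: np.ndarray, panel: ReferencePanel
) -> tuple[np.ndarray, np.ndarray]:
    """(p_A, p_B) for each observed allele copy of one individual."""
    pa, pb = [], []
    valid = panel.valid
    for j in range(alleles_row.shape[0]):
        if not valid[j]:
            continue
        pair = alleles_row[j]
        if MISSING in pair:
            continue
        hits = [panel.lookup(j, int(a)) for a in pair]
        if any(h is None for h in hits):
            warnings.warn(
                f"allele absent from both panels at locus {panel.loci[j]}; locus skipped"
            )
            continue
        for h in hits:
            pa.append(h[0])
            pb.append(h[1])
    return np.asarray(pa, dtype=float), np.asarray(pb, dtype=float)


def loglik_h(h: float, alleles_row: np.ndarray, panel: ReferencePanel) -> float:
    """Log-likelihood of hybrid index ``h`` for one individual."""
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    pa, pb = _copy_probs(np.asarray(alleles_row), panel)
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log((1.0 - h) * pa + h * pb)))


@dataclass
class HybridIndexEstimate:
    mean: float
    ci_low: float
    ci_high: float
    ess: float
    iterations: int
    burn_in: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.mean <= self.ci_high <= 1.0):
            raise AssertionError("credible interval must bracket the mean in [0,1]")


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    n = len(x)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real / (var * n)
    s = 0.0
    for t in range(1, n - 1, 2):
        pair = acf[t] + acf[t + 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


class HybridIndexModel:
    """Hybrid-index model over a genotype matrix and a reference panel.

    Statsmodels-style: construct from data, call :meth:`fit` for a
    :class:`HybridIndexResults`.
    """

    def __init__(self, genotypes: GenotypeMatrix, panel: ReferencePanel):
        if genotypes.loci != panel.loci:
            raise ValueError("genotypes and panel must share the locus list")
        self.genotypes = genotypes
        self.panel = panel
        self._compressed = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(genotypes.n_individuals):
                pa, pb = _copy_probs(genotypes.alleles[i], panel)
                if pa.size:
                    pairs, counts = np.unique(
                        np.column_stack([pa, pb]), axis=0, return_counts=True
                    )
                else:
                    pairs = np.empty((0, 2))
                    counts = np.empty(0)
                self._compressed.append((pairs[:, 0], pairs[:, 1], counts.astype(float)))
        self.n_informative = np.array([c[2].sum() for c in self._compressed]) / 2.0

    def loglik(self, h: float, individual: int = 0) -> float:
        pa, pb, cnt = self._compressed[individual]
        with np.errstate(divide="ignore"):
            return float(np.sum(cnt * np.log((1.0 - h) * pa + h * pb)))

    def fit(
        self,
        iterations: int = 50_000,
        burn_in: int = 10_000,
        seed: int | None = None,
        step: float = 0.05,
        ci_level: float = 0.95,
    ) -> "HybridIndexResults":
        """Sample the posterior for every individual (parallel chains)."""
        n = self.genotypes.n_individuals
        if n == 0:
            return HybridIndexResults(self, np.empty((iterations, 0), dtype=np.float32),
                                      iterations, burn_in, seed, ci_level, 0.0)
        if np.any(self.n_informative == 0):
            bad = [
                self.genotypes.individuals[i]
                for i in np.flatnonzero(self.n_informative == 0)
            ]
            raise ValueError(f"no informative loci for individuals: {bad}")
        gmax = max(c[0].size for c in self._compressed)
        PA = np.ones((n, gmax))
        PB = np.ones((n, gmax))
        CNT = np.zeros((n, gmax))
        for i, (pa, pb, cnt) in enumerate(self._compressed):
            PA[i, : pa.size] = pa
            PB[i, : pb.size] = pb
            CNT[i, : cnt.size] = cnt

        rng = np.random.default_rng(seed)

        def ll(h: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.log((1.0 - h)[:, None] * PA + h[:, None] * PB)
            v = np.where(CNT > 0, v, 0.0)
            return np.where(np.isnan(v), -np.inf, v * CNT).sum(axis=1)

        h = np.full(n, 0.5)
        cur = ll(h)
        total = burn_in + iterations
        samples = np.empty((iterations, n), dtype=np.float32)
        accepted = 0
        for t in range(total):
            prop = h + rng.normal(0.0, step, size=n)
            prop = np.abs(prop)
            prop = np.where(prop > 1.0, 2.0 - prop, prop)
            llp = ll(prop)
            acc = np.log(rng.random(n)) < llp - cur
            h = np.where(acc, prop, h)
            cur = np.where(acc, llp, cur)
            if t >= burn_in:
                samples[t - burn_in] = h
                accepted += int(acc.sum())
        acc_rate = accepted / max(1, iterations * n)
        return HybridIndexResults(self, samples, iterations, burn_in, seed, ci_level, acc_rate)


class HybridIndexResults:
    """Posterior summaries of the hybrid index per individual."""

    def __init__(self, model, samples, iterations, burn_in, seed, ci_level, acceptance_rate):
        self.model = model
        self.samples = samples
        self.iterations = iterations
        self.burn_in = burn_in
        self.seed = seed
        self.ci_level = ci_level
        self.acceptance_rate = acceptance_rate
        alpha = (1.0 - ci_level) / 2.0
        if samples.shape[1]:
            self.params = pd.Series(
                samples.mean(axis=0, dtype=np.float64),
                index=model.genotypes.individuals,
                name="hybrid_index",
            )
            self._ci = np.quantile(samples.astype(np.float64), [alpha, 1 - alpha], axis=0)
        else:
            self.params = pd.Series(dtype=float, name="hybrid_index")
            self._ci = np.empty((2, 0))

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ci_low": self._ci[0], "ci_high": self._ci[1]},
            index=self.params.index,
        )

    def ess(self) -> pd.Series:
        return pd.Series(
            [_ess(self.samples[:, i].astype(np.float64)) for i in range(self.samples.shape[1])],
            index=self.params.index,
            name="ess",
        )

    def estimate(self, individual: str | int = 0) -> HybridIndexEstimate:
        i = (
            individual
            if isinstance(individual, int)
            else self.params.index.get_loc(individual)
        )
        return HybridIndexEstimate(
            float(self.params.iloc[i]),
            float(self._ci[0, i]),
            float(self._ci[1, i]),
            _ess(self.samples[:, i].astype(np.float64)),
            self.iterations,
            self.burn_in,
            self.seed,
        )

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"hybrid_index": self.params})
        ci = self.conf_int()
        df["ci_low"] = ci["ci_low"]
        df["ci_high"] = ci["ci_high"]
        df["q_A"] = 1.0 - df["hybrid_index"]
        df["q_B"] = df["hybrid_index"]
        return df

    def plot(self, ax=None):
        """Point-and-interval plot of per-individual hybrid indices."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.25 * len(self.params)), 3))
        x = np.arange(len(self.params))
        ci = self.conf_int()
        ax.vlines(x, ci["ci_low"], ci["ci_high"], color="grey", lw=1)
        ax.plot(x, self.params.values, "o", ms=4)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("hybrid index (h)")
        ax.set_xticks(x)
        ax.set_xticklabels(self.params.index, rotation=90, fontsize=6)
        return ax


def hybrid_index_posterior(
    alleles_row: np.ndarray,
    panel: ReferencePanel,
    iterations: int = 50_000,
    burn_in: int = 10_000,
    seed: int | None = None,
    step: float = 0.05,
) -> HybridIndexEstimate:
    """Posterior hybrid index for a single individual."""
    geno = GenotypeMatrix(
        np.asarray(alleles_row)[None, :, :], ["ind0"], list(panel.loci)
    )
    res = HybridIndexModel(geno, panel).fit(iterations, burn_in, seed, step)
    return res.estimate(0)


def admixture_k2(
    genotypes: GenotypeMatrix,
    panel: ReferencePanel,
    iterations: int = 50_000,
    burn_in: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Supervised two-cluster admixture table (q_A, q_B per individual)."""
    if genotypes.n_individuals == 0:
        return pd.DataFrame(columns=["hybrid_index", "ci_low", "ci_high", "q_A", "q_B"])
    res = HybridIndexModel(genotypes, panel).fit(iterations, burn_in, seed)
    return res.summary()
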