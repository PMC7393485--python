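# Methods

## Scope and shape

radhyb re-implements, as a reusable and tested library, a hybrid-
detection workflow for two divergent species and their two-generation
hybrid classes: 3RAD read filtering, in silico locus prediction,
haplotype-locus coding, Bayesian hybrid-index estimation, six-class
hybrid-category assignment with diagnostic markers and mtDNA maternal
lineage, nest-level mother inference, and reproductive-output
statistics. The two statistical cores are exposed statsmodels-style —
`HybridIndexModel.fit() → HybridIndexResults` and
`HybridClassifier.fit() → HybridClassResults` — while the pipeline
stages are plain functions over explicit data containers. Read mapping
(external aligners), unsupervised clustering at K > 2, gametic phasing
and BLAST lookups are out of scope; the synthetic pipeline assigns reads
to loci by construction and mtDNA haplotypes are matched against a local
reference table.

## Hybrid-index model

The hybrid index h of an individual is the proportion of its allele
copies from species B. Parental allele-frequency vectors are estimated
from reference panels as

    p(a) = (count(a) + c) / (2 n_called + c K),

with pseudocount c = 0.5 by default over the K alleles observed in
either panel, so every panel-observed allele has positive frequency in
both species. Panels are then treated as fixed: parental-frequency
uncertainty is not propagated into the posterior. This is a documented
simplification relative to samplers that jointly update parental
frequencies; for strongly differentiated loci the pseudocount absorbs
panel sampling noise, and the effect on h is negligible at the locus
numbers used here. Loci uncalled in a panel are flagged and excluded;
alleles absent from both panels cause the locus to be skipped with a
warning.

Likelihood: each observed allele copy a at locus l contributes
(1 − h) p_A(l, a) + h p_B(l, a); copies and loci are independent; missing
genotypes are skipped. The prior on h is uniform. Sampling is a
random-walk Metropolis chain with Gaussian proposals (step 0.05,
tuned for acceptance rates above 20% on diagnostic-panel test cases)
reflected at the [0, 1] boundaries, no thinning, 10,000 burn-in and
50,000 kept iterations by default; chains for all individuals run as one
vectorised batch, with identical (p_A, p_B) copy pairs collapsed into
weighted groups so cost scales with the number of distinct frequency
pairs rather than loci. The reported interval is the equal-tailed 95%
quantile range; the effective sample size uses Geyer's initial positive
sequence estimator on the chain autocorrelation.

For fully diagnostic loci with pseudocount-free panels the posterior is
Beta(x + 1, 2n − x + 1) in the species-B copy count x; the test suite
compares the sampler against this closed form (tolerance 0.01) and
against the panel-swap symmetry h → 1 − h.

## Six-class genotype-frequency model

Classes {PURE_A, PURE_B, F1, F2, BX_A, BX_B} are characterised by their
distribution G_c over the per-locus ancestry pair z ∈ {AA, AB, BB}
(rows (1,0,0), (0,0,1), (0,1,0), (¼,½,¼), (½,½,0), (0,½,½)). Genotype
likelihood given z is Hardy–Weinberg under p_A (z = AA), under p_B
(z = BB), or one draw from each (z = AB). With fixed panel frequencies
the class posterior is exact, computed as a log-space product over loci
under a uniform class prior (configurable); missing and panel-invalid
loci are skipped, and an individual with no informative loci returns the
prior with a warning. An optional Gibbs mode re-draws every locus
frequency vector from its Dirichlet posterior and averages the per-draw
exact posteriors, as a parity check against samplers that integrate over
frequency uncertainty; it is thinned and exists only for comparison.

Locus capping (`max_loci`, the first loci in order) mirrors analyses
restricted to the first few hundred loci; `random_loci` draws the same
number at random as a consistency check.

The diagnostic decision table operates on genotype categories at
fixed-difference marker panels: all HOM_A → pure A; all HOM_B → pure B;
all HET → F1, with the maternal species read from the mtDNA haplotype
(the father is the other species); HET + HOM_A only → backcross to A
(symmetrically B); both homozygous classes present → F2-or-later;
all-missing → undetermined. Over all 3^6 six-marker patterns the table
agrees with the modal exact posterior (the F2-or-later label maps to the
F2 row, the closest model in the six-class family). The companion
power calculation is 0.5^k, the chance a first-generation backcross is
homospecific at all k unlinked diagnostic loci (1.56% at k = 6, 50% at
k = 1).

Mother inference from hatchlings: a pure hatchling implies a pure mother
of that species; a backcross or F2-or-later hatchling implies an F1
mother; an F1 hatchling implies a pure mother on its mtDNA side.
Conflicting implications are flagged inconsistent rather than resolved.

mtDNA assignment is nearest-reference by Hamming distance over the
aligned control-region window (query and references compared over their
common prefix; length mismatches beyond a 5 bp trim raise). Ties are
reported as ambiguous, never broken silently.

## 3RAD read-filter chain

Stage order: demultiplex → PCR-duplicate removal → pair merging →
cut-site check → quality trimming (unmerged pairs only) → internal-site
filter. Two ordering choices deserve note. First, the cut-site check
precedes quality trimming because the EcoRI-remnant anchor occupies the
low-quality reverse-read head that trimming clips off; checking after
the clip would be impossible. Second, quality trimming truncates to the
130 bp cap before removing the 6 bp reverse head, so an all-high-quality
150 bp pair yields 130/124 bp mates. Merged reads bypass per-mate
trimming: they are consensus-called from both mates and a 130 bp cap
would truncate legitimate 240–300 bp merged fragments.

Details per stage:

- **Demultiplexing** matches the forward-read prefix against the barcode
  map within `max_mismatch`; maps whose barcodes can collide at that
  radius are rejected up front. Barcodes are trimmed from assigned reads.
- **Duplicate removal** keys on (i5 tag, first 100 bp of each mate) and
  keeps the first occurrence — the keep-one-copy rule is deterministic
  even though any representative would be statistically equivalent.
  Reads shorter than the window contribute their full sequence.
- **Merging** takes the highest-scoring ungapped suffix/prefix overlap
  (score = matches − mismatches, mismatch fraction ≤ 0.1, ties to the
  longest overlap, consensus base from the higher-quality mate), merges
  at ≥ 30 bp overlap and drops merged reads < 240 bp as below the size
  selection. No overlap-significance test is attempted; the threshold
  pair stands in for it.
- **Cut-site check** keeps forward reads starting with the MseI remnant
  TAA, drops CviQI (TAC) starts and anything else, and requires the
  EcoRI remnant AATTC at the reverse-read start. Recognition sequences
  (EcoRI GAATTC, MseI TTAA, CviQI GTAC) and remnants are standard-enzyme
  defaults, all overridable.
- **Quality trimming** is a Trimmomatic-style sliding window: cut at the
  first base whose 4 bp trailing-window mean quality drops below Q30,
  cap at 130 bp, clip the 6 bp reverse head, drop pairs with a mate
  under 36 bp.
- **Internal-site filter** removes reads containing a complete
  recognition site strictly inside the insert; matches overlapping the
  expected terminal-remnant windows (TAA start, AATTC reverse start,
  reverse-complemented EcoRI remnant at the merged-read end) are the cut
  remnants themselves and do not count.

Every stage reports input/kept/dropped with per-reason counts, and
kept + dropped = input is asserted at construction.

## In silico digestion

Cut positions are the union over enzymes of forward-strand recognition
sites offset by the cut point (all three sites are palindromic or
strand-symmetric, so a forward scan is complete — verified by the
reverse-complement invariance test). Sites containing or adjacent to N
are not cut; fragments spanning N runs of ≥ 10 (assembly gaps) are
discarded. A qualifying locus has one EcoRI and one MseI end in either
orientation, no CviQI flank, and insert length inside the inclusive
350–450 bp window. Because a physical size selection acts on
adapter-ligated molecules, `adapter_offset` shifts the window by the
total adapter length; the default is 0 (insert-length convention), and
the choice should be stated alongside any genome-scale count. The
genome-scale prediction on a real assembly is supported but not part of
the test suite, which verifies predictions against planted fragments and
a quadratic brute-force scan on synthetic genomes.

## Haplotype coding

Per individual and locus, reads with undefined (N) bases are discarded;
a call requires ≥ readCOV (default 6) clean reads. The two most frequent
sequences form a heterozygote when the second count reaches
ceil(0.25 × total) — the 0.25 minor fraction is a standard RAD
genotyping heuristic, configurable, as the exact rule is rarely
published; ties rank lexicographically for determinism. Locus filters
are boundary-inclusive: a haplotype locus survives when called in
≥ intraCOV (0.7) of individuals within ≥ popCOV (3) populations, and the
SNP-level presence filter analogously at 40% within all 3 populations.
Surviving haplotypes are coded as dense per-locus integers (missing −9)
and written in the two-rows-per-individual clustering format;
heterozygosity is preserved exactly under the coding.

## Nest statistics

live = eggshells − dead (floored at zero with a warning), CS =
unhatched + dead + live, HS = 100·live/CS (undefined and flagged at
CS = 0), IP = whole days between the recorded oviposition and emergence
dates. Group comparisons use the Mann–Whitney U from midranks; the
two-sided exact p doubles the smaller enumerated tail (capped at 1) when
n1 + n2 ≤ 12 without ties, otherwise a normal approximation with tie
correction and a 0.5 continuity correction. The in-package
implementation is cross-checked against scipy's to 10⁻⁶ in the tests.
Summaries report sample SDs (n − 1), flagged undefined for single-nest
groups. The per-female arithmetic divides identified nests by distinct
female ids (one decimal), and the season female count divides nesting
events per season by the per-female clutch frequency (default 4),
rounding half up.

## Synthetic-data generator

The generator defines the study conditions and is first-class, tested
code. One global seed expands into fixed named streams (panels, crosses,
genome, reads, nests, mtDNA), so composite runs are reproducible as a
whole and per part.

- **Panels and crosses.** The leading `n_diagnostic` loci are fixed for
  different alleles (allele 0 species-A-typical); each remaining locus
  is fixed-different with probability `divergence` (default 0.2) and
  otherwise shares a Dirichlet-drawn frequency vector between species,
  i.e. is undifferentiated. Panel genotypes are Hardy–Weinberg draws,
  five individuals per species by default, matching the reference-panel
  size a field study of this kind can realistically obtain. Crosses
  sample gametes with unlinked loci: an F1 gamete picks its species of
  origin per locus with probability ½, which generates the ½-per-locus
  homospecificity of backcrosses that the 0.5^k power argument relies
  on. Pedigree truth records expected and realized hybrid indices.
- **Genome and reads.** The genome is a single scrubbed background (all
  spontaneous recognition sites destroyed) with EcoRI–MseI fragments
  planted at known coordinates: in-window qualifying fragments,
  wrong-size decoys and CviQI-flanked decoys, separated by pads short
  enough that no between-plant fragment can qualify. The read set is
  generated per category — in-window pairs (too long to overlap),
  mergeable 240–263 bp inserts, sub-240 bp fragments, CviQI and siteless
  starts, incomplete-digestion inserts carrying an internal site within
  read reach, low-quality reverse mates, corrupted barcodes (kept ≥ 2
  mismatches from every true barcode) — plus PCR duplicates at the
  configured rate (default 0.1) sharing the i5 tag and sequences of
  their template. i5 tags are unique within a (sample, fragment) group
  so the duplicate truth is exact. The sequenced insert is two bases
  longer than the corresponding digestion fragment (the sticky-end
  overhang counted from both strands); the size window refers to the
  fragment. Base qualities are uniform Phred+33 Q38; the generator does
  not model position-dependent error, indels, chimeras or coverage
  heterogeneity, so passing read-chain tests demonstrates rule
  correctness, not robustness to real error profiles.
- **Nests.** Clutch size is a rounded normal draw (≥ 1), hatched eggs
  binomial at the group hatch probability, and 3% of hatched individuals
  are found dead at excavation so the excavation counts reconstruct the
  clutch exactly. Default group parameters are the reported loggerhead
  vs hybrid means (hatch 56.8% vs 27%, clutch 113.7 ± 24.8 vs
  137 ± 20.06, incubation 52.6 ± 3.5 vs 55 ± 3.06 days; 31 vs 16 nests).
  Between-nest overdispersion of hatch probability is not modelled, so
  synthetic HS spreads are narrower than field data; detection power
  computed on synthetic nests is accordingly an upper bound.
- **mtDNA.** Named haplotype references (loggerhead-style CC-*,
  hawksbill-style Ei-*) are a shared random backbone with ≥ 20 private
  substitutions each, keeping nearest-haplotype assignment unambiguous;
  sampled sequences add a configurable number of mutations.

## Numerical choices and degenerate inputs

Genotypes are unordered integer pairs with −9 as missing; allele 0 is
species-A-typical at diagnostic loci. Log-space products are used
everywhere probabilities multiply; zero probabilities are admitted
(−inf log-likelihood) and resolved by normalisation or rejection rather
than by flooring. Empty inputs return empty outputs where meaningful
(empty genotype matrix → empty table, empty sequence → no fragments) and
raise where silence would hide an error (empty groups in the U test,
zero informative loci in the hybrid-index fit, empty populations in the
coverage filter). MCMC posterior draws are stored as float32 to bound
memory at cohort scale.

Problem sizes in the test suite (300 loci, 100 individuals per class,
10,000 read pairs, 1,000 nest replicates) are the scales at which the
targeted contrasts are decisively resolved on synthetic data; the
vectorised samplers run the full default iteration counts at these
sizes.

## Known limitations

- Parental frequencies are fixed at their pseudocounted estimates; with
  very small panels and weakly differentiated loci this understates
  posterior width, and at fixed-difference loci the pseudocount makes
  doubly-discordant F2 patterns attributable to backcrosses. Use
  pseudocount 0 when frequencies are genuinely known.
- Loci are treated as unlinked throughout; linked RAD loci would make
  the 0.5^k power argument and the class posteriors anticonservative.
- The read merger has no overlap-significance model; random-overlap
  false merges are limited only by the 30 bp / 10% mismatch thresholds.
- F2-or-later diagnostic patterns are reported as a single category; the
  six-class model cannot separate later-generation hybrids, and deeper
  backcross generations are absent from both the generator and model.
- The digestion module ignores methylation sensitivity and partial
  digestion; the genome-scale locus count depends on the adapter-offset
  convention, which must be chosen explicitly.
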