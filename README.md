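# radhyb

Detection and classification of interspecific hybrids from reduced-
representation sequencing data, built around the study design used for
nesting sea turtles: loggerhead (*Caretta caretta*) × hawksbill
(*Eretmochelys imbricata*) hybridization detected from three-enzyme RAD
(3RAD) libraries, a small panel of species-diagnostic nuclear markers,
and mtDNA control-region haplotypes, together with the reproductive-
output statistics used to compare hybrid and pure nests.

The package is aimed at molecular ecologists who need a tested,
end-to-end reference implementation of this analysis: every pipeline
stage is exercised against a synthetic-data generator with known ground
truth, so each filter, estimator and decision rule can be verified
before being pointed at real data.

## What it computes

**Hybrid index.** For an individual with genotypes at loci *l* and
parental allele-frequency vectors *p_A(l,·)*, *p_B(l,·)* estimated from
reference panels, the hybrid index *h* ∈ [0, 1] is the proportion of
allele copies descending from species B. Each observed allele copy *a*
contributes likelihood

    (1 − h) · p_A(l, a) + h · p_B(l, a)

and the posterior under a uniform prior is sampled with a reflected
random-walk Metropolis chain (50,000 kept iterations after 10,000
burn-in by default). At fully diagnostic loci the posterior is
Beta(n_B + 1, n_A + 1) in closed form, which the tests use as an
independent oracle. *h* = 0 denotes pure species A, *h* = 1 pure
species B.

**Six-class assignment.** Hybrid categories {pure A, pure B, F1, F2,
backcross-to-A, backcross-to-B} are distinguished by their distribution
G_c over the per-locus ancestry pair *z* ∈ {AA, AB, BB}:

| class  | AA  | AB  | BB  |
|--------|-----|-----|-----|
| pure A | 1   | 0   | 0   |
| pure B | 0   | 0   | 1   |
| F1     | 0   | 1   | 0   |
| F2     | ¼   | ½   | ¼   |
| BX_A   | ½   | ½   | 0   |
| BX_B   | 0   | ½   | ½   |

With P(genotype | z) given by Hardy–Weinberg draws from the parental
frequencies, the class posterior is exact (a log-space product over
loci). A first-generation backcross is homospecific at any one
diagnostic locus with probability ½, so a panel of *k* independent
diagnostic markers misses it with probability 0.5^k — 1.56% at the
six-marker panel.

**3RAD read processing.** The bespoke filter chain: in-line barcode
demultiplexing, PCR-duplicate removal keyed on the random i5 tag plus
the first 100 bp of each mate, overlap merging (≥ 30 bp) with removal of
merged reads under 240 bp, restriction-site checking (keep MseI-cut
fragments, drop CviQI-cut ones, anchor the reverse read on the EcoRI
remnant), sliding-window quality trimming (Q > 30, 130 bp cap, 6 bp
reverse-head clip) and removal of reads with complete internal
restriction sites — each stage with conserving drop counts.

**Locus prediction, haplotype coding, nests.** In silico EcoRI/MseI/
CviQI digestion with a 350–450 bp size window; haplotype calling with
readCOV/popCOV/intraCOV coverage filters and dense multi-allelic integer
coding; clutch size, hatching success and incubation period per nest
with exact/asymptotic Mann–Whitney U group comparisons.

## Worked example

```python
from radhyb.synth import SimConfig, make_reference_panels, simulate_cross
from radhyb.ancestry import estimate_allele_freqs, HybridIndexModel
from radhyb.classify import HybridClassifier, backcross_error_rate

cfg = SimConfig(n_loci=300, n_diagnostic=300, seed=42)
panels = make_reference_panels(cfg)
ref = estimate_allele_freqs(panels.panel_a, panels.panel_b)

geno, ped = simulate_cross(panels, "BX_A", 3, seed=43)
res = HybridIndexModel(geno, ref).fit(iterations=50_000, burn_in=10_000, seed=44)
print(res.summary().round(3))

cls = HybridClassifier(geno, ref, max_loci=300).fit()
print(cls.summary().round(4))
print(f"backcross misassignment at 6 markers: {100*backcross_error_rate(6):.2f}%")
```

prints

```
        hybrid_index  ci_low  ci_high    q_A    q_B
BX_A_1         0.231   0.194    0.270  0.769  0.231
BX_A_2         0.224   0.187    0.264  0.776  0.224
BX_A_3         0.237   0.198    0.276  0.763  0.237
        PURE_A  PURE_B   F1   F2  BX_A  BX_B modal_class  modal_prob
BX_A_1     0.0     0.0  0.0  0.0   1.0   0.0        BX_A         1.0
BX_A_2     0.0     0.0  0.0  0.0   1.0   0.0        BX_A         1.0
BX_A_3     0.0     0.0  0.0  0.0   1.0   0.0        BX_A         1.0
backcross misassignment at 6 markers: 1.56%
```

Three simulated first-generation backcrosses to species A sit near the
expected hybrid index of 0.25 (credible intervals excluding both 0 and
0.5), and the six-class posterior identifies all three as backcrosses
with support that rounds to 100%.

The same operations are available from the shell:

```
radhyb simulate --seed 2 --out sim/
radhyb filter-reads --in sim/reads_R1.fastq sim/reads_R2.fastq \
    --barcodes barcodes.tsv --report report.tsv --out filtered/
radhyb digest --genome sim/genome.fasta --min 350 --max 450
radhyb hybrid-index --geno sim/cohort.tsv --panel-a sim/panel_A.tsv --panel-b sim/panel_B.tsv
radhyb classify --geno sim/cohort.tsv --panel-a sim/panel_A.tsv --panel-b sim/panel_B.tsv
radhyb nests --records sim/nests.csv
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its limits, numerical choices and known limitations.
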