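"""Six-class posteriors, diagnostic decision table, mtDNA and nest rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radhyb import hybrid_classes as hc
from radhyb.classify import (
    F2_OR_LATER,
    HET,
    HOM_A,
    HOM_B,
    MISSING_CALL,
    UNDETERMINED,
    DiagnosticCall,
    HybridClassifier,
    assign_mtdna,
    backcross_error_rate,
    categorize_diagnostic,
    class_posterior,
    classify_nest,
    diagnostic_assignment,
    genotype_prob_given_class,
)
from radhyb.genotypes import MISSING, GenotypeMatrix
from radhyb.synth import make_mtdna_references, sample_mtdna, simulate_cross

HOM_A_PAIR, HET_PAIR, HOM_B_PAIR = (0, 0), (0, 1), (1, 1)


class TestGenotypeProb:
    def test_f1_heterozygous_certain(self, diag_ref):
        assert genotype_prob_given_class(HET_PAIR, 0, hc.F1, diag_ref) == pytest.approx(1.0)

    def test_f2_heterozygous_half(self, diag_ref):
        assert genotype_prob_given_class(HET_PAIR, 0, hc.F2, diag_ref) == pytest.approx(0.5)

    def test_backcross_half_half_zero(self, diag_ref):
        assert genotype_prob_given_class(HOM_A_PAIR, 0, hc.BX_A, diag_ref) == pytest.approx(0.5)
        assert genotype_prob_given_class(HET_PAIR, 0, hc.BX_A, diag_ref) == pytest.approx(0.5)
        assert genotype_prob_given_class(HOM_B_PAIR, 0, hc.BX_A, diag_ref) == pytest.approx(0.0)

    def test_unknown_class_rejected(self, diag_ref):
        with pytest.raises(ValueError):
            genotype_prob_given_class(HET_PAIR, 0, "F9", diag_ref)

    def test_probabilities_sum_over_genotypes(self, big_ref):
        # at any locus the three genotype categories exhaust the
        # biallelic outcomes, so probabilities sum to 1 per class
        for cls in hc.CLASSES:
            total = sum(
                genotype_prob_given_class(g, 0, cls, big_ref)
                for g in (HOM_A_PAIR, HET_PAIR, HOM_B_PAIR)
            )
            assert total == pytest.approx(1.0)


class TestClassPosterior:
    def test_single_het_locus_hand_computed(self, diag_ref):
        # P(HET | class) over classes = (0, 0, 1, 1/2, 1/2, 1/2);
        # uniform prior -> posterior (0, 0, 0.4, 0.2, 0.2, 0.2)
        row = np.array([HET_PAIR] + [(MISSING, MISSING)] * 5)
        post = class_posterior(row, diag_ref)
        np.testing.assert_allclose(
            post.values, [0, 0, 0.4, 0.2, 0.2, 0.2], atol=1e-12
        )

    def test_all_missing_returns_prior(self, diag_ref):
        row = np.full((6, 2), MISSING)
        with pytest.warns(UserWarning):
            post = class_posterior(row, diag_ref)
        np.testing.assert_allclose(post.values, np.full(6, 1 / 6))

    def test_matches_brute_force_enumeration(self, diag_ref):
        # independent oracle: direct product over loci of
        # sum_z G_c(z) P(g|z) with fixed 0/1 panel frequencies
        G = {c: hc.ANCESTRY_PROPORTIONS[c] for c in hc.CLASSES}
        p_given_z = {  # (genotype, z) -> prob at a fixed-difference locus
            (HOM_A_PAIR, "AA"): 1.0, (HET_PAIR, "AA"): 0.0, (HOM_B_PAIR, "AA"): 0.0,
            (HOM_A_PAIR, "AB"): 0.0, (HET_PAIR, "AB"): 1.0, (HOM_B_PAIR, "AB"): 0.0,
            (HOM_A_PAIR, "BB"): 0.0, (HET_PAIR, "BB"): 0.0, (HOM_B_PAIR, "BB"): 1.0,
        }
        rng = np.random.default_rng(2)
        genotypes = [HOM_A_PAIR, HET_PAIR, HOM_B_PAIR]
        for _ in range(20):
            row = [genotypes[i] for i in rng.integers(0, 3, size=6)]
            post = class_posterior(np.array(row), diag_ref)
            lik = np.array(
                [
                    np.prod(
                        [
                            sum(G[c][k] * p_given_z[(g, z)] for k, z in enumerate(("AA", "AB", "BB")))
                            for g in row
                        ]
                    )
                    for c in hc.CLASSES
                ]
            )
            if lik.sum() == 0:
                continue
            np.testing.assert_allclose(post.values, lik / lik.sum(), atol=1e-12)

    def test_rows_sum_to_one_and_uninformative_locus_is_neutral(self, diag_ref):
        from radhyb.ancestry import ReferencePanel

        # append a locus with identical frequencies in both species
        ref = ReferencePanel(
            list(diag_ref.loci) + ["Lx"],
            list(diag_ref.alleles) + [np.array([0, 1])],
            list(diag_ref.freqs_a) + [np.array([0.6, 0.4])],
            list(diag_ref.freqs_b) + [np.array([0.6, 0.4])],
            np.append(diag_ref.n_called_a, 5),
            np.append(diag_ref.n_called_b, 5),
            diag_ref.pseudocount,
        )
        row6 = np.array([HET_PAIR] * 6 + [(MISSING, MISSING)])
        row7 = np.array([HET_PAIR] * 6 + [HET_PAIR])
        p6 = class_posterior(row6, ref)
        p7 = class_posterior(row7, ref)
        assert p6.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p6.values, p7.values, atol=1e-9)

    def test_simulation_recovery_20_diagnostic_loci(self):
        from radhyb.ancestry import estimate_allele_freqs
        from radhyb.synth import SimConfig, make_reference_panels, simulate_cohort

        # at fixed-difference loci the parental frequencies are known
        # exactly, so the reference is pseudocount-free; a pseudocounted
        # panel admits backcross explanations for doubly-discordant F2
        # patterns and deliberately trades accuracy for robustness
        cfg = SimConfig(n_loci=20, n_diagnostic=20, n_per_class=100, seed=313)
        panels = make_reference_panels(cfg)
        ref = estimate_allele_freqs(panels.panel_a, panels.panel_b, pseudocount=0.0)
        cohort, ped = simulate_cohort(panels, cfg)
        res = HybridClassifier(cohort, ref).fit()
        modal = res.modal_class
        correct = (modal.values == np.array(ped.class_labels)).mean()
        assert correct >= 0.99

    def test_gibbs_mode_agrees_with_exact_on_diagnostic_panels(self, diag_panels, diag_ref):
        geno, _ = simulate_cross(diag_panels, hc.BX_A, 3, 55)
        exact = HybridClassifier(geno, diag_ref).fit(method="exact")
        gibbs = HybridClassifier(geno, diag_ref).fit(
            method="gibbs", iterations=2_000, burn_in=400, seed=1
        )
        # frequency resampling from fixed panels barely moves the posterior
        np.testing.assert_allclose(
            exact.posterior.values, gibbs.posterior.values, atol=0.05
        )


class TestDiagnosticRules:
    def test_error_rate_six_markers(self):
        assert backcross_error_rate(6) == 0.015625
        assert round(100 * backcross_error_rate(6), 2) == 1.56
        assert backcross_error_rate(1) == 0.5
        assert backcross_error_rate(0) == 1.0
        with pytest.raises(ValueError):
            backcross_error_rate(-1)

    def test_decision_table(self):
        f1 = diagnostic_assignment([HET] * 6, mtdna_species="A", mtdna_haplotype="CC-A4.1")
        assert f1.label == hc.F1 and f1.maternal_species == "A"
        assert f1.n_informative == 6
        assert diagnostic_assignment([HET] * 3 + [HOM_A] * 3).label == hc.BX_A
        assert diagnostic_assignment([HET] * 3 + [HOM_B] * 3).label == hc.BX_B
        assert diagnostic_assignment([HOM_A] * 6).label == hc.PURE_A
        assert diagnostic_assignment([HOM_B] * 6).label == hc.PURE_B
        assert diagnostic_assignment([HOM_A, HOM_B] + [HET] * 4).label == F2_OR_LATER
        assert diagnostic_assignment([MISSING_CALL] * 6).label == UNDETERMINED

    def test_agrees_with_modal_posterior_exhaustively(self, diag_ref):
        # all 3^6 diagnostic patterns: where the rule yields a definite
        # class, it must be the modal class of the exact posterior
        pair_of = {HOM_A: HOM_A_PAIR, HET: HET_PAIR, HOM_B: HOM_B_PAIR}
        for pattern in itertools.product((HOM_A, HET, HOM_B), repeat=6):
            call = diagnostic_assignment(list(pattern))
            post = class_posterior(
                np.array([pair_of[c] for c in pattern]), diag_ref
            )
            modal = post.idxmax()
            if call.label in hc.CLASSES:
                assert modal == call.label, pattern
            else:  # F2-or-later patterns: F2 is the only admissible class
                assert call.label == F2_OR_LATER
                assert modal == hc.F2, pattern

    def test_categorize_diagnostic_convention(self, diag_panels):
        geno, _ = simulate_cross(diag_panels, hc.F1, 2, 9)
        cats = categorize_diagnostic(geno)
        assert (cats.values == HET).all()


class TestNestAndMtdna:
    def test_mother_inference_rules(self):
        pure = DiagnosticCall(hc.PURE_A)
        bx = DiagnosticCall(hc.BX_A)
        f1 = DiagnosticCall(hc.F1, maternal_species="A")
        assert classify_nest([pure]).mother == hc.PURE_A
        assert classify_nest([bx]).mother == "F1_HYBRID"
        assert classify_nest([f1]).mother == hc.PURE_A
        conflict = classify_nest([pure, bx])
        assert not conflict.consistent
        assert classify_nest([]).mother == UNDETERMINED

    def test_mtdna_exact_and_near_match(self, rng):
        refs = make_mtdna_references(7)
        exact = sample_mtdna(refs, "CC-A4.1", 0, rng)
        hit = assign_mtdna(exact, refs)
        assert hit.haplotype == "CC-A4.1" and hit.distance == 0
        assert hit.species == "A"
        near = sample_mtdna(refs, "Ei-A01", 1, rng)
        hit2 = assign_mtdna(near, refs)
        assert hit2.haplotype == "Ei-A01" and hit2.distance == 1

    def test_mtdna_tie_is_ambiguous(self):
        refs = pd.DataFrame(
            [
                {"haplotype": "H1", "species": "A", "sequence": "AAAA"},
                {"haplotype": "H2", "species": "B", "sequence": "TTTT"},
            ]
        )
        hit = assign_mtdna("AATT", refs)
        assert hit.ambiguous and set(hit.candidates) == {"H1", "H2"}

    def test_mtdna_length_mismatch_rejected(self):
        refs = pd.DataFrame(
            [{"haplotype": "H1", "species": "A", "sequence": "A" * 100}]
        )
        with pytest.raises(ValueError):
            assign_mtdna("A" * 50, refs)

    def test_f1_maternal_side_resolves_cross_direction(self, rng):
        # all-heterozygous nuclear profile plus species-A mtDNA: an F1
        # with species-A mother and species-B father
        refs = make_mtdna_references(8)
        seq = sample_mtdna(refs, "CC-A4.1", 0, rng)
        mt = assign_mtdna(seq, refs)
        call = diagnostic_assignment([HET] * 6, mt.species, mt.haplotype)
        assert call.label == hc.F1 and call.maternal_species == "A"
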