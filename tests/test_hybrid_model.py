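"""Hybrid-class model: phi table, genotype frequencies, classifier, power."""

from __future__ import annotations

import numpy as np
import pytest

from gtpanel.baseline import from_biallelic_arrays
from gtpanel.hybrid_model import (
    CLASSES,
    accuracy_vs_missing,
    class_phi_table,
    classify,
    curate_baseline,
    expected_genotype_probs,
    inject_missing,
    power_analysis,
    simulate_all_classes,
    simulate_class,
)
from gtpanel.io_formats import from_dosage
from gtpanel.synthetic_data import make_species_panel

from oracles import hybrid_posterior_oracle, phi_by_pedigree_enumeration


def _fixed_diff(n_loci=100):
    return from_biallelic_arrays(np.zeros(n_loci), np.ones(n_loci))


class TestPhiTable:
    def test_matches_pedigree_enumeration(self):
        model = class_phi_table()
        oracle = phi_by_pedigree_enumeration()
        for cls, row in zip(model.classes, model.phi):
            assert tuple(row) == pytest.approx(oracle[cls], abs=0)

    def test_named_rows(self):
        model = class_phi_table()
        phi = dict(zip(model.classes, map(tuple, model.phi)))
        assert phi["PureA"] == (1, 0, 0)
        assert phi["F2"] == (0.25, 0.5, 0.25)
        assert phi["BxA"] == (0.5, 0.5, 0)

    def test_uniform_prior(self):
        model = class_phi_table()
        assert model.prior == pytest.approx(np.full(6, 1 / 6))


class TestExpectedGenotypeProbs:
    def test_fixed_difference_f1_is_heterozygous(self):
        probs = expected_genotype_probs("F1", {1: 1.0}, {2: 1.0})
        assert probs[(1, 2)] == pytest.approx(1.0)

    def test_fixed_difference_f2_quarters(self):
        probs = expected_genotype_probs("F2", {1: 1.0}, {2: 1.0})
        assert probs[(1, 1)] == pytest.approx(0.25)
        assert probs[(1, 2)] == pytest.approx(0.5)
        assert probs[(2, 2)] == pytest.approx(0.25)

    def test_normalisation_over_random_frequencies(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            w = rng.dirichlet(np.ones(3))
            pa = dict(zip((1, 2, 3), rng.dirichlet(np.ones(3))))
            pb = dict(zip((1, 2, 3), rng.dirichlet(np.ones(3))))
            cls = CLASSES[rng.integers(6)]
            probs = expected_genotype_probs(cls, pa, pb)
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_bad_frequencies_rejected(self):
        from gtpanel.io_formats import PanelValidationError

        with pytest.raises(PanelValidationError):
            expected_genotype_probs("F1", {1: 0.7}, {2: 1.0})


class TestSimulateClass:
    def test_f1_fully_heterozygous_at_fixed_loci(self):
        gm = simulate_class(_fixed_diff(), "F1", n=20, seed=1)
        dos = gm.dosage(alt_allele=np.full(100, 2))
        assert (dos == 1).all()

    def test_bxa_never_homozygous_for_b(self):
        gm = simulate_class(_fixed_diff(), "BxA", n=50, seed=2)
        dos = gm.dosage(alt_allele=np.full(100, 2))
        assert (dos != 2).all()

    def test_f2_segregation_ratios(self):
        gm = simulate_class(_fixed_diff(1), "F2", n=10_000, seed=3)
        dos = gm.dosage(alt_allele=np.array([2]))[:, 0]
        props = np.bincount(dos, minlength=3) / 10_000
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 10_000)
        assert np.all(np.abs(props - (0.25, 0.5, 0.25)) < 3 * se)

    def test_seeded_determinism(self):
        bf, _ = make_species_panel(20, 0, seed=5)
        a = simulate_class(bf, "F2", n=10, seed=9)
        b = simulate_class(bf, "F2", n=10, seed=9)
        assert np.array_equal(a.calls, b.calls)


class TestClassify:
    def test_all_het_sample_is_f1(self):
        bf = _fixed_diff(100)
        gm = from_dosage(np.full((1, 100), 1), locus_ids=bf.locus_ids)
        rec = classify(gm, bf)[0]
        assert rec.assigned_class == "F1"
        assert rec.posterior[list(CLASSES).index("F1")] > 0.999

    def test_all_reference_homozygous_is_pure_a(self):
        bf = _fixed_diff(100)
        gm = from_dosage(np.zeros((1, 100), dtype=int), locus_ids=bf.locus_ids)
        rec = classify(gm, bf)[0]
        assert rec.assigned_class == "PureA"
        assert rec.max_posterior > 0.999

    def test_zero_called_loci_is_unclassified(self):
        bf = _fixed_diff(10)
        gm = from_dosage(np.full((1, 10), -1), locus_ids=bf.locus_ids)
        rec = classify(gm, bf)[0]
        assert rec.assigned_class is None and rec.posterior is None
        assert rec.n_loci_used == 0

    def test_matches_bruteforce_mixture_likelihood(self):
        """1-3 locus posteriors equal the enumeration oracle to 1e-12."""
        rng = np.random.default_rng(8)
        for n_loci in (1, 2, 3):
            pa = rng.uniform(0.05, 0.95, n_loci)
            pb = rng.uniform(0.05, 0.95, n_loci)
            bf = from_biallelic_arrays(pa, pb)
            for _ in range(5):
                dos = rng.integers(-1, 3, size=(1, n_loci))
                if (dos >= 0).sum() == 0:
                    continue
                gm = from_dosage(dos, locus_ids=bf.locus_ids)
                rec = classify(gm, bf)[0]
                oracle = hybrid_posterior_oracle(list(dos[0]), list(pa), list(pb))
                assert rec.posterior == pytest.approx(oracle, abs=1e-12)

    def test_population_swap_symmetry(self):
        rng = np.random.default_rng(10)
        pa, pb = rng.uniform(0.1, 0.9, 30), rng.uniform(0.1, 0.9, 30)
        bf = from_biallelic_arrays(pa, pb)
        # swapping populations means allele frequencies swap; genotype dosage
        # is unchanged (it counts allele 2 regardless of population)
        bf_swapped = from_biallelic_arrays(pb, pa)
        dos = rng.integers(0, 3, size=(6, 30))
        gm = from_dosage(dos, locus_ids=bf.locus_ids)
        rec = classify(gm, bf)
        rec_s = classify(gm, bf_swapped)
        perm = [1, 0, 2, 3, 5, 4]  # PureA<->PureB, BxA<->BxB
        for r, rs in zip(rec, rec_s):
            assert rs.posterior == pytest.approx(r.posterior[perm], abs=1e-12)

    def test_posterior_normalised(self):
        bf, _ = make_species_panel(40, 0, seed=6)
        gm, _ = simulate_all_classes(bf, 5, seed=7)
        for rec in classify(gm, bf):
            assert rec.posterior.sum() == pytest.approx(1.0, abs=1e-9)


class TestInjectMissing:
    def test_zero_rate_is_identity(self):
        bf, _ = make_species_panel(10, 0, seed=1)
        gm = simulate_class(bf, "F1", n=5, seed=1)
        assert inject_missing(gm, 0.0, seed=2).equals(gm)

    def test_full_rate_blanks_everything(self):
        bf, _ = make_species_panel(10, 0, seed=1)
        gm = simulate_class(bf, "F1", n=5, seed=1)
        assert inject_missing(gm, 1.0, seed=2).missing_mask().all()

    def test_realised_rate_near_nominal(self):
        gm = from_dosage(np.zeros((100, 100), dtype=int))
        out = inject_missing(gm, 0.3, seed=3)
        assert 0.28 <= out.missing_mask().mean() <= 0.32


class TestPower:
    def test_strong_panel_perfect_at_half_threshold(self, strong_panel):
        df = power_analysis(strong_panel, n_per_class=10, replicates=1,
                            thresholds=[0.5], seed=20)
        assert (df["accuracy"] == 1.0).all()

    def test_weak_panel_backcrosses_harder_than_pures(self):
        rng = np.random.default_rng(30)
        pa = rng.uniform(0.3, 0.45, 25)
        bf = from_biallelic_arrays(pa, pa + 0.25)
        df = power_analysis(bf, n_per_class=40, replicates=2, thresholds=[0.5], seed=31)
        mean_acc = df.groupby("class")["accuracy"].mean()
        pure = (mean_acc["PureA"] + mean_acc["PureB"]) / 2
        back = (mean_acc["BxA"] + mean_acc["BxB"]) / 2
        assert back < pure

    def test_accuracy_monotone_in_threshold(self, strong_panel):
        df = power_analysis(strong_panel, n_per_class=8, replicates=1,
                            thresholds=[0.5, 0.9, 1.0], seed=22)
        for cls in CLASSES:
            accs = df[df["class"] == cls].sort_values("threshold")["accuracy"].values
            assert (np.diff(accs) <= 1e-12).all()


class TestAccuracyVsMissing:
    def test_zero_missing_consistent_with_power(self, strong_panel):
        amv = accuracy_vs_missing(strong_panel, missing_grid=[0.0], threshold=0.9,
                                  n_per_class=10, seed=40)
        pw = power_analysis(strong_panel, n_per_class=10, replicates=1,
                            thresholds=[0.9], seed=40)
        for cls in CLASSES:
            a = amv[amv["class"] == cls]["accuracy"].iloc[0]
            b = pw[pw["class"] == cls]["accuracy"].iloc[0]
            assert a == pytest.approx(b)

    def test_accuracy_does_not_increase_with_missingness(self, strong_panel):
        amv = accuracy_vs_missing(strong_panel, missing_grid=[0.0, 0.3, 0.6, 0.9],
                                  threshold=0.9, n_per_class=20, seed=41)
        tol = 3 * np.sqrt(0.25 / 20)  # 3 SE at n=20 per class
        for cls in CLASSES:
            accs = amv[amv["class"] == cls].sort_values("missing")["accuracy"].values
            assert (np.diff(accs) <= tol).all()


def test_curate_baseline_drops_contaminant():
    bf, _ = make_species_panel(60, 0, seed=50, s_min_delta=0.8)
    pure_a = simulate_class(bf, "PureA", n=20, seed=51, prefix="a")
    pure_b = simulate_class(bf, "PureB", n=20, seed=52, prefix="b")
    f1 = simulate_class(bf, "F1", n=1, seed=53, prefix="hyb")
    calls = np.concatenate([pure_a.calls, pure_b.calls, f1.calls])
    ids = pure_a.sample_ids + pure_b.sample_ids + f1.sample_ids
    from gtpanel.io_formats import GenotypeMatrix

    gm = GenotypeMatrix(ids, list(bf.locus_ids), calls)
    z = {s: "A" for s in pure_a.sample_ids} | {s: "B" for s in pure_b.sample_ids}
    retained, excluded, recs = curate_baseline(gm, z, min_posterior=0.99)
    # the F1 contaminant classifies as F1, not pure, with high confidence,
    # and the curation keeps only confidently classified samples
    rec = {r.sample_id: r for r in recs}["hyb_0000"]
    assert rec.assigned_class == "F1"
    assert set(retained) >= set(pure_a.sample_ids + pure_b.sample_ids)
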