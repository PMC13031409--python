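"""Read counting, ratio-window calling and primer metrics."""

from __future__ import annotations

import numpy as np
import pytest

from gtpanel.amplicon_genotyper import (
    LocusCounts,
    RatioWindows,
    call_genotype,
    call_genotype_matrix,
    count_locus_reads,
    counts_to_arrays,
    flag_ratio_anomalies,
    primer_metrics,
)
from gtpanel.io_formats import PanelValidationError, ProbeRecord
from gtpanel.synthetic_data import (
    BaselineSpec,
    ReadSimSpec,
    make_probe_set,
    simulate_baseline_pair,
    simulate_read_counts,
    write_sample_fastq,
)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            (30, 0, "hom1"),  # r = inf
            (0, 30, "hom2"),
            (5, 4, "missing"),  # depth 9 below the 10x minimum
            (12, 10, "het"),  # r = 1.2 inside [0.2, 5]
            (6, 1, "missing"),  # depth 7: below minimum despite clear ratio
            (60, 10, "missing"),  # depth fine but r = 6 is ambiguous
            (100, 9, "hom1"),  # r > 10
            (100, 11, "missing"),  # r ~ 9.1: ambiguous zone
            (2, 19, "missing"),  # r ~ 0.105: ambiguous on the low side
            (2, 20, "hom2"),  # r = 0.1 boundary
        ],
    )
    def test_ratio_window_semantics(self, c1, c2, expected):
        assert call_genotype(c1, c2).call == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(PanelValidationError):
            call_genotype(-1, 5)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        c1 = rng.integers(0, 60, size=(40, 15))
        c2 = rng.integers(0, 60, size=(40, 15))
        gm = call_genotype_matrix(c1, c2)
        dos = gm.dosage(alt_allele=np.full(15, 2))
        mapping = {"hom1": 0, "het": 1, "hom2": 2, "missing": -1}
        for i in range(40):
            for j in range(15):
                assert dos[i, j] == mapping[call_genotype(int(c1[i, j]), int(c2[i, j])).call]


class TestCounting:
    @pytest.fixture()
    def small_panel(self, tmp_path):
        bf, gm = simulate_baseline_pair(BaselineSpec(n_loci=8, n_samples_per_pop=3, seed=2))
        probes = make_probe_set(gm.locus_ids, seed=2)
        return gm, probes, tmp_path

    def test_fastq_roundtrip_preserves_counts(self, small_panel):
        """simulate counts -> FASTQ -> count_locus_reads is lossless at error 0."""
        gm, probes, tmp = small_panel
        c1, c2 = simulate_read_counts(
            gm, probes, ReadSimSpec(mean_depth=40, per_read_allele_error=0.0, seed=3)
        )
        for i, sid in enumerate(gm.sample_ids[:3]):
            r1, r2 = tmp / f"{sid}_R1.fastq", tmp / f"{sid}_R2.fastq"
            write_sample_fastq(probes, gm.locus_ids, c1[i], c2[i], r1, r2, seed=i)
            counts, off = count_locus_reads(r1, r2, probes.probes, sid)
            got1, got2 = counts_to_arrays(counts, [sid], gm.locus_ids)
            assert off == 0
            assert np.array_equal(got1[0], c1[i])
            assert np.array_equal(got2[0], c2[i])
            # every on-target read's mate matches its locus
            for c in counts:
                assert c.n_pair_matched == c.n_fwd_primer

    def test_probe1_only_reads_give_zero_probe2(self, small_panel):
        gm, probes, tmp = small_panel
        c1 = np.full((1, gm.n_loci), 20)
        c2 = np.zeros((1, gm.n_loci), dtype=int)
        r1, r2 = tmp / "x_R1.fastq", tmp / "x_R2.fastq"
        write_sample_fastq(probes, gm.locus_ids, c1[0], c2[0], r1, r2)
        counts, _ = count_locus_reads(r1, r2, probes.probes, "x")
        assert all(c.n_probe2 == 0 for c in counts)
        assert all(c.n_probe1 == 20 for c in counts)

    def test_unknown_prefix_counts_off_target(self, small_panel):
        gm, probes, tmp = small_panel
        r1, r2 = tmp / "y_R1.fastq", tmp / "y_R2.fastq"
        r1.write_text("@r0\n" + "T" * 75 + "\n+\n" + "I" * 75 + "\n")
        r2.write_text("@r0\n" + "T" * 75 + "\n+\n" + "I" * 75 + "\n")
        counts, off = count_locus_reads(r1, r2, probes.probes, "y")
        assert off == 1
        assert sum(c.n_fwd_primer for c in counts) == 0

    def test_one_mismatch_mode_recovers_errored_probe(self, small_panel):
        gm, probes, tmp = small_panel
        probe = probes.probes[0]
        amp1, _ = probes.amplicons[probe.locus_id]
        # introduce one sequencing error inside the probe, away from the SNP
        pos = amp1.index(probe.probe_allele1)
        errbase = "A" if amp1[pos] != "A" else "C"
        read = (amp1[:pos] + errbase + amp1[pos + 1 :])[:75]
        r1, r2 = tmp / "z_R1.fastq", tmp / "z_R2.fastq"
        r1.write_text(f"@r0\n{read}\n+\n{'I' * len(read)}\n")
        from gtpanel.synthetic_data import revcomp

        r2.write_text(f"@r0\n{revcomp(amp1)[:75]}\n+\n{'I' * 75}\n")
        exact, _ = count_locus_reads(r1, r2, probes.probes, "z")
        fuzzy, _ = count_locus_reads(r1, r2, probes.probes, "z", probe_mismatches=1)
        assert exact[0].n_probe1 == 0
        assert fuzzy[0].n_probe1 == 1

    def test_shared_primer_prefix_rejected(self):
        p1 = ProbeRecord("L1", "ACGTACGTACGTACGTACGT", "T" * 20, "AAAAA", "AAAAC", 100)
        p2 = ProbeRecord("L2", "ACGTACGTACGT", "T" * 20, "AAAAA", "AAAAC", 100)
        with pytest.raises(PanelValidationError, match="prefix"):
            count_locus_reads("/dev/null", "/dev/null", [p1, p2])


def test_truth_concordance_at_depth_100():
    """>= 99.5% of calls match simulated truth at depth 100, error 0.01."""
    bf, gm = simulate_baseline_pair(
        BaselineSpec(n_loci=200, n_samples_per_pop=25, seed=8)
    )
    probes = make_probe_set(gm.locus_ids, seed=8)
    c1, c2 = simulate_read_counts(
        gm, probes, ReadSimSpec(mean_depth=100, per_read_allele_error=0.01, seed=9)
    )
    called = call_genotype_matrix(c1, c2, sample_ids=gm.sample_ids, locus_ids=gm.locus_ids)
    truth = gm.dosage(alt_allele=np.full(gm.n_loci, 2))
    got = called.dosage(alt_allele=np.full(gm.n_loci, 2))
    assert truth.size == 10_000
    concordant = (got == truth)[got >= 0]
    assert concordant.mean() >= 0.995


class TestPrimerMetrics:
    def test_perfect_pairing(self):
        counts = [LocusCounts("s", "L1", 50, 30, 20, 50)]
        df = primer_metrics(counts).set_index("locus_id")
        assert df.loc["L1", "agreement_rate"] == 1.0
        assert df.loc["L1", "on_target_pct"] == 1.0

    def test_no_reverse_matches(self):
        counts = [LocusCounts("s", "L1", 50, 30, 20, 0)]
        df = primer_metrics(counts).set_index("locus_id")
        assert df.loc["L1", "agreement_rate"] == 0.0

    def test_low_agreement_identifies_removal_candidates(self):
        counts = [
            LocusCounts("s", "good", 100, 60, 40, 95),
            LocusCounts("s", "bad", 100, 60, 40, 40),
        ]
        df = primer_metrics(counts).set_index("locus_id")
        removable = df.index[df["agreement_rate"] < 0.5].tolist()
        assert removable == ["bad"]

    def test_off_target_denominator(self):
        counts = [LocusCounts("s", "L1", 50, 30, 20, 50)]
        df = primer_metrics(counts, total_reads=200).set_index("locus_id")
        assert df.loc["L1", "on_target_pct"] == 0.25


class TestRatioAnomalies:
    def test_clean_disomic_locus_not_flagged(self):
        bf, gm = simulate_baseline_pair(BaselineSpec(n_loci=30, n_samples_per_pop=30, seed=5))
        probes = make_probe_set(gm.locus_ids, seed=5)
        c1, c2 = simulate_read_counts(
            gm, probes, ReadSimSpec(mean_depth=100, per_read_allele_error=0.0, seed=5)
        )
        flagged, frac = flag_ratio_anomalies(c1, c2, gm.locus_ids)
        assert flagged == []

    def test_duplicated_locus_flagged(self):
        """A tetrasomic-like locus with 1:3 'het' ratios lands in the
        ambiguous windows often enough to be flagged."""
        rng = np.random.default_rng(6)
        n = 60
        depth = rng.poisson(100, size=n)
        c1 = rng.binomial(depth, 0.125)  # extreme duplicated-ratio mode
        c2 = depth - c1
        flagged, frac = flag_ratio_anomalies(
            c1[:, None], c2[:, None], ["dup"], max_ambiguous_frac=0.10
        )
        assert flagged == ["dup"]
        assert frac[0] > 0.10

    def test_threshold_of_one_never_flags(self):
        rng = np.random.default_rng(7)
        c1 = rng.integers(0, 100, size=(50, 5))
        c2 = rng.integers(0, 100, size=(50, 5))
        flagged, _ = flag_ratio_anomalies(c1, c2, [f"L{j}" for j in range(5)], max_ambiguous_frac=1.0)
        assert flagged == []

    def test_min_called_guard(self):
        c1 = np.full((10, 1), 50)
        c2 = np.full((10, 1), 50)
        flagged, frac = flag_ratio_anomalies(c1, c2, ["L"], min_called=20)
        assert flagged == [] and np.isnan(frac[0])
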