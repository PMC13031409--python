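"""Estimator parity with brute-force oracles and selection-rule semantics."""

from __future__ import annotations

import numpy as np
import pytest

from gtpanel.io_formats import GenotypeMatrix, LocusRecord, PanelValidationError
from gtpanel.popgen_selection import (
    compute_locus_stats,
    one_snp_per_contig,
    select_panels,
    site_pi,
    thin_by_linkage,
    weir_cockerham_theta,
)

from conftest import calls_of, geno_matrix
from oracles import pi_oracle, wc_theta_oracle


class TestTheta:
    def test_fixed_difference_is_one(self):
        gm = geno_matrix({"A": ["AA"] * 10, "B": ["aa"] * 10})
        assert weir_cockerham_theta(gm, ["A", "B"])[0] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        gm = geno_matrix({"A": ["AA", "Aa", "aa"], "B": ["AA", "Aa", "aa"]})
        assert weir_cockerham_theta(gm, ["A", "B"])[0] <= 0

    def test_small_table_matches_component_oracle(self):
        gm = geno_matrix({"A": ["AA", "AA", "Aa"], "B": ["aa", "aa", "Aa"]})
        theta = weir_cockerham_theta(gm, ["A", "B"])[0]
        assert theta == pytest.approx(
            wc_theta_oracle([(1, 1), (1, 1), (1, 2)], [(2, 2), (2, 2), (1, 2)]), abs=1e-12
        )

    def test_monomorphic_is_undefined_not_zero(self):
        gm = geno_matrix({"A": ["AA", "AA"], "B": ["AA", "AA"]})
        assert np.isnan(weir_cockerham_theta(gm, ["A", "B"])[0])

    def test_requires_two_populations(self):
        gm = geno_matrix({"A": ["AA"]})
        with pytest.raises(PanelValidationError):
            weir_cockerham_theta(gm, ["A"])


class TestPi:
    def test_balanced_counts(self):
        gm = geno_matrix({"A": ["Aa"] * 5})  # allele counts 5/5, n=10
        assert site_pi(gm, "A")[0] == pytest.approx(50 / 90, abs=1e-12)

    def test_skewed_counts(self):
        gm = geno_matrix({"A": ["AA", "AA", "AA", "AA", "Aa"]})  # counts 9/1
        assert site_pi(gm, "A")[0] == pytest.approx(0.2, abs=1e-12)

    def test_monomorphic_is_zero(self):
        gm = geno_matrix({"A": ["AA", "AA"]})
        assert site_pi(gm, "A")[0] == 0.0


def test_theta_and_pi_match_oracles_on_random_tables():
    """100 random small two-population tables agree with the brute-force
    variance-components and pairwise-difference oracles to 1e-12."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        n1, n2 = rng.integers(2, 11, size=2)
        mk = lambda n: [tuple(sorted(rng.integers(1, 3, size=2))) for _ in range(n)]
        g1, g2 = mk(n1), mk(n2)
        calls = np.array([list(g) for g in g1 + g2], dtype=np.int32)[:, None, :]
        ids = [f"s{i}" for i in range(n1 + n2)]
        pops = {s: ("A" if i < n1 else "B") for i, s in enumerate(ids)}
        gm = GenotypeMatrix(ids, ["L0"], calls, pops)
        theta = weir_cockerham_theta(gm, ["A", "B"])[0]
        expected = wc_theta_oracle(g1, g2)
        if np.isnan(expected):
            assert np.isnan(theta)
        else:
            assert theta == pytest.approx(expected, abs=1e-12)
        pi = site_pi(gm, "A")[0]
        assert pi == pytest.approx(pi_oracle([a for g in g1 for a in g]), abs=1e-12)


def _rec(lid, contig="c1", pos=1, theta=None, pi=None, lg=None, cm=None, flank=20):
    return LocusRecord(
        locus_id=lid, contig=contig, position=pos, flank_left="A" * flank,
        flank_right="A" * flank, linkage_group=lg, cm_position=cm, theta=theta, pi=pi,
    )


class TestOneSnpPerContig:
    def test_argmax_kept(self):
        recs = [_rec("a", pos=10, theta=0.1), _rec("b", pos=20, theta=0.9), _rec("c", pos=30, theta=0.4)]
        kept = one_snp_per_contig(recs, "theta")
        assert [r.locus_id for r in kept] == ["b"]

    def test_singletons_unchanged(self):
        recs = [_rec("a", contig="c1", theta=0.1), _rec("b", contig="c2", theta=0.2)]
        assert len(one_snp_per_contig(recs, "theta")) == 2

    def test_tie_breaks_to_lower_position(self):
        recs = [_rec("hi", pos=50, theta=0.5), _rec("lo", pos=5, theta=0.5)]
        assert one_snp_per_contig(recs, "theta")[0].locus_id == "lo"
        assert one_snp_per_contig(recs[::-1], "theta")[0].locus_id == "lo"


class TestLinkageThinning:
    def test_close_pair_drops_lower_ranked(self):
        recs = [_rec("hi", theta=0.9, lg="lg1", cm=10.0), _rec("lo", theta=0.2, lg="lg1", cm=50.0)]
        kept, dropped = thin_by_linkage(recs, min_cm=50)
        assert [r.locus_id for r in kept] == ["hi"]
        assert dropped == {"lo": "hi"}

    def test_distant_pair_kept(self):
        recs = [_rec("a", theta=0.9, lg="lg1", cm=10.0), _rec("b", theta=0.2, lg="lg1", cm=70.0)]
        kept, _ = thin_by_linkage(recs, min_cm=50)
        assert len(kept) == 2

    def test_boundary_distance_kept(self):
        recs = [_rec("a", theta=0.9, lg="lg1", cm=0.0), _rec("b", theta=0.2, lg="lg1", cm=50.0)]
        kept, _ = thin_by_linkage(recs, min_cm=50)
        assert len(kept) == 2

    def test_different_groups_never_clash(self):
        recs = [_rec("a", theta=0.9, lg="lg1", cm=10.0), _rec("b", theta=0.2, lg="lg2", cm=10.0)]
        kept, _ = thin_by_linkage(recs, min_cm=50)
        assert len(kept) == 2

    def test_unmapped_pass_through(self):
        recs = [_rec("a", theta=0.9, lg="lg1", cm=10.0), _rec("u", theta=0.1)]
        kept, _ = thin_by_linkage(recs, min_cm=1000)
        assert "u" in [r.locus_id for r in kept]

    def test_raising_min_cm_never_increases_retention(self):
        rng = np.random.default_rng(2)
        recs = [
            _rec(f"l{i}", theta=float(rng.random()), lg=f"lg{rng.integers(3)}", cm=float(rng.uniform(0, 200)))
            for i in range(40)
        ]
        counts = [len(thin_by_linkage(recs, min_cm=c)[0]) for c in (0, 10, 25, 50, 100, 200)]
        assert counts == sorted(counts, reverse=True)

    def test_negative_cm_rejected_at_record_level(self):
        with pytest.raises(PanelValidationError):
            _rec("a", lg="lg1", cm=-5.0)


class TestSelectPanels:
    def _many(self, n=700):
        rng = np.random.default_rng(0)
        return [
            _rec(f"l{i:03d}", theta=float(rng.random()), pi=float(rng.uniform(0, 0.5)))
            for i in range(n)
        ]

    def test_requested_panel_sizes(self):
        sel = select_panels(self._many(), n_s=303, n_p=291)
        assert len(sel.s_loci) == 303 and len(sel.p_loci) == 291
        assert sel.s_shortfall == 0 and sel.p_shortfall == 0

    def test_short_flank_rejected(self):
        recs = [_rec("short", theta=0.99, pi=0.5, flank=14), _rec("ok", theta=0.5, pi=0.3)]
        sel = select_panels(recs, n_s=1, n_p=1, min_flank=15)
        assert sel.rejected == {"short": "flank"}
        assert sel.s_loci == ["ok"]

    def test_equal_theta_ties_break_by_locus_id(self):
        recs = [_rec(lid, theta=0.5, pi=0.1) for lid in ("b", "a", "c")]
        sel = select_panels(recs, n_s=2, n_p=2)
        assert sel.s_loci == ["a", "b"]

    def test_permutation_invariant_and_idempotent(self):
        recs = self._many(100)
        sel1 = select_panels(recs, n_s=20, n_p=20)
        sel2 = select_panels(recs[::-1], n_s=20, n_p=20)
        assert sel1.s_loci == sel2.s_loci and sel1.p_loci == sel2.p_loci

    def test_shortfall_reported(self):
        sel = select_panels(self._many(10), n_s=303, n_p=291)
        assert sel.s_shortfall == 293 and sel.p_shortfall == 281


def test_compute_locus_stats_frame(random_matrix):
    df = compute_locus_stats(random_matrix, ["A", "B"])
    assert list(df.columns) == ["locus_id", "theta", "pi", "maf", "call_rate"]
    assert ((df["call_rate"] >= 0) & (df["call_rate"] <= 1)).all()
    valid = df["maf"].dropna()
    assert ((valid >= 0) & (valid <= 0.5)).all()
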