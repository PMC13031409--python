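"""Per-locus statistics and the marker-selection pipeline.

Candidate SNPs are ranked by Weir–Cockerham FST (theta) between the two
species samples for the species-diagnostic panel (S-loci) and by nucleotide
diversity (pi) within the focal species for the parentage panel (P-loci).
Selection then applies one-SNP-per-contig collapsing, 50-cM linkage thinning
and a minimum flanking-sequence rule before taking the top-N of each ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, LocusRecord, PanelValidationError


@dataclass
class LocusStats:
    locus_id: str
    theta: float  # Weir-Cockerham FST; NaN where undefined
    pi: float  # nucleotide diversity in the focal population
    maf: float
    call_rate: float


@dataclass
class PanelSelection:
    """Ordered S- and P-panels plus the audit trail of rejections."""

    s_loci: list[str]
    p_loci: list[str]
    rejected: dict[str, str] = field(default_factory=dict)
    s_shortfall: int = 0
    p_shortfall: int = 0

    def overlap(self) -> list[str]:
        return [l for l in self.s_loci if l in set(self.p_loci)]


# ---------------------------------------------------------------------------
# estimators


def _allele_tables(gm: GenotypeMatrix, rows: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alleles, per-allele counts, per-allele het counts) among called genotypes."""
    col = gm.calls[rows, j, :]
    called = col[col[:, 0] != MISSING]
    alleles = np.unique(called)
    counts = np.array([(called == a).sum() for a in alleles])
    hets = np.array([((called == a).sum(axis=1) == 1).sum() for a in alleles])
    return alleles, counts, hets


def weir_cockerham_theta(gm: GenotypeMatrix, pops: Sequence[str]) -> np.ndarray:
    """Per-locus Weir & Cockerham (1984) theta between exactly two populations.

    Variance components a (between populations), b (between individuals within
    populations) and c (within individuals) are summed over alleles, matching
    the per-site convention of the standard VCF toolchain; theta = a/(a+b+c).
    Negative estimates are retained unclipped.  Loci monomorphic across both
    populations, or with fewer than two called genotypes in either population,
    yield NaN (undefined, not zero).
    """
    if len(pops) != 2:
        raise PanelValidationError("weir_cockerham_theta requires exactly two population labels")
    rows = [gm.samples_in_pop(p) for p in pops]
    r = 2
    out = np.full(gm.n_loci, np.nan)
    for j in range(gm.n_loci):
        per_pop = []
        ok = True
        for rws in rows:
            col = gm.calls[rws, j, :]
            called = col[col[:, 0] != MISSING]
            if len(called) < 2:
                ok = False
                break
            per_pop.append(called)
        if not ok:
            continue
        alleles = np.unique(np.concatenate(per_pop).ravel())
        alleles = alleles[alleles != MISSING]
        if len(alleles) < 2:
            continue  # monomorphic: theta undefined
        ns = np.array([len(c) for c in per_pop], dtype=float)
        n_bar = ns.mean()
        n_c = (r * n_bar - (ns**2).sum() / (r * n_bar)) / (r - 1)
        a_sum = 0.0
        abc_sum = 0.0
        for al in alleles:
            p_i = np.array([(c == al).sum() / (2 * len(c)) for c in per_pop])
            h_i = np.array([((c == al).sum(axis=1) == 1).mean() for c in per_pop])
            p_bar = (ns * p_i).sum() / (r * n_bar)
            s2 = (ns * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (ns * h_i).sum() / (r * n_bar)
            inner = p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0
            a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
            )
            c_comp = h_bar / 2.0
            a_sum += a
            abc_sum += a + b + c_comp
        if abc_sum != 0:
            out[j] = a_sum / abc_sum
    return out


def site_pi(gm: GenotypeMatrix, pop: str | None = None) -> np.ndarray:
    """Per-locus nucleotide diversity: unbiased mean pairwise difference.

    pi = sum_{i<j} 2 n_i n_j / (n (n-1)) over allele counts n_i with n total
    called alleles; for a biallelic SNP this is the unbiased expected
    heterozygosity.  Loci with fewer than two called alleles yield NaN.
    """
    rows = gm.samples_in_pop(pop) if pop is not None else np.arange(gm.n_samples)
    out = np.full(gm.n_loci, np.nan)
    for j in range(gm.n_loci):
        col = gm.calls[rows, j, :]
        called = col[col[:, 0] != MISSING].ravel()
        n = len(called)
        if n < 2:
            continue
        _, counts = np.unique(called, return_counts=True)
        out[j] = (n * n - (counts.astype(float) ** 2).sum()) / (n * (n - 1))
    return out


def compute_locus_stats(
    gm: GenotypeMatrix,
    species_pops: Sequence[str],
    focal_pop: str | None = None,
) -> pd.DataFrame:
    """Theta, pi, MAF and call rate per locus as a tidy DataFrame.

    ``species_pops`` are the two populations for the FST contrast; ``focal_pop``
    (default: the first of the pair) is the population within which pi and
    MAF are measured.
    """
    focal = focal_pop if focal_pop is not None else species_pops[0]
    theta = weir_cockerham_theta(gm, species_pops)
    pi = site_pi(gm, focal)
    rows = gm.samples_in_pop(focal)
    maf = np.full(gm.n_loci, np.nan)
    for j in range(gm.n_loci):
        col = gm.calls[rows, j, :]
        called = col[col[:, 0] != MISSING].ravel()
        if len(called) == 0:
            continue
        _, counts = np.unique(called, return_counts=True)
        maf[j] = 0.0 if len(counts) < 2 else np.sort(counts)[-2:][0] / counts.sum()
    call_rate = 1.0 - gm.missing_mask().mean(axis=0)
    return pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "theta": theta,
            "pi": pi,
            "maf": maf,
            "call_rate": call_rate,
        }
    )


# ---------------------------------------------------------------------------
# selection pipeline


def _criterion_value(rec: LocusRecord, criterion: str) -> float:
    v = getattr(rec, criterion, None)
    return float("-inf") if v is None or np.isnan(v) else float(v)


def one_snp_per_contig(records: Sequence[LocusRecord], criterion: str = "theta") -> list[LocusRecord]:
    """Retain exactly one SNP per contig: the one maximising ``criterion``.

    Ties break to the lowest position, so the result is deterministic and
    permutation-invariant.
    """
    if criterion not in ("theta", "pi"):
        raise PanelValidationError(f"criterion must be theta or pi, got {criterion!r}")
    best: dict[str, LocusRecord] = {}
    for rec in records:
        cur = best.get(rec.contig)
        if cur is None:
            best[rec.contig] = rec
            continue
        v_new, v_cur = _criterion_value(rec, criterion), _criterion_value(cur, criterion)
        if v_new > v_cur or (v_new == v_cur and rec.position < cur.position):
            best[rec.contig] = rec
    keep_ids = {r.locus_id for r in best.values()}
    return [r for r in records if r.locus_id in keep_ids]


def thin_by_linkage(
    records: Sequence[LocusRecord],
    min_cm: float = 50.0,
    rank: Callable[[LocusRecord], float] | None = None,
) -> tuple[list[LocusRecord], dict[str, str]]:
    """Greedy linkage thinning: drop a locus lying within ``min_cm`` of a
    better-ranked retained locus on the same linkage group.

    Candidates are scanned in descending rank order (default: theta); a
    candidate closer than ``min_cm`` (strict; the boundary distance is kept)
    to any retained mapped locus on its group is dropped.  Unmapped loci pass
    through untouched.  Returns (retained in input order, dropped -> blocking
    locus map).
    """
    if min_cm < 0:
        raise PanelValidationError("min_cm must be non-negative")
    rank = rank or (lambda r: _criterion_value(r, "theta"))
    mapped = [r for r in records if r.linkage_group is not None]
    order = sorted(mapped, key=lambda r: (-rank(r), r.locus_id))
    kept_by_group: dict[str, list[LocusRecord]] = {}
    dropped: dict[str, str] = {}
    for rec in order:
        clash = next(
            (
                k
                for k in kept_by_group.get(rec.linkage_group, [])
                if abs(k.cm_position - rec.cm_position) < min_cm
            ),
            None,
        )
        if clash is not None:
            dropped[rec.locus_id] = clash.locus_id
        else:
            kept_by_group.setdefault(rec.linkage_group, []).append(rec)
    retained = [r for r in records if r.locus_id not in dropped]
    return retained, dropped


def select_panels(
    records: Sequence[LocusRecord],
    n_s: int = 303,
    n_p: int = 291,
    min_flank: int = 15,
) -> PanelSelection:
    """Top-N panel selection after the minimum-flank rule.

    Loci with either flank shorter than ``min_flank`` bases are rejected with
    reason ``"flank"``.  S-loci are the ``n_s`` highest-theta eligible loci and
    P-loci the ``n_p`` highest-pi ones, ties broken by locus id; the two
    panels are selected independently, so overlap is possible (and reported
    by :meth:`PanelSelection.overlap`).  A shortfall (fewer eligible loci than
    requested) is recorded, never silently truncated.
    """
    rejected: dict[str, str] = {}
    eligible: list[LocusRecord] = []
    for rec in records:
        if len(rec.flank_left) < min_flank or len(rec.flank_right) < min_flank:
            rejected[rec.locus_id] = "flank"
        else:
            eligible.append(rec)
    s_ranked = sorted(eligible, key=lambda r: (-_criterion_value(r, "theta"), r.locus_id))
    p_ranked = sorted(eligible, key=lambda r: (-_criterion_value(r, "pi"), r.locus_id))
    s_loci = [r.locus_id for r in s_ranked[:n_s]]
    p_loci = [r.locus_id for r in p_ranked[:n_p]]
    return PanelSelection(
        s_loci=s_loci,
        p_loci=p_loci,
        rejected=rejected,
        s_shortfall=max(0, n_s - len(s_loci)),
        p_shortfall=max(0, n_p - len(p_loci)),
    )
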