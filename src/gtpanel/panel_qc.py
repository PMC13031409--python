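"""Panel optimisation filters and baseline preparation.

Implements the locus-level quality filters applied between a reference
genotype set (e.g., RAD-derived) and the new amplicon genotypes: the
five-level concordance score, the non-informative and primer-agreement
filters, the Hardy–Weinberg excess-heterozygosity / missingness filter for
parentage loci, modal-genotype imputation, and missingness profiling.  Every
removal is logged as (filter, locus, reason) so a panel's attrition can be
audited end to end.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .baseline import BaselineFrequencies, from_genotypes as compute_baseline_frequencies
from .io_formats import MISSING, GenotypeMatrix, PanelValidationError

__all__ = [
    "concordance_score",
    "concordance_matrix",
    "filter_concordant",
    "filter_noninformative",
    "hwe_excess_het_p",
    "hwe_excess_het_filter",
    "impute_most_frequent",
    "missingness_profile",
    "compute_baseline_frequencies",
    "BaselineFrequencies",
    "qc_audit",
]

SCORE_BOTH_CALLED_EQUAL = 2
SCORE_REF_MISSING = 1
SCORE_NEW_MISSING = 0
SCORE_BOTH_MISSING = -1
SCORE_DISCORDANT = -2


def concordance_score(g_ref: tuple[int, int], g_new: tuple[int, int]) -> int:
    """Five-level concordance score for one (sample, locus) cell.

    2 identical; 1 only the reference call missing; 0 only the new call
    missing; -1 both missing; -2 both called but different.
    """
    ref_missing = g_ref[0] == MISSING
    new_missing = g_new[0] == MISSING
    if ref_missing and new_missing:
        return SCORE_BOTH_MISSING
    if ref_missing:
        return SCORE_REF_MISSING
    if new_missing:
        return SCORE_NEW_MISSING
    return SCORE_BOTH_CALLED_EQUAL if tuple(g_ref) == tuple(g_new) else SCORE_DISCORDANT


def concordance_matrix(
    gm_ref: GenotypeMatrix,
    gm_new: GenotypeMatrix,
    allele_map: Mapping[str, Mapping[int, int]] | None = None,
) -> pd.DataFrame:
    """Score matrix (samples x shared loci) between two genotype sets.

    Samples and loci are aligned by identifier; only the intersection is
    scored.  ``allele_map`` reconciles per-locus allele-code flips in the new
    set (e.g., ref/alt orientation differences) before comparison.
    """
    samples = [s for s in gm_ref.sample_ids if s in set(gm_new.sample_ids)]
    loci = [l for l in gm_ref.locus_ids if l in set(gm_new.locus_ids)]
    if not samples or not loci:
        raise PanelValidationError("no shared samples or loci to score")
    ri = {s: i for i, s in enumerate(gm_ref.sample_ids)}
    rj = {l: j for j, l in enumerate(gm_ref.locus_ids)}
    ni = {s: i for i, s in enumerate(gm_new.sample_ids)}
    nj = {l: j for j, l in enumerate(gm_new.locus_ids)}
    scores = np.zeros((len(samples), len(loci)), dtype=int)
    for a, s in enumerate(samples):
        for b, l in enumerate(loci):
            g_ref = tuple(gm_ref.calls[ri[s], rj[l]])
            g_new = tuple(gm_new.calls[ni[s], nj[l]])
            if allele_map and l in allele_map and g_new[0] != MISSING:
                m = allele_map[l]
                g_new = tuple(sorted(m.get(x, x) for x in g_new))
            scores[a, b] = concordance_score(g_ref, g_new)
    return pd.DataFrame(scores, index=samples, columns=loci)


def filter_concordant(
    scores: pd.DataFrame, max_discordant: int = 4
) -> tuple[list[str], pd.DataFrame]:
    """Keep loci with at most ``max_discordant`` discordant (-2) cells.

    The default 4 encodes "fewer than five discordant genotypes".  Returns
    the retained locus list and a per-locus score histogram whose five
    columns always sum to the sample count.
    """
    hist = pd.DataFrame(
        {
            score: (scores == score).sum(axis=0)
            for score in (
                SCORE_BOTH_CALLED_EQUAL,
                SCORE_REF_MISSING,
                SCORE_NEW_MISSING,
                SCORE_BOTH_MISSING,
                SCORE_DISCORDANT,
            )
        }
    )
    retained = [l for l in scores.columns if hist.loc[l, SCORE_DISCORDANT] <= max_discordant]
    return retained, hist


def filter_noninformative(gm: GenotypeMatrix) -> tuple[list[str], dict[str, str]]:
    """Drop loci with no genotype variation among called samples, or no calls."""
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for j, lid in enumerate(gm.locus_ids):
        col = gm.calls[:, j, :]
        called = col[col[:, 0] != MISSING]
        if len(called) == 0:
            dropped[lid] = "all_missing"
        elif len(np.unique(called, axis=0)) == 1:
            dropped[lid] = "monomorphic"
        else:
            retained.append(lid)
    return retained, dropped


# ---------------------------------------------------------------------------
# Hardy-Weinberg excess heterozygosity


def _log_hwe_prob(n_het: int, n: int, n_a: int) -> float:
    """Log probability of ``n_het`` heterozygotes under the exact conditional
    HWE distribution given n diploids and n_a copies of allele A."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_het) // 2
    n_bb = (n_b - n_het) // 2
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_het + 1)
        - gammaln(n_bb + 1)
        + n_het * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def hwe_excess_het_p(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """One-sided exact p-value for heterozygote excess at a biallelic locus.

    p = P(heterozygote count >= observed) under the exact HWE conditional
    distribution given the allele counts.
    """
    n = n_het + n_hom_a + n_hom_b
    n_a = 2 * n_hom_a + n_het
    rare = min(n_a, 2 * n - n_a)
    terms = [_log_hwe_prob(h, n, n_a) for h in range(n_het, rare + 1) if (h - n_het) % 2 == 0]
    if not terms:
        return 1.0
    m = max(terms)
    return float(min(1.0, np.exp(m) * np.sum(np.exp(np.array(terms) - m))))


def hwe_excess_het_filter(
    gm: GenotypeMatrix,
    population: str | None = None,
    alpha: float = 0.05,
    max_missing: float = 0.20,
    min_called: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Drop loci with significant heterozygote excess or high missingness.

    The exact one-sided test runs within ``population`` (default: all
    samples); loci with p < alpha are removed with reason "excess_het", loci
    missing in more than ``max_missing`` of the population with reason
    "missingness".  Monomorphic or multi-allelic (>2) loci pass through the
    HWE test with NaN p; loci with fewer than ``min_called`` called genotypes
    are not tested.
    """
    rows = gm.samples_in_pop(population) if population is not None else np.arange(gm.n_samples)
    retained: list[str] = []
    recs = []
    for j, lid in enumerate(gm.locus_ids):
        col = gm.calls[rows, j, :]
        called = col[col[:, 0] != MISSING]
        miss = 1.0 - len(called) / len(rows)
        p = np.nan
        alleles = np.unique(called) if len(called) else np.array([])
        if len(called) >= min_called and len(alleles) == 2:
            a = alleles[0]
            n_het = int((called[:, 0] != called[:, 1]).sum())
            n_hom_a = int(((called[:, 0] == a) & (called[:, 1] == a)).sum())
            n_hom_b = len(called) - n_het - n_hom_a
            p = hwe_excess_het_p(n_het, n_hom_a, n_hom_b)
        reason = ""
        if miss > max_missing:
            reason = "missingness"
        elif not np.isnan(p) and p < alpha:
            reason = "excess_het"
        if not reason:
            retained.append(lid)
        recs.append({"locus_id": lid, "p_excess_het": p, "missingness": miss, "reason": reason})
    return retained, pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# imputation and missingness


def impute_most_frequent(
    gm: GenotypeMatrix, reference_pops: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    """Replace every missing call with the modal genotype of the sample's
    reference population at that locus.

    Modal ties break to the lexicographically smallest allele pair.  Called
    cells are never altered; the result has zero missing cells.  A locus with
    no called genotype in a population whose samples need it raises an error
    naming the locus.
    """
    pops = dict(reference_pops) if reference_pops is not None else dict(gm.populations or {})
    if not pops:
        raise PanelValidationError("imputation requires population labels")
    work = GenotypeMatrix(
        list(gm.sample_ids), list(gm.locus_ids), gm.calls.copy(), dict(pops)
    )
    bf = compute_baseline_frequencies(work)
    missing = work.missing_mask()
    for i, sid in enumerate(work.sample_ids):
        pop = pops.get(sid)
        if pop is None:
            if missing[i].any():
                raise PanelValidationError(f"sample {sid} has missing calls but no population label")
            continue
        for j in np.nonzero(missing[i])[0]:
            modal = bf.most_frequent_genotype[pop][j]
            if modal is None:
                raise PanelValidationError(
                    f"locus {work.locus_ids[j]} has no called genotype in population {pop!r}"
                )
            work.calls[i, j] = modal
    return work


def missingness_profile(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample and per-locus missing proportions (both in [0, 1])."""
    mask = gm.missing_mask()
    return mask.mean(axis=1), mask.mean(axis=0)


def qc_audit(*removals: tuple[str, dict[str, str]]) -> pd.DataFrame:
    """Stack (filter_name, {locus: reason}) pairs into one removal log."""
    recs = [
        {"filter": name, "locus_id": lid, "reason": reason}
        for name, dropped in removals
        for lid, reason in dropped.items()
    ]
    return pd.DataFrame(recs, columns=["filter", "locus_id", "reason"])
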