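"""Two-generation six-class hybrid machinery.

The six classes — pure A, pure B, F1, F2, backcross-to-A and backcross-to-B —
are characterised by their gene-pair origin proportions
phi = (phi_AA, phi_AB, phi_BB): the probability that, at a locus, the two
gene copies both descend from population A, one from each, or both from B.
Expected genotype frequencies per class follow from phi plus the parental
allele frequencies; classification is a plug-in Bayes rule over those
frequencies (parental frequencies fixed from the curated baseline rather
than sampled, which makes the posterior deterministic and auditable by
enumeration).  Simulation of class individuals is gamete-based, so Mendelian
segregation — not the phi marginals — generates F2 and backcross genotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baseline import BaselineFrequencies, smoothed_biallelic
from .io_formats import MISSING, GenotypeMatrix, PanelValidationError, from_dosage

CLASSES = ("PureA", "PureB", "F1", "F2", "BxA", "BxB")

_PHI = {
    "PureA": (1.0, 0.0, 0.0),
    "PureB": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BxA": (0.5, 0.5, 0.0),
    "BxB": (0.0, 0.5, 0.5),
}


@dataclass
class HybridClassModel:
    """Class set, phi matrix (rows sum to 1) and per-class prior."""

    classes: tuple[str, ...] = CLASSES
    phi: np.ndarray = field(default_factory=lambda: np.array([_PHI[c] for c in CLASSES]))
    prior: np.ndarray = field(default_factory=lambda: np.full(len(CLASSES), 1.0 / len(CLASSES)))

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.phi.shape != (len(self.classes), 3):
            raise PanelValidationError("phi must be classes x 3")
        if not np.allclose(self.phi.sum(axis=1), 1.0):
            raise PanelValidationError("phi rows must sum to 1")
        if not np.isclose(self.prior.sum(), 1.0):
            raise PanelValidationError("prior must sum to 1")


def class_phi_table() -> HybridClassModel:
    """The default two-generation model with a uniform class prior."""
    return HybridClassModel()


@dataclass
class PosteriorRecord:
    sample_id: str
    posterior: np.ndarray | None  # None when unclassified
    n_loci_used: int
    assigned_class: str | None
    max_posterior: float


# ---------------------------------------------------------------------------
# expected genotype frequencies


def _validate_freq_map(fmap: Mapping[int, float], label: str) -> None:
    if abs(sum(fmap.values()) - 1.0) > 1e-6:
        raise PanelValidationError(f"{label}: allele frequencies sum to {sum(fmap.values())}")


def expected_genotype_probs(
    hybrid_class: str | Sequence[float],
    p_a: Mapping[int, float],
    p_b: Mapping[int, float],
) -> dict[tuple[int, int], float]:
    """Probability of each unordered genotype under a hybrid class.

    P(i,i) = phi_AA p_Ai^2 + phi_AB p_Ai p_Bi + phi_BB p_Bi^2 and
    P(i,j) = phi_AA 2 p_Ai p_Aj + phi_AB (p_Ai p_Bj + p_Aj p_Bi)
           + phi_BB 2 p_Bi p_Bj for i != j; the distribution sums to 1.
    """
    _validate_freq_map(p_a, "p_A")
    _validate_freq_map(p_b, "p_B")
    phi = np.asarray(_PHI[hybrid_class] if isinstance(hybrid_class, str) else hybrid_class, dtype=float)
    alleles = sorted(set(p_a) | set(p_b))
    pa = {i: p_a.get(i, 0.0) for i in alleles}
    pb = {i: p_b.get(i, 0.0) for i in alleles}
    out: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations_with_replacement(alleles, 2):
        if i == j:
            out[(i, i)] = phi[0] * pa[i] ** 2 + phi[1] * pa[i] * pb[i] + phi[2] * pb[i] ** 2
        else:
            out[(i, j)] = (
                phi[0] * 2 * pa[i] * pa[j]
                + phi[1] * (pa[i] * pb[j] + pa[j] * pb[i])
                + phi[2] * 2 * pb[i] * pb[j]
            )
    return out


def _biallelic_prob_cube(model: HybridClassModel, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """(n_classes, n_loci, 3) genotype probabilities over alt-allele dosage."""
    qa, qb = 1.0 - pa, 1.0 - pb
    phi = model.phi  # (C, 3)
    g0 = np.stack([qa * qa, qa * qb, qb * qb])  # (3 origins, L) for dosage 0
    g1 = np.stack([2 * pa * qa, pa * qb + pb * qa, 2 * pb * qb])
    g2 = np.stack([pa * pa, pa * pb, pb * pb])
    cube = np.stack([phi @ g0, phi @ g1, phi @ g2], axis=2)  # (C, L, 3)
    return cube


# ---------------------------------------------------------------------------
# simulation


def _hw_pair(p: np.ndarray, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independent gametes per individual drawn from frequencies p."""
    return (
        (rng.random((n, len(p))) < p).astype(np.int8),
        (rng.random((n, len(p))) < p).astype(np.int8),
    )


def _segregate(a1: np.ndarray, a2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian gamete from a parent's two allele arrays."""
    pick = rng.integers(0, 2, size=a1.shape, dtype=np.int8)
    return np.where(pick == 0, a1, a2)


def simulate_class(
    freqs: BaselineFrequencies,
    hybrid_class: str,
    n: int = 30,
    seed: int = 0,
    prefix: str | None = None,
) -> GenotypeMatrix:
    """Gamete-based simulation of ``n`` individuals of one hybrid class.

    Pure parents draw both gametes from their population frequencies; F1
    takes one from each; F2 and backcross individuals are children of
    independently simulated parents with Mendelian segregation.  Loci are
    treated as unlinked.  Alleles carry codes 1 (reference) and 2.
    """
    if hybrid_class not in CLASSES:
        raise PanelValidationError(f"unknown hybrid class {hybrid_class!r}")
    if freqs.n_loci == 0:
        raise PanelValidationError("empty panel")
    rng = np.random.default_rng(seed)
    pa, pb = freqs.biallelic_arrays()

    def gamete(cls: str) -> np.ndarray:
        if cls == "PureA":
            a1, a2 = _hw_pair(pa, n, rng)
        elif cls == "PureB":
            a1, a2 = _hw_pair(pb, n, rng)
        elif cls == "F1":
            a1 = (rng.random((n, len(pa))) < pa).astype(np.int8)
            a2 = (rng.random((n, len(pb))) < pb).astype(np.int8)
        else:
            raise AssertionError(cls)
        return _segregate(a1, a2, rng)

    if hybrid_class == "PureA":
        g1, g2 = _hw_pair(pa, n, rng)
    elif hybrid_class == "PureB":
        g1, g2 = _hw_pair(pb, n, rng)
    elif hybrid_class == "F1":
        g1 = (rng.random((n, len(pa))) < pa).astype(np.int8)
        g2 = (rng.random((n, len(pb))) < pb).astype(np.int8)
    elif hybrid_class == "F2":
        g1, g2 = gamete("F1"), gamete("F1")
    elif hybrid_class == "BxA":
        g1, g2 = gamete("F1"), gamete("PureA")
    else:  # BxB
        g1, g2 = gamete("F1"), gamete("PureB")

    dosage = (g1 + g2).astype(np.int8)
    prefix = prefix if prefix is not None else hybrid_class
    sample_ids = [f"{prefix}_{i:04d}" for i in range(n)]
    return from_dosage(dosage, sample_ids=sample_ids, locus_ids=list(freqs.locus_ids))


def simulate_all_classes(
    freqs: BaselineFrequencies,
    n_per_class: int = 30,
    seed: int = 0,
    model: HybridClassModel | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Simulate every class; returns the stacked matrix and true labels."""
    model = model or class_phi_table()
    mats, truth = [], []
    for k, cls in enumerate(model.classes):
        gm = simulate_class(freqs, cls, n=n_per_class, seed=seed + 1000 * k)
        mats.append(gm)
        truth += [cls] * n_per_class
    calls = np.concatenate([g.calls for g in mats], axis=0)
    sample_ids = [s for g in mats for s in g.sample_ids]
    return GenotypeMatrix(sample_ids, list(freqs.locus_ids), calls), truth


# ---------------------------------------------------------------------------
# classification


def classify(
    gm: GenotypeMatrix,
    freqs: BaselineFrequencies,
    model: HybridClassModel | None = None,
    min_loci: int = 1,
    eps: float | None = None,
) -> list[PosteriorRecord]:
    """Plug-in Bayesian class posteriors per sample.

    Per-sample log-likelihood for each class sums log expected genotype
    probabilities over called loci; missing loci are skipped; the posterior
    is prior x likelihood normalised over the six classes.  Baseline
    frequencies are smoothed with a pseudo-count (default 1/(2n+2)) so
    sampling zeros cannot produce -inf log-likelihoods.  Samples with fewer
    than ``min_loci`` called loci are returned unclassified (posterior None),
    not as a uniform posterior.
    """
    model = model or class_phi_table()
    lidx = {l: j for j, l in enumerate(freqs.locus_ids)}
    missing_loci = [l for l in gm.locus_ids if l not in lidx]
    if missing_loci:
        raise PanelValidationError(f"loci absent from baseline: {missing_loci[:5]}")
    cols = [lidx[l] for l in gm.locus_ids]
    pa, pb = smoothed_biallelic(freqs, eps=eps)
    cube = np.log(_biallelic_prob_cube(model, pa[cols], pb[cols]))  # (C, L, 3)
    dosage = gm.dosage(alt_allele=np.full(gm.n_loci, 2))
    records: list[PosteriorRecord] = []
    log_prior = np.log(model.prior)
    for i, sid in enumerate(gm.sample_ids):
        called = dosage[i] >= 0
        n_used = int(called.sum())
        if n_used < min_loci:
            records.append(PosteriorRecord(sid, None, n_used, None, float("nan")))
            continue
        ll = cube[:, called, dosage[i, called]].sum(axis=1) + log_prior
        ll -= ll.max()
        post = np.exp(ll)
        post /= post.sum()
        k = int(post.argmax())
        records.append(PosteriorRecord(sid, post, n_used, model.classes[k], float(post[k])))
    return records


# ---------------------------------------------------------------------------
# power analyses


def power_analysis(
    freqs: BaselineFrequencies,
    model: HybridClassModel | None = None,
    n_per_class: int = 30,
    thresholds: Sequence[float] | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Classification power per class and posterior threshold.

    For each replicate all six classes are simulated, classified against the
    same baseline, and scored: accuracy at threshold t is the proportion of
    a class's individuals whose posterior for their true class is >= t.
    Returns a tidy frame with per-replicate accuracies plus mean and SD.
    """
    model = model or class_phi_table()
    thresholds = np.asarray(thresholds if thresholds is not None else np.arange(0.5, 1.0001, 0.05))
    rows = []
    for rep in range(replicates):
        gm, truth = simulate_all_classes(freqs, n_per_class, seed=seed + 7919 * rep, model=model)
        recs = classify(gm, freqs, model)
        for cls in model.classes:
            k = model.classes.index(cls)
            post_true = np.array(
                [r.posterior[k] if r.posterior is not None else 0.0 for r, t in zip(recs, truth) if t == cls]
            )
            for t in thresholds:
                rows.append(
                    {
                        "replicate": rep,
                        "class": cls,
                        "threshold": float(t),
                        "accuracy": float((post_true >= t).mean()),
                    }
                )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["class", "threshold"])["accuracy"].agg(["mean", "std"]).reset_index()
    )
    return df.merge(summary, on=["class", "threshold"])


def inject_missing(gm: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each called cell to MISSING independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise PanelValidationError("missing rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    hit = (rng.random((gm.n_samples, gm.n_loci)) < rate) & ~gm.missing_mask()
    calls[hit] = (MISSING, MISSING)
    return GenotypeMatrix(list(gm.sample_ids), list(gm.locus_ids), calls, dict(gm.populations or {}) or None)


def accuracy_vs_missing(
    freqs: BaselineFrequencies,
    model: HybridClassModel | None = None,
    missing_grid: Sequence[float] | None = None,
    threshold: float = 0.9,
    n_per_class: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class accuracy as controlled missingness is injected.

    One simulated dataset (all classes) is degraded to each level of the
    grid and re-classified; accuracy is the proportion of a class's
    individuals whose posterior for the true class is >= ``threshold``.
    """
    model = model or class_phi_table()
    grid = list(missing_grid if missing_grid is not None else np.arange(0.0, 0.91, 0.1))
    gm0, truth = simulate_all_classes(freqs, n_per_class, seed=seed, model=model)
    rows = []
    for m in grid:
        gm = inject_missing(gm0, m, seed=seed + int(round(1000 * m)) + 1) if m > 0 else gm0
        recs = classify(gm, freqs, model, min_loci=1)
        for cls in model.classes:
            k = model.classes.index(cls)
            post_true = np.array(
                [
                    r.posterior[k] if r.posterior is not None else 0.0
                    for r, t in zip(recs, truth)
                    if t == cls
                ]
            )
            rows.append(
                {
                    "missing": float(m),
                    "class": cls,
                    "accuracy": float((post_true >= threshold).mean()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline curation


def curate_baseline(
    gm: GenotypeMatrix,
    z_map: Mapping[str, str],
    min_posterior: float = 0.99,
    model: HybridClassModel | None = None,
) -> tuple[list[str], list[str], list[PosteriorRecord]]:
    """Anchor known pure individuals, classify everyone, and drop low-confidence samples.

    ``z_map`` maps sample ids to "A" or "B" (known pure designations);
    baseline frequencies are computed from designated individuals only.
    Samples whose maximum class posterior falls below ``min_posterior`` are
    excluded.  Returns (retained ids, excluded ids, posterior records).
    """
    from .baseline import from_genotypes

    bad = set(z_map.values()) - {"A", "B"}
    if bad:
        raise PanelValidationError(f"z designations must be 'A' or 'B', got {sorted(bad)}")
    anchored = GenotypeMatrix(
        list(gm.sample_ids), list(gm.locus_ids), gm.calls.copy(), dict(z_map)
    )
    rows = [i for i, s in enumerate(gm.sample_ids) if s in z_map]
    if not rows:
        raise PanelValidationError("no z-designated individuals")
    bf = from_genotypes(anchored.subset(samples=rows), pops=["A", "B"])
    recs = classify(gm, bf, model)
    retained = [r.sample_id for r in recs if r.posterior is not None and r.max_posterior >= min_posterior]
    excluded = [r.sample_id for r in recs if r.sample_id not in set(retained)]
    return retained, excluded, recs
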