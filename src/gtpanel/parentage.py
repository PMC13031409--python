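"""Likelihood-based parentage assignment power simulation.

Parent-pair LOD scores follow the classical trio likelihood with a
genotype-replacement error model: each observed genotype is, independently
with probability e, replaced by a random Hardy–Weinberg draw from the
population frequencies.  Under that convention the marginal distribution of
an observed genotype is still Hardy–Weinberg, so the non-parentage
(denominator) likelihood is the plain HW product and

    LOD = sum over shared typed loci of
          ln P(g_o, g_m, g_f | parentage, e) / ln-free HW product.

Delta is the LOD gap between the most and second most likely candidate pair;
critical Delta values at the relaxed (80%) and strict (95%) confidence
levels are estimated by simulation, exactly as the standard parentage
software does, and assignment rate is the proportion of simulated offspring
correctly assigned at or above the critical Delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import BaselineFrequencies
from .io_formats import PanelValidationError

# Mendelian transmission tensor over dosages: T[g_m, g_f, g_o]
_T = np.zeros((3, 3, 3))
for _gm in range(3):
    for _gf in range(3):
        qm, qf = _gm / 2.0, _gf / 2.0
        _T[_gm, _gf, 0] = (1 - qm) * (1 - qf)
        _T[_gm, _gf, 1] = qm * (1 - qf) + (1 - qm) * qf
        _T[_gm, _gf, 2] = qm * qf


@dataclass
class ParentageSimConfig:
    """Simulation conditions for parentage power analysis."""

    n_offspring: int = 10_000
    n_males: int = 100
    n_females: int = 100
    prop_sampled: float = 1.0
    prop_typed: float = 0.9
    error_rate: float = 0.02
    min_typed_frac: float = 0.5
    confidences: tuple[float, ...] = (0.80, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_sampled", "prop_typed"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise PanelValidationError(f"{name} must lie in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise PanelValidationError("error_rate must lie in [0, 1)")
        if not 0 <= self.min_typed_frac <= 1:
            raise PanelValidationError("min_typed_frac must lie in [0, 1]")
        if self.n_males < 1 or self.n_females < 1:
            raise PanelValidationError("need at least one candidate of each sex")


@dataclass
class AssignmentRecord:
    offspring_id: str
    best_pair: tuple[int, int]
    best_lod: float
    second_lod: float
    delta: float
    true_pair: tuple[int, int]
    true_sampled: bool
    correct: bool  # best pair is the true pair
    typed_frac: float
    assigned: dict[float, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary likelihood pieces


def transmission_prob(g_off: tuple[int, int], g_m: tuple[int, int], g_f: tuple[int, int]) -> float:
    """Exact Mendelian probability of an unordered offspring genotype."""
    prob = 0.0
    target = tuple(sorted(g_off))
    for am in g_m:
        for af in g_f:
            if tuple(sorted((am, af))) == target:
                prob += 0.25
    return prob


def _hw_prior(p: np.ndarray) -> np.ndarray:
    """(L, 3) HW genotype priors from alt-allele frequencies."""
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=1)


def trio_log_tables(p: np.ndarray, e: float) -> np.ndarray:
    """Per-locus log likelihood-ratio tables over observed dosages.

    Returns ``tbl`` of shape (L, 4, 16): ``tbl[l, g_o, 4*g_m + g_f]`` is the
    locus's LOD contribution; index 3 encodes a missing genotype and any
    missing member zeroes the contribution (the locus is skipped).
    """
    prior = _hw_prior(np.asarray(p, dtype=float))  # (L, 3)
    L = prior.shape[0]
    eye = np.eye(3)
    obs = (1 - e) * eye[None, :, :] + e * prior[:, :, None]  # obs[l, o, t] = P(o|t)
    num = np.einsum("lm,lf,mft,lot,lam,lbf->loab", prior, prior, _T, obs, obs, obs)
    den = np.einsum("lo,la,lb->loab", prior, prior, prior)
    with np.errstate(divide="ignore"):
        tbl3 = np.log(num) - np.log(den)
    out = np.zeros((L, 4, 16))
    for a in range(3):
        for b in range(3):
            out[:, :3, 4 * a + b] = tbl3[:, :, a, b]
    return out


def lod_pair(
    g_off: np.ndarray,
    g_mother: np.ndarray,
    g_father: np.ndarray,
    p: np.ndarray,
    e: float = 0.02,
) -> float:
    """LOD (natural log) for one offspring against one mother/father pair.

    Genotypes are alt-allele dosage vectors with -1 for untyped loci; loci
    untyped in any trio member are skipped.  With e = 0 an offspring allele
    absent from both candidates yields -inf (hard exclusion).
    """
    g_off, g_mother, g_father = (np.asarray(g, dtype=int) for g in (g_off, g_mother, g_father))
    shared = (g_off >= 0) & (g_mother >= 0) & (g_father >= 0)
    if not shared.any():
        raise PanelValidationError("no shared typed loci between offspring and pair")
    tbl = trio_log_tables(np.asarray(p)[shared], e)
    o, m, f = g_off[shared], g_mother[shared], g_father[shared]
    return float(tbl[np.arange(len(o)), o, 4 * m + f].sum())


# ---------------------------------------------------------------------------
# pair ranking


def rank_and_delta(
    scores: np.ndarray,
) -> tuple[int, float, float, float]:
    """Best pair index, best LOD, second LOD and Delta from a flat score vector.

    A single candidate pair's Delta equals its own LOD (assignment must stay
    defined when only one pair exists); tied top pairs give Delta 0.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise PanelValidationError("no candidate pairs")
    best = int(np.argmax(scores))
    best_lod = float(scores[best])
    if scores.size == 1:
        return best, best_lod, float("-inf"), best_lod
    rest = np.delete(scores, best)
    second = float(rest.max())
    if not np.isfinite(best_lod):
        delta = 0.0  # every pair excluded: nothing assignable
    elif not np.isfinite(second):
        delta = float("inf")  # sole compatible pair
    else:
        delta = best_lod - second
    return best, best_lod, second, delta


# ---------------------------------------------------------------------------
# simulation


def _hw_dosage(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, p[None, :], size=(n, len(p))).astype(np.int8)


def _corrupt(
    g: np.ndarray, p: np.ndarray, typed_p: float, err: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply typing dropout (-> -1) then genotype-replacement error."""
    out = g.astype(np.int8).copy()
    if err > 0:
        hit = rng.random(g.shape) < err
        out[hit] = rng.binomial(2, np.broadcast_to(p, g.shape)[hit])
    if typed_p < 1:
        out[rng.random(g.shape) > typed_p] = -1
    return out


def simulate_assignment(
    freqs: BaselineFrequencies | np.ndarray,
    cfg: ParentageSimConfig,
) -> tuple[list[AssignmentRecord], pd.DataFrame]:
    """Simulate offspring and score parent-pair assignment power.

    Candidate parents are HW draws from the focal population's frequencies;
    offspring arise by Mendelian transmission from a uniformly chosen
    mother/father pair.  Every individual's genotypes are independently
    dropped to untyped with probability 1 - prop_typed and, where typed,
    replaced by a random HW genotype with probability ``error_rate``.
    Offspring typed at fewer than ``min_typed_frac`` of loci are excluded.
    With probability 1 - prop_sampled the true parents are absent from the
    candidate pool, making a correct assignment impossible for that
    offspring.  Returns per-offspring records and the per-confidence summary
    (critical Delta and assignment rate).
    """
    if isinstance(freqs, BaselineFrequencies):
        p, _ = freqs.biallelic_arrays()
    else:
        p = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    L = len(p)
    mothers = _hw_dosage(p, cfg.n_females, rng)
    fathers = _hw_dosage(p, cfg.n_males, rng)
    true_m = rng.integers(0, cfg.n_females, size=cfg.n_offspring)
    true_f = rng.integers(0, cfg.n_males, size=cfg.n_offspring)
    gm_off = (
        (rng.random((cfg.n_offspring, L)) < mothers[true_m] / 2.0).astype(np.int8)
        + (rng.random((cfg.n_offspring, L)) < fathers[true_f] / 2.0).astype(np.int8)
    )
    obs_mothers = _corrupt(mothers, p, cfg.prop_typed, cfg.error_rate, rng)
    obs_fathers = _corrupt(fathers, p, cfg.prop_typed, cfg.error_rate, rng)
    obs_off = _corrupt(gm_off, p, cfg.prop_typed, cfg.error_rate, rng)
    sampled = rng.random(cfg.n_offspring) < cfg.prop_sampled

    tbl = trio_log_tables(p, cfg.error_rate)  # (L, 4, 16)
    m_idx = np.where(obs_mothers < 0, 3, obs_mothers)
    f_idx = np.where(obs_fathers < 0, 3, obs_fathers)
    # pair state per (mother, father, locus): 4*g_m + g_f, missing folded to 12..15
    ps = (4 * m_idx[:, None, :] + f_idx[None, :, :]).reshape(-1, L)
    ps = np.minimum(ps, 15)
    n_pairs = ps.shape[0]
    o_idx = np.where(obs_off < 0, 3, obs_off)
    larange = np.arange(L)

    records: list[AssignmentRecord] = []
    for i in range(cfg.n_offspring):
        typed_frac = float((obs_off[i] >= 0).mean())
        if typed_frac < cfg.min_typed_frac:
            continue
        per_locus = tbl[larange, o_idx[i], :]  # (L, 16)
        scores = per_locus[larange[:, None], ps.T].sum(axis=0)  # (n_pairs,)
        tm, tf = int(true_m[i]), int(true_f[i])
        true_flat = tm * cfg.n_males + tf
        if not sampled[i]:
            # true parents absent from the candidate pool
            mask = np.zeros(n_pairs, dtype=bool)
            mask.reshape(cfg.n_females, cfg.n_males)[tm, :] = True
            mask.reshape(cfg.n_females, cfg.n_males)[:, tf] = True
            scores = np.where(mask, -np.inf, scores)
        best, best_lod, second_lod, delta = rank_and_delta(scores)
        bm, bf = divmod(best, cfg.n_males)
        correct = sampled[i] and best == true_flat and np.isfinite(best_lod)
        records.append(
            AssignmentRecord(
                offspring_id=f"off{i:05d}",
                best_pair=(bm, bf),
                best_lod=best_lod,
                second_lod=second_lod,
                delta=delta,
                true_pair=(tm, tf),
                true_sampled=bool(sampled[i]),
                correct=bool(correct),
                typed_frac=typed_frac,
            )
        )
    summary = summarise(records, cfg.confidences)
    return records, summary


# ---------------------------------------------------------------------------
# critical Delta


def critical_delta(records: Sequence[AssignmentRecord], confidence: float) -> float:
    """Smallest Delta threshold at which the retained assignments reach the
    stated confidence.

    Delta* is the smallest value such that, among offspring with
    Delta >= Delta*, the fraction whose best pair is the true pair is at
    least ``confidence``; 0 when the unthresholded fraction already
    qualifies, +inf when no threshold does.
    """
    if not records:
        raise PanelValidationError("no assignment records")
    deltas = np.array([r.delta for r in records])
    correct = np.array([r.correct for r in records])
    order = np.argsort(deltas)
    deltas, correct = deltas[order], correct[order]
    n = len(deltas)
    # suffix fractions: among records with delta >= deltas[k]
    suffix_correct = np.cumsum(correct[::-1])[::-1]
    counts = n - np.arange(n)
    frac = suffix_correct / counts
    if frac[0] >= confidence:
        return 0.0
    qualifying = np.nonzero(frac >= confidence)[0]
    if len(qualifying) == 0:
        return float("inf")
    return float(deltas[qualifying[0]])


def summarise(records: Sequence[AssignmentRecord], confidences: Sequence[float]) -> pd.DataFrame:
    """Per-confidence critical Delta and assignment rate.

    Assignment rate is the proportion of scored offspring correctly assigned
    to their true parents at or above the critical Delta.
    """
    rows = []
    for conf in confidences:
        if records:
            d_star = critical_delta(records, conf)
            flags = [bool(r.correct and r.delta >= d_star) for r in records]
            for r, fl in zip(records, flags):
                r.assigned[conf] = fl
            rate = float(np.mean(flags))
        else:
            d_star, rate = float("nan"), float("nan")
        rows.append(
            {
                "confidence": conf,
                "critical_delta": d_star,
                "assignment_rate": rate,
                "n_offspring": len(records),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_grid(
    freqs: BaselineFrequencies | np.ndarray,
    base_cfg: ParentageSimConfig,
    typed_props: Sequence[float] | None = None,
    min_typed_fracs: Sequence[float] | None = None,
    sampled_props: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Assignment rate and critical Delta over grids of the sensitivity axes.

    Any axis left as None stays at the base configuration's value; the
    returned frame has one row per grid point per confidence level.  Each
    grid point reruns the full simulation with a seed derived from the base
    seed and the grid coordinates, so rows are independently reproducible.
    """
    t_grid = list(typed_props) if typed_props is not None else [base_cfg.prop_typed]
    m_grid = list(min_typed_fracs) if min_typed_fracs is not None else [base_cfg.min_typed_frac]
    s_grid = list(sampled_props) if sampled_props is not None else [base_cfg.prop_sampled]
    rows = []
    for ti, t in enumerate(t_grid):
        for mi, m in enumerate(m_grid):
            for si, s in enumerate(s_grid):
                cfg = ParentageSimConfig(
                    n_offspring=base_cfg.n_offspring,
                    n_males=base_cfg.n_males,
                    n_females=base_cfg.n_females,
                    prop_sampled=s,
                    prop_typed=t,
                    error_rate=base_cfg.error_rate,
                    min_typed_frac=m,
                    confidences=base_cfg.confidences,
                    seed=(base_cfg.seed + 100_003 * ti + 1009 * mi + 13 * si) % (2**31),
                )
                _, summary = simulate_assignment(freqs, cfg)
                for _, srow in summary.iterrows():
                    rows.append(
                        {
                            "prop_typed": t,
                            "min_typed_frac": m,
                            "prop_sampled": s,
                            "confidence": srow["confidence"],
                            "critical_delta": srow["critical_delta"],
                            "assignment_rate": srow["assignment_rate"],
                            "n_offspring": int(srow["n_offspring"]),
                        }
                    )
    return pd.DataFrame(rows)
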