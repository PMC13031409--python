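"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, exact fractions, published thermodynamic constants) and never calls
into the code paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product

# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) two-population theta, explicit variance components


def wc_theta_oracle(pop1: list[tuple[int, int]], pop2: list[tuple[int, int]]) -> float:
    """Direct evaluation of the a, b, c variance components for one locus.

    ``pop1``/``pop2`` are lists of called genotypes (allele-code pairs).
    Returns a/(a+b+c) summed over alleles; nan if monomorphic.
    """
    pops = [pop1, pop2]
    r = 2
    ns = [len(p) for p in pops]
    alleles = sorted({a for p in pops for g in p for a in g})
    if len(alleles) < 2:
        return float("nan")
    n_bar = sum(ns) / r
    n_c = (r * n_bar - sum(n * n for n in ns) / (r * n_bar)) / (r - 1)
    a_total = 0.0
    abc_total = 0.0
    for al in alleles:
        p_i = []
        h_i = []
        for pop, n in zip(pops, ns):
            count = sum(int(g[0] == al) + int(g[1] == al) for g in pop)
            het = sum(1 for g in pop if (g[0] == al) != (g[1] == al))
            p_i.append(count / (2 * n))
            h_i.append(het / n)
        p_bar = sum(n * p for n, p in zip(ns, p_i)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, h_i)) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        a_total += a
        abc_total += a + b + c
    return float("nan") if abc_total == 0 else a_total / abc_total


def pi_oracle(alleles: list[int]) -> float:
    """Mean pairwise difference over all ordered pairs of sampled alleles."""
    n = len(alleles)
    diffs = sum(1 for i in range(n) for j in range(n) if i != j and alleles[i] != alleles[j])
    return diffs / (n * (n - 1))


# ---------------------------------------------------------------------------
# SantaLucia (1998)-corrected unified nearest-neighbour melting temperature

_NN = {  # kcal/mol, cal/(mol K); Allawi & SantaLucia unified parameters,
    # keyed as 5'-step-3' / complement
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_SYM = (0.0, -1.4)
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def nn_tm_oracle(seq: str, na_mm: float = 50.0, oligo_um: float = 0.25) -> float:
    """Unified NN duplex Tm with the dS-based salt correction, coded from the
    published tables."""
    seq = seq.upper()
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inc = _INIT_GC if end in "GC" else _INIT_AT
        dh += inc[0]
        ds += inc[1]
    selfcomp = seq == _rc(seq)
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        key = f"{step}/{_COMP[step[0]]}{_COMP[step[1]]}"
        if key not in _NN:
            flipped = _rc(step)
            key = f"{flipped}/{_COMP[flipped[0]]}{_COMP[flipped[1]]}"
        dh += _NN[key][0]
        ds += _NN[key][1]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)
    nm = oligo_um * 1000.0
    k = (nm if selfcomp else nm - nm / 2.0) * 1e-9
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


# ---------------------------------------------------------------------------
# exact HWE heterozygote-excess p-value by enumeration


def hwe_excess_p_oracle(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """One-sided exact p by enumerating every admissible heterozygote count
    with exact rational weights."""
    n = n_het + n_hom_a + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n - n_a
    weights: dict[int, Fraction] = {}
    for h in range(min(n_a, n_b) + 1):
        if (n_a - h) % 2 or (n_b - h) % 2 or n_a - h < 0 or n_b - h < 0:
            continue
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(naa) * math.factorial(h) * math.factorial(nbb),
        )
    total = sum(weights.values())
    upper = sum(w for h, w in weights.items() if h >= n_het)
    return float(upper / total)


# ---------------------------------------------------------------------------
# hybrid classes: pedigree enumeration and mixture-likelihood posterior


def phi_by_pedigree_enumeration() -> dict[str, tuple[float, float, float]]:
    """Gene-pair origin proportions from exhaustive two-generation pedigrees.

    Individuals are origin pairs; each parent transmits one of its two
    origin genes with probability 1/2.  Enumerating every transmission path
    yields the exact (phi_AA, phi_AB, phi_BB) per class.
    """

    def cross(p1: dict, p2: dict) -> dict:
        out: dict[tuple[str, str], Fraction] = {}
        for g1, w1 in p1.items():
            for g2, w2 in p2.items():
                for a in g1:
                    for b in g2:
                        key = tuple(sorted((a, b)))
                        out[key] = out.get(key, Fraction(0)) + w1 * w2 * Fraction(1, 4)
        return out

    pure_a = {("A", "A"): Fraction(1)}
    pure_b = {("B", "B"): Fraction(1)}
    f1 = cross(pure_a, pure_b)
    classes = {
        "PureA": pure_a,
        "PureB": pure_b,
        "F1": f1,
        "F2": cross(f1, f1),
        "BxA": cross(f1, pure_a),
        "BxB": cross(f1, pure_b),
    }
    out = {}
    for name, dist in classes.items():
        out[name] = (
            float(dist.get(("A", "A"), Fraction(0))),
            float(dist.get(("A", "B"), Fraction(0))),
            float(dist.get(("B", "B"), Fraction(0))),
        )
    return out


_PHI_ORACLE = phi_by_pedigree_enumeration()
_CLASS_ORDER = ("PureA", "PureB", "F1", "F2", "BxA", "BxB")


def _smooth(p: float, n: int = 100) -> float:
    """The documented pseudo-count smoothing, re-derived: eps = 1/(2n+2)."""
    n2 = 2 * n
    eps = 1.0 / (n2 + 2)
    return (n2 * p + eps) / (n2 + 2 * eps)


def hybrid_posterior_oracle(
    dosages: list[int], p_a: list[float], p_b: list[float], smoothing_n: int = 100
) -> list[float]:
    """Posterior over the six classes by direct mixture-likelihood products.

    ``dosages`` are alt-allele counts per locus (-1 = missing).  Frequencies
    undergo the same documented pseudo-count smoothing the classifier states.
    """
    posts = []
    for cls in _CLASS_ORDER:
        phi = _PHI_ORACLE[cls]
        lik = 1.0
        for g, pa_raw, pb_raw in zip(dosages, p_a, p_b):
            if g < 0:
                continue
            pa = _smooth(pa_raw, smoothing_n)
            pb = _smooth(pb_raw, smoothing_n)
            hw = {
                "AA": [(1 - pa) ** 2, 2 * pa * (1 - pa), pa**2],
                "AB": [
                    (1 - pa) * (1 - pb),
                    pa * (1 - pb) + pb * (1 - pa),
                    pa * pb,
                ],
                "BB": [(1 - pb) ** 2, 2 * pb * (1 - pb), pb**2],
            }
            lik *= phi[0] * hw["AA"][g] + phi[1] * hw["AB"][g] + phi[2] * hw["BB"][g]
        posts.append(lik / len(_CLASS_ORDER))
    total = sum(posts)
    return [p / total for p in posts]


# ---------------------------------------------------------------------------
# parentage trio likelihood and critical-Delta scan


def _hw(p: float) -> list[float]:
    return [(1 - p) ** 2, 2 * p * (1 - p), p**2]


def _mendel(gm: int, gf: int, go: int) -> float:
    qm, qf = gm / 2.0, gf / 2.0
    return [
        (1 - qm) * (1 - qf),
        qm * (1 - qf) + (1 - qm) * qf,
        qm * qf,
    ][go]


def lod_oracle(
    g_off: list[int], g_m: list[int], g_f: list[int], p: list[float], e: float
) -> float:
    """Trio LOD by summing all 27 true-genotype states per locus."""
    total = 0.0
    for go, gm, gf, freq in zip(g_off, g_m, g_f, p):
        if go < 0 or gm < 0 or gf < 0:
            continue
        prior = _hw(freq)

        def obs(o: int, t: int) -> float:
            return (1 - e) * (o == t) + e * prior[o]

        num = sum(
            prior[tm] * prior[tf] * _mendel(tm, tf, to) * obs(go, to) * obs(gm, tm) * obs(gf, tf)
            for tm, tf, to in product(range(3), repeat=3)
        )
        den = prior[go] * prior[gm] * prior[gf]
        if num == 0.0:
            return float("-inf")
        total += math.log(num) - math.log(den)
    return total


def critical_delta_oracle(pairs: list[tuple[float, bool]], confidence: float) -> float:
    """Exhaustive scan over candidate thresholds (0 and every observed Delta)."""
    thresholds = sorted({0.0} | {d for d, _ in pairs})
    for thr in thresholds:
        kept = [ok for d, ok in pairs if d >= thr]
        if kept and sum(kept) / len(kept) >= confidence:
            return thr
    return float("inf")
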