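"""Shared fixtures and genotype-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gtpanel.io_formats import GenotypeMatrix

# genotype shorthand: "AA" -> (1,1), "Aa"/"aA" -> (1,2), "aa" -> (2,2), ".." -> missing
_CODE = {"A": 1, "a": 2}


def geno_matrix(pop_specs: dict[str, list[str]], locus_ids=None) -> GenotypeMatrix:
    """Build a matrix from per-population lists of genotype strings.

    Each sample string holds one two-letter genotype per locus, e.g.
    ``"AAAa.."`` is AA at locus 1, het at locus 2, missing at locus 3.
    """
    sample_ids, pops, rows = [], {}, []
    for pop, samples in pop_specs.items():
        for k, s in enumerate(samples):
            sid = f"{pop}{k}"
            sample_ids.append(sid)
            pops[sid] = pop
            pairs = [s[i : i + 2] for i in range(0, len(s), 2)]
            rows.append(
                [(0, 0) if p == ".." else (_CODE[p[0]], _CODE[p[1]]) for p in pairs]
            )
    n_loci = len(rows[0])
    locus_ids = locus_ids or [f"L{j}" for j in range(n_loci)]
    calls = np.array(rows, dtype=np.int32)
    return GenotypeMatrix(sample_ids, list(locus_ids), calls, pops)


def calls_of(gm: GenotypeMatrix, pop: str, j: int = 0) -> list[tuple[int, int]]:
    """Called genotype tuples of one population at locus column j."""
    rows = gm.samples_in_pop(pop)
    out = []
    for i in rows:
        a, b = gm.calls[i, j]
        if a != 0:
            out.append((int(a), int(b)))
    return out


@pytest.fixture(scope="session")
def strong_panel():
    """155 S-like loci with |p_A - p_B| >= 0.8 (species-diagnostic tail)."""
    from gtpanel.synthetic_data import make_species_panel

    bf, sel = make_species_panel(155, 0, seed=11, s_min_delta=0.8)
    return bf


@pytest.fixture(scope="session")
def p_panel():
    """112 P-like high-heterozygosity loci for parentage power."""
    from gtpanel.synthetic_data import make_species_panel

    bf, sel = make_species_panel(0, 112, seed=12)
    return bf


@pytest.fixture(scope="session")
def random_matrix():
    """A modest random two-population matrix with some missing calls."""
    rng = np.random.default_rng(5)
    n, m = 12, 8
    calls = np.zeros((n, m, 2), dtype=np.int32)
    for i in range(n):
        for j in range(m):
            if rng.random() < 0.1:
                continue
            calls[i, j] = sorted(rng.integers(1, 3, size=2))
    sample_ids = [f"s{i}" for i in range(n)]
    pops = {s: ("A" if i < 6 else "B") for i, s in enumerate(sample_ids)}
    return GenotypeMatrix(sample_ids, [f"L{j}" for j in range(m)], calls, pops)
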