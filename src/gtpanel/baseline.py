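"""Per-locus allele-frequency baselines for two parental populations.

:class:`BaselineFrequencies` is the hinge between the curated reference
genotypes and every simulation stage: hybrid-class simulation, plug-in
classification and parentage power all consume per-locus allele-frequency
maps for the two parental populations (p_A, p_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, PanelValidationError


@dataclass
class BaselineFrequencies:
    """Allele frequencies (and call counts) per locus for each population.

    ``freqs[pop][j]`` maps allele code -> frequency at locus ``j``; ``n[pop][j]``
    is the number of called diploid genotypes behind it (0 for analytic
    baselines specified directly as frequencies).
    """

    locus_ids: list[str]
    pops: list[str]
    freqs: dict[str, list[dict[int, float]]]
    n: dict[str, np.ndarray] = field(default_factory=dict)
    most_frequent_genotype: dict[str, list[tuple[int, int] | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in self.pops:
            if pop not in self.freqs:
                raise PanelValidationError(f"no frequencies for population {pop!r}")
            if len(self.freqs[pop]) != len(self.locus_ids):
                raise PanelValidationError(f"frequency list length mismatch for {pop!r}")
            for j, fmap in enumerate(self.freqs[pop]):
                if fmap and abs(sum(fmap.values()) - 1.0) > 1e-9:
                    raise PanelValidationError(
                        f"{self.locus_ids[j]}/{pop}: frequencies sum to {sum(fmap.values())}"
                    )
        if not self.n:
            self.n = {pop: np.zeros(len(self.locus_ids), dtype=int) for pop in self.pops}

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def alleles_at(self, j: int) -> list[int]:
        s: set[int] = set()
        for pop in self.pops:
            s.update(self.freqs[pop][j])
        return sorted(s)

    def biallelic_arrays(self, alt_allele: int = 2) -> tuple[np.ndarray, np.ndarray]:
        """Frequencies of ``alt_allele`` in the two populations, as vectors.

        Only valid for two-population biallelic baselines; absent alleles get
        frequency 0.
        """
        if len(self.pops) != 2:
            raise PanelValidationError("biallelic_arrays needs exactly two populations")
        pa = np.array([self.freqs[self.pops[0]][j].get(alt_allele, 0.0) for j in range(self.n_loci)])
        pb = np.array([self.freqs[self.pops[1]][j].get(alt_allele, 0.0) for j in range(self.n_loci)])
        return pa, pb

    def subset(self, loci: Sequence[int]) -> "BaselineFrequencies":
        loci = list(loci)
        return BaselineFrequencies(
            locus_ids=[self.locus_ids[j] for j in loci],
            pops=list(self.pops),
            freqs={p: [self.freqs[p][j] for j in loci] for p in self.pops},
            n={p: self.n[p][loci] for p in self.pops},
            most_frequent_genotype={
                p: [self.most_frequent_genotype[p][j] for j in loci]
                for p in self.most_frequent_genotype
            },
        )


def from_biallelic_arrays(
    p_a: np.ndarray,
    p_b: np.ndarray,
    locus_ids: Sequence[str] | None = None,
    pops: tuple[str, str] = ("A", "B"),
    n_per_pop: int = 0,
) -> BaselineFrequencies:
    """Build a biallelic two-population baseline from alt-allele (code 2) frequencies."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise PanelValidationError("p_a and p_b must have equal length")
    if ((p_a < 0) | (p_a > 1) | (p_b < 0) | (p_b > 1)).any():
        raise PanelValidationError("frequencies must lie in [0, 1]")
    m = len(p_a)
    locus_ids = list(locus_ids) if locus_ids is not None else [f"L{j:04d}" for j in range(m)]
    freqs = {
        pops[0]: [{1: 1.0 - float(p), 2: float(p)} for p in p_a],
        pops[1]: [{1: 1.0 - float(p), 2: float(p)} for p in p_b],
    }
    n = {p: np.full(m, n_per_pop, dtype=int) for p in pops}
    return BaselineFrequencies(locus_ids, list(pops), freqs, n)


def from_genotypes(gm: GenotypeMatrix, pops: Sequence[str] | None = None) -> BaselineFrequencies:
    """Count allele and modal-genotype frequencies from called genotypes only."""
    if gm.populations is None:
        raise PanelValidationError("genotype matrix carries no population labels")
    pops = list(pops) if pops is not None else gm.pop_labels()
    freqs: dict[str, list[dict[int, float]]] = {}
    ns: dict[str, np.ndarray] = {}
    modal: dict[str, list[tuple[int, int] | None]] = {}
    for pop in pops:
        rows = gm.samples_in_pop(pop)
        fl: list[dict[int, float]] = []
        nl = np.zeros(gm.n_loci, dtype=int)
        ml: list[tuple[int, int] | None] = []
        for j in range(gm.n_loci):
            col = gm.calls[rows, j, :]
            called = col[col[:, 0] != MISSING]
            nl[j] = len(called)
            if len(called) == 0:
                fl.append({})
                ml.append(None)
                continue
            vals, counts = np.unique(called.ravel(), return_counts=True)
            tot = counts.sum()
            fl.append({int(v): c / tot for v, c in zip(vals, counts)})
            pairs, pcounts = np.unique(called, axis=0, return_counts=True)
            # modal genotype; ties -> lexicographically smallest allele pair
            best = max(range(len(pairs)), key=lambda k: (pcounts[k], -pairs[k][0], -pairs[k][1]))
            ml.append((int(pairs[best][0]), int(pairs[best][1])))
        freqs[pop] = fl
        ns[pop] = nl
        modal[pop] = ml
    return BaselineFrequencies(list(gm.locus_ids), pops, freqs, ns, modal)


def write_freq_table(bf: BaselineFrequencies, path, sep: str = "\t") -> None:
    """Write a biallelic baseline as locus_id, p_a, p_b (alt-allele code 2)."""
    from pathlib import Path

    pa, pb = bf.biallelic_arrays()
    with Path(path).open("w") as fh:
        fh.write(sep.join(["locus_id", "p_a", "p_b"]) + "\n")
        for lid, a, b in zip(bf.locus_ids, pa, pb):
            fh.write(f"{lid}{sep}{a:.10g}{sep}{b:.10g}\n")


def read_freq_table(path, sep: str = "\t") -> BaselineFrequencies:
    """Read a locus_id / p_a / p_b table back into a baseline."""
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    header = lines[0].split(sep)
    if header[:3] != ["locus_id", "p_a", "p_b"]:
        raise PanelValidationError(f"{path}: expected header locus_id{sep}p_a{sep}p_b")
    ids, pa, pb = [], [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split(sep)
        ids.append(cells[0])
        pa.append(float(cells[1]))
        pb.append(float(cells[2]))
    return from_biallelic_arrays(np.array(pa), np.array(pb), locus_ids=ids)


def smoothed_biallelic(
    bf: BaselineFrequencies,
    alt_allele: int = 2,
    eps: float | None = None,
    default_n: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-count-smoothed alt-allele frequencies for the two populations.

    Each frequency p observed from 2n alleles becomes (2n p + eps) / (2n + 2 eps)
    with eps defaulting to 1/(2n + 2), so sampling zeros never produce
    zero-probability genotypes in downstream likelihoods.  Baselines declared
    analytically (n = 0) are smoothed as if counted from ``default_n`` diploids.
    """
    out = []
    for pop in bf.pops[:2]:
        n2 = 2.0 * np.where(bf.n[pop] > 0, bf.n[pop], default_n)
        p = np.array([bf.freqs[pop][j].get(alt_allele, 0.0) for j in range(bf.n_loci)])
        e = eps if eps is not None else 1.0 / (n2 + 2.0)
        out.append((n2 * p + e) / (n2 + 2 * e))
    return out[0], out[1]
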