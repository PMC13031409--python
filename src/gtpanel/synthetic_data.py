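"""Synthetic two-population baselines, panels, probes and amplicon reads.

Everything downstream of raw sequencing can be exercised without any external
download: this module fabricates (i) two-population SNP baselines with a
tunable divergence spectrum under the Balding–Nichols model, (ii) ready-made
S-like (species-diagnostic) and P-like (high-heterozygosity) panels,
(iii) probe/primer sets with per-allele amplicon sequences, and (iv) per-locus
allele read counts — optionally rendered as 75-bp paired-end FASTQ — with
negative-binomial depth and a per-read allele-error rate.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .baseline import BaselineFrequencies, from_biallelic_arrays
from .io_formats import GenotypeMatrix, PanelValidationError, ProbeRecord, from_dosage
from .popgen_selection import PanelSelection

READ_LEN = 75  # mirrors 75-bp paired-end sequencing


@dataclass
class BaselineSpec:
    """Conditions for a simulated two-population SNP baseline.

    ``divergence_f`` is the Balding–Nichols drift scale per population: each
    population's allele frequency is a Beta draw with mean equal to the
    ancestral frequency and variance F p(1-p).  Ancestral frequencies are
    uniform on ``ancestral_range``.
    """

    n_loci: int = 1000
    divergence_f: float = 0.3
    n_samples_per_pop: int = 60
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_f < 1:
            raise PanelValidationError("divergence_f must lie in (0, 1)")
        if self.n_loci < 1:
            raise PanelValidationError("n_loci must be >= 1")
        lo, hi = self.ancestral_range
        if not (0 <= lo < hi <= 1):
            raise PanelValidationError("ancestral_range must be an increasing pair in [0, 1]")


@dataclass
class ReadSimSpec:
    """Amplicon read-count conditions: NB depth and per-read allele error."""

    mean_depth: float = 100.0
    depth_dispersion: float = 5.0
    per_read_allele_error: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise PanelValidationError("mean_depth must be >= 0")
        if not 0 <= self.per_read_allele_error < 0.5:
            raise PanelValidationError("per_read_allele_error must lie in [0, 0.5)")
        if self.depth_dispersion <= 0:
            raise PanelValidationError("depth_dispersion must be positive")


# ---------------------------------------------------------------------------
# baselines


def _hw_genotypes(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Hardy–Weinberg dosage draws (n samples x loci) for alt frequencies p."""
    return rng.binomial(2, p[None, :], size=(n, len(p))).astype(np.int8)


def simulate_baseline_pair(spec: BaselineSpec) -> tuple[BaselineFrequencies, GenotypeMatrix]:
    """Draw a two-population baseline under the Balding–Nichols model.

    Population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws around a
    shared ancestral frequency p; genotypes are Hardy–Weinberg within each
    population.  Returns the true frequencies and the sampled genotypes
    (populations labelled ``A`` and ``B``).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_range
    anc = rng.uniform(lo, hi, size=spec.n_loci)
    f = spec.divergence_f
    shape = (1.0 - f) / f
    p_a = rng.beta(anc * shape, (1 - anc) * shape)
    p_b = rng.beta(anc * shape, (1 - anc) * shape)
    n = spec.n_samples_per_pop
    dos = np.vstack([_hw_genotypes(p_a, n, rng), _hw_genotypes(p_b, n, rng)])
    sample_ids = [f"A{i:04d}" for i in range(n)] + [f"B{i:04d}" for i in range(n)]
    pops = {s: ("A" if s.startswith("A") else "B") for s in sample_ids}
    gm = from_dosage(dos, sample_ids=sample_ids, populations=pops)
    bf = from_biallelic_arrays(p_a, p_b, locus_ids=gm.locus_ids, n_per_pop=n)
    return bf, gm


def make_species_panel(
    n_s_like: int,
    n_p_like: int,
    seed: int = 0,
    s_min_delta: float = 0.5,
    p_min_het: float = 0.4,
) -> tuple[BaselineFrequencies, PanelSelection]:
    """Construct an idealised panel: S-like diagnostic loci plus P-like
    high-heterozygosity loci.

    S-like loci are built with |p_A - p_B| >= ``s_min_delta`` (symmetric about
    0.5); P-like loci have expected heterozygosity 2p(1-p) >= ``p_min_het``
    within population A.  Returned frequencies list the S-panel first.
    """
    if n_s_like < 0 or n_p_like < 0:
        raise PanelValidationError("panel sizes must be non-negative")
    rng = np.random.default_rng(seed)
    delta = rng.uniform(s_min_delta, 0.98, size=n_s_like)
    s_pa = (1.0 + delta) / 2.0
    s_pb = (1.0 - delta) / 2.0
    # solve 2p(1-p) >= h for the admissible band around 0.5
    half_width = 0.5 * np.sqrt(max(0.0, 1.0 - 2.0 * p_min_het))
    p_pa = rng.uniform(0.5 - half_width, 0.5 + half_width, size=n_p_like)
    p_pb = np.clip(p_pa + rng.normal(0, 0.05, size=n_p_like), 0.02, 0.98)
    locus_ids = [f"S{j:04d}" for j in range(n_s_like)] + [f"P{j:04d}" for j in range(n_p_like)]
    bf = from_biallelic_arrays(
        np.concatenate([s_pa, p_pa]), np.concatenate([s_pb, p_pb]), locus_ids=locus_ids
    )
    sel = PanelSelection(s_loci=locus_ids[:n_s_like], p_loci=locus_ids[n_s_like:])
    return bf, sel


# ---------------------------------------------------------------------------
# probes and reads


_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ProbeSet:
    """Probe records plus the per-allele amplicon sequences behind them."""

    probes: list[ProbeRecord]
    amplicons: dict[str, tuple[str, str]] = field(default_factory=dict)

    def by_locus(self) -> dict[str, ProbeRecord]:
        return {p.locus_id: p for p in self.probes}


def make_probe_set(
    locus_ids: Sequence[str],
    seed: int = 0,
    amplicon_length: int = 100,
    primer_len: int = 20,
    probe_len: int = 15,
    snp_offset: int = 45,
) -> ProbeSet:
    """Generate random amplicons with a single SNP and derive probes/primers.

    The forward primer is the amplicon's first ``primer_len`` bases, the
    reverse primer the reverse complement of its last ``primer_len``; probes
    are ``probe_len``-mers centred on the SNP, one per allele.  Forward
    primers are guaranteed unique across loci.
    """
    rng = np.random.default_rng(seed)
    probes: list[ProbeRecord] = []
    amplicons: dict[str, tuple[str, str]] = {}
    seen_primers: set[str] = set()
    for lid in locus_ids:
        while True:
            seq = "".join(rng.choice(_BASES, size=amplicon_length))
            fwd = seq[:primer_len]
            if fwd not in seen_primers:
                seen_primers.add(fwd)
                break
        ref = seq[snp_offset]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        seq_alt = seq[:snp_offset] + alt + seq[snp_offset + 1 :]
        half = probe_len // 2
        lo, hi = snp_offset - half, snp_offset + probe_len - half
        probes.append(
            ProbeRecord(
                locus_id=lid,
                fwd_primer=fwd,
                rev_primer=revcomp(seq[-primer_len:]),
                probe_allele1=seq[lo:hi],
                probe_allele2=seq_alt[lo:hi],
                expected_amplicon_length=amplicon_length,
            )
        )
        amplicons[lid] = (seq, seq_alt)
    return ProbeSet(probes, amplicons)


def simulate_read_counts(
    gm: GenotypeMatrix,
    probes: ProbeSet | Sequence[ProbeRecord],
    spec: ReadSimSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(sample, locus) allele read counts (c1, c2) for allele 1 / allele 2.

    Depth is negative binomial with the spec's mean and dispersion k
    (variance m + m^2/k); heterozygotes split reads Binomial(depth, 1/2)
    before error; each read's allele then flips with the per-read error
    probability.  Missing genotypes receive zero depth.
    """
    probe_list = probes.probes if isinstance(probes, ProbeSet) else list(probes)
    have = {p.locus_id for p in probe_list}
    lacking = [l for l in gm.locus_ids if l not in have]
    if lacking:
        raise PanelValidationError(f"loci without a probe record: {lacking[:5]}")
    rng = np.random.default_rng(spec.seed)
    n, m = gm.n_samples, gm.n_loci
    if spec.mean_depth == 0:
        z = np.zeros((n, m), dtype=int)
        return z, z.copy()
    k = spec.depth_dispersion
    mu = spec.mean_depth
    depth = rng.negative_binomial(k, k / (k + mu), size=(n, m))
    # allele codes are fixed (1 = probe_allele1, 2 = probe_allele2)
    dos = gm.dosage(alt_allele=np.full(m, 2))
    depth[dos < 0] = 0
    q1 = np.select([dos == 0, dos == 1, dos == 2], [1.0, 0.5, 0.0], default=0.0)
    c1_true = rng.binomial(depth, q1)
    c2_true = depth - c1_true
    e = spec.per_read_allele_error
    if e > 0:
        c1 = rng.binomial(c1_true, 1 - e) + rng.binomial(c2_true, e)
    else:
        c1 = c1_true
    c2 = depth - c1
    c1[dos < 0] = 0
    c2[dos < 0] = 0
    return c1, c2


def write_sample_fastq(
    probeset: ProbeSet,
    locus_ids: Sequence[str],
    c1_row: np.ndarray,
    c2_row: np.ndarray,
    r1_path: str | Path,
    r2_path: str | Path,
    read_len: int = READ_LEN,
    seed: int = 0,
) -> None:
    """Render one sample's allele counts as a paired FASTQ (R1/R2).

    R1 is the amplicon 5' end (forward primer + probe region) and R2 the
    reverse complement of the amplicon 3' end, both clipped to ``read_len``;
    base qualities are constant (no quality model).
    """
    rng = np.random.default_rng(seed)
    amps = probeset.amplicons
    r1_lines: list[str] = []
    r2_lines: list[str] = []
    ridx = 0
    for j, lid in enumerate(locus_ids):
        seq1, seq2 = amps[lid]
        for seq, count in ((seq1, int(c1_row[j])), (seq2, int(c2_row[j]))):
            r1 = seq[:read_len]
            r2 = revcomp(seq)[:read_len]
            qual = "I" * len(r1)
            for _ in range(count):
                name = f"@read{ridx}"
                ridx += 1
                r1_lines += [name, r1, "+", qual]
                r2_lines += [name, r2, "+", "I" * len(r2)]
    # shuffle read order so parsing cannot rely on locus grouping
    order = rng.permutation(ridx)
    r1_recs = [r1_lines[4 * i : 4 * i + 4] for i in order]
    r2_recs = [r2_lines[4 * i : 4 * i + 4] for i in order]
    Path(r1_path).write_text("\n".join(l for rec in r1_recs for l in rec) + ("\n" if r1_recs else ""))
    Path(r2_path).write_text("\n".join(l for rec in r2_recs for l in rec) + ("\n" if r2_recs else ""))
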