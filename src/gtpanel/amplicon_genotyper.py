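"""Amplicon reads -> genotypes: counting, ratio-based calling, primer metrics.

Reads are assigned to panel loci by exact forward-primer prefix match; the
two allele probes are searched within the first 75 bases of the forward read
and the reverse read is checked against the locus to score read-pair
agreement.  Genotypes are called from the allele-1 : allele-2 count ratio r
at a minimum depth of 10x:

    r >= 10        -> homozygous allele 1
    r <= 0.1       -> homozygous allele 2
    0.2 <= r <= 5  -> heterozygous
    otherwise      -> missing (ambiguous zone)

The ambiguous zones (0.1 < r < 0.2 and 5 < r < 10) are exactly the ratio
signature of duplicated/tetrasomic loci, which is what the aberrant-ratio
flagger screens for.  All thresholds are configurable and echoed in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PanelValidationError, ProbeRecord, from_dosage

SNP_SEARCH_WINDOW = 75  # probe must sit within the first 75 bases of the amplicon


@dataclass
class RatioWindows:
    """Ratio-calling thresholds (defaults of the reference amplicon pipeline)."""

    min_depth: int = 10
    hom1_min_ratio: float = 10.0
    hom2_max_ratio: float = 0.1
    het_min_ratio: float = 0.2
    het_max_ratio: float = 5.0

    def describe(self) -> str:
        return (
            f"min_depth={self.min_depth} hom1>=r{self.hom1_min_ratio} "
            f"hom2<=r{self.hom2_max_ratio} het=[{self.het_min_ratio},{self.het_max_ratio}]"
        )


@dataclass
class LocusCounts:
    """Read-count tallies for one (sample, locus) cell."""

    sample_id: str
    locus_id: str
    n_fwd_primer: int = 0
    n_probe1: int = 0
    n_probe2: int = 0
    n_pair_matched: int = 0

    def validate(self) -> None:
        if self.n_probe1 + self.n_probe2 > self.n_fwd_primer:
            raise PanelValidationError(f"{self.sample_id}/{self.locus_id}: probe counts exceed primer count")
        if self.n_pair_matched > self.n_fwd_primer:
            raise PanelValidationError(f"{self.sample_id}/{self.locus_id}: pair count exceeds primer count")


@dataclass
class GenotypeCall:
    call: str  # "hom1" | "het" | "hom2" | "missing"
    depth: int
    ratio: float


# ---------------------------------------------------------------------------
# read counting


def _validate_panel(probes: Sequence[ProbeRecord]) -> None:
    prefixes = [p.fwd_primer.upper() for p in probes]
    for i, a in enumerate(prefixes):
        for b in prefixes[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise PanelValidationError(
                    f"ambiguous panel: forward primers {a!r} and {b!r} share a prefix"
                )


def _iter_fastq(path: str | Path):
    with Path(path).open() as fh:
        while True:
            name = fh.readline()
            if not name:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield seq


def _fuzzy_find(needle: str, haystack: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return needle in haystack
    n = len(needle)
    for start in range(len(haystack) - n + 1):
        window = haystack[start : start + n]
        if sum(a != b for a, b in zip(needle, window)) <= max_mismatches:
            return True
    return False


def count_locus_reads(
    r1_path: str | Path,
    r2_path: str | Path,
    probes: Sequence[ProbeRecord],
    sample_id: str = "sample",
    probe_mismatches: int = 0,
) -> tuple[list[LocusCounts], int]:
    """Tally per-locus primer/probe/pair matches for one sample's FASTQ pair.

    Each read pair is assigned to at most one locus: the first panel locus
    (in panel order) whose forward primer is an exact prefix of R1.  Probes
    are searched within the first 75 bases of R1 — exact substrings by
    default; ``probe_mismatches=1`` enables a one-mismatch mode (off by
    default since probes are short and residual error is absorbed by the
    ratio windows).  The pair is "matched" when R2 begins with the locus
    reverse primer.  Returns the per-locus counts plus the number of
    off-target read pairs.
    """
    _validate_panel(probes)
    counts = {p.locus_id: LocusCounts(sample_id, p.locus_id) for p in probes}
    off_target = 0
    r2_iter = _iter_fastq(r2_path)
    for r1 in _iter_fastq(r1_path):
        try:
            r2 = next(r2_iter)
        except StopIteration:
            raise PanelValidationError("R2 file has fewer reads than R1")
        r1u = r1.upper()
        hit = next((p for p in probes if r1u.startswith(p.fwd_primer.upper())), None)
        if hit is None:
            off_target += 1
            continue
        c = counts[hit.locus_id]
        c.n_fwd_primer += 1
        window = r1u[:SNP_SEARCH_WINDOW]
        p1, p2 = hit.probe_allele1.upper(), hit.probe_allele2.upper()
        if p1 in window:
            c.n_probe1 += 1
        elif p2 in window:
            c.n_probe2 += 1
        elif probe_mismatches > 0:
            f1 = _fuzzy_find(p1, window, probe_mismatches)
            f2 = _fuzzy_find(p2, window, probe_mismatches)
            # a read matching both probes fuzzily is allele-ambiguous
            if f1 and not f2:
                c.n_probe1 += 1
            elif f2 and not f1:
                c.n_probe2 += 1
        if r2.upper().startswith(hit.rev_primer.upper()):
            c.n_pair_matched += 1
    out = [counts[p.locus_id] for p in probes]
    for c in out:
        c.validate()
    return out, off_target


def counts_to_arrays(
    counts: Iterable[LocusCounts], sample_ids: Sequence[str], locus_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Arrange LocusCounts into (c1, c2) arrays shaped samples x loci."""
    si = {s: i for i, s in enumerate(sample_ids)}
    lj = {l: j for j, l in enumerate(locus_ids)}
    c1 = np.zeros((len(sample_ids), len(locus_ids)), dtype=int)
    c2 = np.zeros_like(c1)
    for c in counts:
        c1[si[c.sample_id], lj[c.locus_id]] = c.n_probe1
        c2[si[c.sample_id], lj[c.locus_id]] = c.n_probe2
    return c1, c2


# ---------------------------------------------------------------------------
# calling


def call_genotype(
    n_probe1: int, n_probe2: int, windows: RatioWindows | None = None
) -> GenotypeCall:
    """Ratio-based call for a single (sample, locus) count pair."""
    w = windows or RatioWindows()
    if n_probe1 < 0 or n_probe2 < 0:
        raise PanelValidationError("negative probe counts")
    depth = n_probe1 + n_probe2
    ratio = float("inf") if n_probe2 == 0 else n_probe1 / n_probe2
    if depth < w.min_depth:
        return GenotypeCall("missing", depth, ratio)
    if ratio >= w.hom1_min_ratio:
        return GenotypeCall("hom1", depth, ratio)
    if ratio <= w.hom2_max_ratio:
        return GenotypeCall("hom2", depth, ratio)
    if w.het_min_ratio <= ratio <= w.het_max_ratio:
        return GenotypeCall("het", depth, ratio)
    return GenotypeCall("missing", depth, ratio)  # ambiguous zone


def call_genotype_matrix(
    c1: np.ndarray,
    c2: np.ndarray,
    windows: RatioWindows | None = None,
    sample_ids: Sequence[str] | None = None,
    locus_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Vectorised ratio calling over count arrays; alleles coded 1 and 2."""
    w = windows or RatioWindows()
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    depth = c1 + c2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c2 == 0, np.inf, c1 / np.maximum(c2, 1e-300))
    dos = np.full(c1.shape, -1, dtype=np.int8)
    ok = depth >= w.min_depth
    dos[ok & (ratio >= w.hom1_min_ratio)] = 0
    dos[ok & (ratio <= w.hom2_max_ratio)] = 2
    dos[ok & (ratio >= w.het_min_ratio) & (ratio <= w.het_max_ratio)] = 1
    return from_dosage(dos, sample_ids=sample_ids, locus_ids=locus_ids)


# ---------------------------------------------------------------------------
# per-locus metrics


def primer_metrics(
    counts: Iterable[LocusCounts], total_reads: int | None = None
) -> pd.DataFrame:
    """On-target and forward/reverse agreement rates per locus.

    ``on_target_pct`` divides each locus's primer-matched reads by the total
    read count (pass ``total_reads`` to include off-target reads; otherwise
    the panel-wide primer-matched total is used).  ``agreement_rate`` is
    pair-matched reads over probe-matched reads.  With zero reads both are
    NaN and the locus is flagged undefined.
    """
    rows: dict[str, dict[str, int]] = {}
    for c in counts:
        r = rows.setdefault(c.locus_id, {"fwd": 0, "probe": 0, "pair": 0})
        r["fwd"] += c.n_fwd_primer
        r["probe"] += c.n_probe1 + c.n_probe2
        r["pair"] += c.n_pair_matched
    total = total_reads if total_reads is not None else sum(r["fwd"] for r in rows.values())
    recs = []
    for lid, r in rows.items():
        on_target = r["fwd"] / total if total > 0 else np.nan
        agreement = r["pair"] / r["probe"] if r["probe"] > 0 else (np.nan if r["fwd"] == 0 else 0.0)
        recs.append(
            {
                "locus_id": lid,
                "on_target_pct": on_target,
                "agreement_rate": agreement,
                "undefined": total == 0,
            }
        )
    return pd.DataFrame(recs)


def flag_ratio_anomalies(
    c1: np.ndarray,
    c2: np.ndarray,
    locus_ids: Sequence[str],
    windows: RatioWindows | None = None,
    max_ambiguous_frac: float = 0.10,
    min_called: int = 20,
) -> tuple[list[str], np.ndarray]:
    """Flag loci whose depth-passing samples fall too often in the ambiguous
    ratio zones (0.1 < r < 0.2 or 5 < r < 10), the duplicated/tetrasomic
    signature.

    Loci with fewer than ``min_called`` depth-passing samples are skipped.
    Returns (flagged locus ids, per-locus ambiguous fraction; NaN if skipped).
    """
    w = windows or RatioWindows()
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    depth = c1 + c2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c2 == 0, np.inf, c1 / np.maximum(c2, 1e-300))
    passing = depth >= w.min_depth
    ambiguous = passing & (
        ((ratio > w.hom2_max_ratio) & (ratio < w.het_min_ratio))
        | ((ratio > w.het_max_ratio) & (ratio < w.hom1_min_ratio))
    )
    n_pass = passing.sum(axis=0)
    frac = np.full(c1.shape[1], np.nan)
    enough = n_pass >= min_called
    frac[enough] = ambiguous.sum(axis=0)[enough] / n_pass[enough]
    flagged = [locus_ids[j] for j in range(len(locus_ids)) if enough[j] and frac[j] > max_ambiguous_frac]
    return flagged, frac
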