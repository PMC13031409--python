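"""Multiplex-pool primer screening.

Candidate primers for each locus are filtered by a melting-temperature
window (58–64 °C, tag sequences excluded), amplicon geometry (80–150 bp with
the SNP inside the first 75 bases) and, sequentially against the growing
accepted pool, by 3'-end cross-dimer potential (the last 10 bases must not
form a duplex above 15 °C with any accepted primer) and hairpin stability
(no stem–loop with stem duplex Tm above 50 °C).

Melting temperatures are unified nearest-neighbour values (Allawi &
SantaLucia), with configurable monovalent salt and oligo concentration; the
rule thresholds, not the absolute Tm scale, are the screening contract, so
the parameterisation is recorded on every decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .io_formats import LocusRecord, PanelValidationError
from .synthetic_data import revcomp

TM_MIN = 58.0
TM_MAX = 64.0
AMPLICON_MIN = 80
AMPLICON_MAX = 150
SNP_MAX_OFFSET = 75
CROSS_DIMER_TM = 15.0
HAIRPIN_TM = 50.0
THREE_PRIME_WINDOW = 10


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbour conditions: monovalent salt (mM) and oligo conc (uM)."""

    monovalent_mm: float = 50.0
    oligo_um: float = 0.25

    def describe(self) -> str:
        return f"NN unified, Na+ {self.monovalent_mm} mM, oligo {self.oligo_um} uM, dS salt correction"


@dataclass
class PrimerCandidate:
    locus_id: str
    side: str  # "left" | "right"
    sequence: str  # 5'->3'
    tm: float
    amplicon_length: int
    snp_offset: int


@dataclass
class PoolDecision:
    """Outcome of greedy pool assembly: accepted pairs and per-locus reasons."""

    accepted: list[tuple[str, PrimerCandidate, PrimerCandidate]] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)
    params: ThermoParams = field(default_factory=ThermoParams)

    def accepted_sequences(self) -> list[str]:
        out = []
        for _, left, right in self.accepted:
            out += [left.sequence, right.sequence]
        return out


# ---------------------------------------------------------------------------
# thermodynamics


def _check_seq(seq: str) -> str:
    if not seq:
        raise PanelValidationError("empty sequence")
    s = seq.upper()
    if set(s) - set("ACGT"):
        raise PanelValidationError(f"non-ACGT symbols in sequence {seq!r}")
    return s


def melting_temp(seq: str, params: ThermoParams | None = None) -> float:
    """Unified nearest-neighbour Tm in °C for a primer against its perfect complement."""
    params = params or ThermoParams()
    s = _check_seq(seq)
    nm = params.oligo_um * 1000.0
    return float(
        _mt.Tm_NN(
            s,
            nn_table=_mt.DNA_NN3,
            Na=params.monovalent_mm,
            dnac1=nm,
            dnac2=nm,
            saltcorr=5,
        )
    )


def duplex_tm(segment: str, params: ThermoParams | None = None) -> float:
    """Tm of a short perfectly complementary duplex segment (same NN model)."""
    return melting_temp(segment, params)


# ---------------------------------------------------------------------------
# single-primer filters


def candidate_filter_reason(cand: PrimerCandidate, params: ThermoParams | None = None) -> str | None:
    """Reason a candidate fails the per-primer windows, or None if it passes."""
    if not (TM_MIN <= cand.tm <= TM_MAX):
        return "tm_window"
    if not (AMPLICON_MIN <= cand.amplicon_length <= AMPLICON_MAX):
        return "amplicon_len"
    if cand.snp_offset > SNP_MAX_OFFSET:
        return "snp_position"
    return None


def enumerate_candidates(
    record: LocusRecord,
    params: ThermoParams | None = None,
    primer_lengths: Sequence[int] = range(18, 29),
    max_per_side: int = 40,
) -> list[PrimerCandidate]:
    """Enumerate passing primer candidates for both flanks of a locus.

    The template is ``flank_left + SNP + flank_right``; left-side candidates
    are template prefixes ending before the SNP, right-side candidates the
    reverse complements of template suffixes starting after it.  Geometry is
    judged against the widest amplicon each primer could participate in, so
    every returned candidate can appear in at least one valid pair.  At most
    ``max_per_side`` candidates are returned per side.
    """
    params = params or ThermoParams()
    template = record.flank_left.upper() + record.alleles[0].upper() + record.flank_right.upper()
    snp_pos = len(record.flank_left)  # 0-based
    out: list[PrimerCandidate] = []
    n_left = n_right = 0
    for plen in primer_lengths:
        # left primers: [start, start+plen) with end <= snp_pos
        for start in range(0, snp_pos - plen + 1):
            if n_left >= max_per_side:
                break
            seq = template[start : start + plen]
            if set(seq) - set("ACGT"):
                continue
            max_amp = min(len(template) - start, AMPLICON_MAX)
            offset = snp_pos - start
            cand = PrimerCandidate(record.locus_id, "left", seq, melting_temp(seq, params), max_amp, offset)
            if candidate_filter_reason(cand, params) is None and start <= len(template) - AMPLICON_MIN:
                out.append(cand)
                n_left += 1
        # right primers: template[end-plen:end) with end-plen > snp_pos
        min_plen = min(primer_lengths)
        for end in range(len(template), snp_pos + plen, -1):
            if n_right >= max_per_side:
                break
            if end - plen <= snp_pos:
                break
            seq = revcomp(template[end - plen : end])
            if set(seq) - set("ACGT"):
                continue
            max_amp = min(end, AMPLICON_MAX)
            # best achievable SNP offset over valid amplicon starts: the
            # amplicon must begin at a left primer (>= min_plen before the
            # SNP) and span at least AMPLICON_MIN bases
            offset = max(min_plen, snp_pos - (end - AMPLICON_MIN))
            cand = PrimerCandidate(record.locus_id, "right", seq, melting_temp(seq, params), max_amp, offset)
            if candidate_filter_reason(cand, params) is None:
                out.append(cand)
                n_right += 1
    return out


# ---------------------------------------------------------------------------
# pool-level filters


def _best_cross_tm(three_prime: str, partner: str, params: ThermoParams) -> float:
    """Best duplex Tm of any >=4-nt complementary stretch of the 3' window
    against ``partner`` (gap-free, antiparallel)."""
    best = float("-inf")
    n = len(three_prime)
    for length in range(n, 3, -1):
        for start in range(0, n - length + 1):
            sub = three_prime[start : start + length]
            if revcomp(sub) in partner:
                tm = duplex_tm(sub, params)
                if tm > best:
                    best = tm
        if best > float("-inf"):
            # longer stretches dominate; no shorter sub-stretch can beat them
            break
    return best


def cross_dimer_reject(
    cand: PrimerCandidate | str,
    accepted_pool: Iterable[str],
    params: ThermoParams | None = None,
    threshold: float = CROSS_DIMER_TM,
) -> tuple[bool, str | None]:
    """Reject if the candidate's 3'-terminal 10 bases can form a duplex above
    ``threshold`` °C with any accepted primer.  Returns (reject, partner)."""
    params = params or ThermoParams()
    seq = cand if isinstance(cand, str) else cand.sequence
    tail = _check_seq(seq)[-THREE_PRIME_WINDOW:]
    for partner in accepted_pool:
        if _best_cross_tm(tail, partner.upper(), params) > threshold:
            return True, partner
    return False, None


def hairpin_reject(
    seq: str,
    params: ThermoParams | None = None,
    threshold: float = HAIRPIN_TM,
    min_stem: int = 3,
    loop_range: tuple[int, int] = (3, 8),
) -> bool:
    """Reject if any stem-loop (stem >= 3 bp, loop 3-8 nt) has stem duplex Tm
    above ``threshold`` °C."""
    params = params or ThermoParams()
    s = _check_seq(seq)
    n = len(s)
    lo, hi = loop_range
    for i in range(n):
        for loop in range(lo, hi + 1):
            max_k = (n - i - loop) // 2
            for k in range(min_stem, max_k + 1):
                stem1 = s[i : i + k]
                stem2 = s[i + k + loop : i + 2 * k + loop]
                if stem2 == revcomp(stem1):
                    if duplex_tm(stem1, params) > threshold:
                        return True
    return False


def assemble_pool(
    locus_order: Sequence[str],
    candidates: dict[str, Sequence[tuple[PrimerCandidate, PrimerCandidate]]],
    params: ThermoParams | None = None,
) -> PoolDecision:
    """Greedy sequential pool assembly in locus priority order.

    For each locus the first (left, right) candidate pair whose primers pass
    the hairpin filter and show no cross-dimer against the accepted pool (or
    against each other) is accepted; its primers join the pool.  Loci with no
    passing pair are rejected with the last failing reason.
    """
    params = params or ThermoParams()
    decision = PoolDecision(params=params)
    pool: list[str] = []
    for lid in locus_order:
        pairs = candidates.get(lid, [])
        reason = "no_candidates"
        accepted = False
        for left, right in pairs:
            per_pair_reason = None
            for primer in (left, right):
                r = candidate_filter_reason(primer, params)
                if r is not None:
                    per_pair_reason = r
                    break
                if hairpin_reject(primer.sequence, params):
                    per_pair_reason = "hairpin"
                    break
                other = right.sequence if primer is left else left.sequence
                rej, partner = cross_dimer_reject(primer, pool + [other], params)
                if rej:
                    per_pair_reason = f"cross_dimer({partner})"
                    break
                # symmetric direction: an already-accepted primer's 3' end
                # must not anneal to the incoming primer either
                for pooled in pool + [other]:
                    if cross_dimer_reject(pooled, [primer.sequence], params)[0]:
                        rej, partner = True, pooled
                        break
                if rej:
                    per_pair_reason = f"cross_dimer({partner})"
                    break
            if per_pair_reason is None:
                decision.accepted.append((lid, left, right))
                pool += [left.sequence, right.sequence]
                accepted = True
                break
            reason = per_pair_reason
        if not accepted:
            decision.rejected[lid] = reason
    return decision


def audit_pool(decision: PoolDecision) -> list[str]:
    """Re-audit the final pool: single-primer windows, hairpins and pairwise
    cross-dimer cleanliness.  Returns a list of violation descriptions."""
    problems: list[str] = []
    seqs = decision.accepted_sequences()
    for lid, left, right in decision.accepted:
        for cand in (left, right):
            r = candidate_filter_reason(cand, decision.params)
            if r is not None:
                problems.append(f"{lid}:{cand.side}:{r}")
            if hairpin_reject(cand.sequence, decision.params):
                problems.append(f"{lid}:{cand.side}:hairpin")
            others = [s for s in seqs if s != cand.sequence]
            rej, partner = cross_dimer_reject(cand, others, decision.params)
            if rej:
                problems.append(f"{lid}:{cand.side}:cross_dimer({partner})")
    return problems
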