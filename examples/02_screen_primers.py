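"""Screen candidate primers into a multiplex-compatible pool.

Builds random locus flanks, enumerates primer candidates passing the Tm
window (58-64 C), amplicon geometry (80-150 bp, SNP in the first 75 bases),
then greedily assembles a pool rejecting 3'-end cross-dimers (> 15 C against
any accepted primer) and stable hairpins (> 50 C).
"""

import numpy as np

from gtpanel import LocusRecord
from gtpanel.primer_screen import assemble_pool, audit_pool, enumerate_candidates

rng = np.random.default_rng(2)
records = [
    LocusRecord(
        locus_id=f"L{i:02d}", contig=f"c{i}", position=100,
        flank_left="".join(rng.choice(list("ACGT"), 80)),
        flank_right="".join(rng.choice(list("ACGT"), 80)),
    )
    for i in range(12)
]

candidates = {}
for rec in records:
    cl = enumerate_candidates(rec)
    lefts = [c for c in cl if c.side == "left"]
    rights = [c for c in cl if c.side == "right"]
    candidates[rec.locus_id] = [(l, r) for l in lefts for r in rights]

decision = assemble_pool([r.locus_id for r in records], candidates)
print(f"accepted {len(decision.accepted)} loci into the pool")
for lid, reason in decision.rejected.items():
    print(f"  rejected {lid}: {reason}")
print(f"pool audit violations: {audit_pool(decision)}")
# An empty audit list means the final pool is pairwise dimer-clean and every
# accepted primer individually satisfies the Tm/geometry/hairpin rules.
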