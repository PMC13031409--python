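"""From amplicon reads to genotypes via ratio-based calling.

Simulates per-locus allele read counts (negative-binomial depth, per-read
allele error), renders one sample as paired FASTQ, counts primer/probe
matches back out of the reads, and calls genotypes at the 10x minimum-depth
ratio windows.
"""

import tempfile
from pathlib import Path

import numpy as np

from gtpanel import BaselineSpec, ReadSimSpec, make_probe_set, simulate_baseline_pair, simulate_read_counts
from gtpanel.amplicon_genotyper import (
    call_genotype_matrix,
    count_locus_reads,
    counts_to_arrays,
    primer_metrics,
)
from gtpanel.synthetic_data import write_sample_fastq

bf, gm = simulate_baseline_pair(BaselineSpec(n_loci=50, n_samples_per_pop=5, seed=3))
probes = make_probe_set(gm.locus_ids, seed=3)
c1, c2 = simulate_read_counts(gm, probes, ReadSimSpec(mean_depth=80, per_read_allele_error=0.01, seed=4))

with tempfile.TemporaryDirectory() as d:
    r1, r2 = Path(d) / "s0_R1.fastq", Path(d) / "s0_R2.fastq"
    write_sample_fastq(probes, gm.locus_ids, c1[0], c2[0], r1, r2, seed=5)
    counts, off_target = count_locus_reads(r1, r2, probes.probes, "s0")

got1, got2 = counts_to_arrays(counts, ["s0"], gm.locus_ids)
called = call_genotype_matrix(got1, got2, locus_ids=gm.locus_ids)
truth = gm.dosage(alt_allele=np.full(gm.n_loci, 2))[0]
dos = called.dosage(alt_allele=np.full(gm.n_loci, 2))[0]

metrics = primer_metrics(counts)
print(f"off-target read pairs: {off_target}")
print(f"loci called: {(dos >= 0).sum()} of {gm.n_loci}")
print(f"calls matching simulated truth: {(dos == truth)[dos >= 0].mean():.3f}")
print(f"mean fwd/rev agreement rate: {metrics['agreement_rate'].mean():.3f}")
# Agreement rate is the read-pair consistency metric used to drop
# poorly-performing primers from the multiplex.
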