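# gtpanel

Design and power evaluation of targeted amplicon (GT-seq) SNP panels for
closely related, hybridising species pairs.

Conservation programs that propagate an endangered species alongside an
abundant, hybridising congener need two things from a genetic marker panel:
(i) reliable classification of individuals into pure species and
two-generation hybrid classes — F1, F2 and, hardest of all, backcrosses —
and (ii) parentage assignment strong enough to separate hatchery-origin
from wild-origin fish. `gtpanel` is a toolkit for building and
stress-testing such dual-purpose panels: it ranks candidate SNPs, screens
multiplex primer pools, calls genotypes from amplicon reads, runs panel QC,
and quantifies — by simulation — how much classification and assignment
power a panel actually delivers, including under missing data.

## What it computes

**Marker selection.** Per-locus Weir–Cockerham FST between the two species
(θ = a/(a+b+c) from the variance components, summed over alleles) ranks
species-diagnostic **S-loci**; nucleotide diversity within the focal
species, π = Σ_{i<j} 2nᵢnⱼ / (n(n−1)), ranks high-heterozygosity **P-loci**
for parentage. Selection applies one-SNP-per-contig collapsing, 50-cM
linkage thinning and a 15-bp minimum flank before taking the top-N of each
ranking.

**Primer screening.** Nearest-neighbour Tm window 58–64 °C, amplicons
80–150 bp with the SNP in the first 75 bases, greedy pool assembly
rejecting 3′-end cross-dimers (> 15 °C against any accepted primer) and
hairpins (> 50 °C), plus a whole-pool audit.

**Genotyping.** Allele-ratio calling at ≥ 10× depth (r ≥ 10 → hom₁,
r ≤ 0.1 → hom₂, 0.2 ≤ r ≤ 5 → het, else missing), primer performance
metrics, and an aberrant-ratio screen for duplicated loci.

**Hybrid power.** A six-class model (PureA, PureB, F1, F2, BxA, BxB) over
gene-pair origin proportions φ; expected genotype frequencies
P(i,i) = φ_AA p_Aᵢ² + φ_AB p_Aᵢ p_Bᵢ + φ_BB p_Bᵢ², plug-in Bayesian
posteriors, gamete-based class simulation, and accuracy curves across
posterior thresholds and missing-data levels.

**Parentage power.** Trio LOD scores with a genotype-replacement error
model, Δ = LOD(best pair) − LOD(second pair), simulation-derived critical
Δ* at 80% (relaxed) and 95% (strict) confidence, and sensitivity grids over
typed-loci proportion, minimum typed-loci threshold and parent sampling.

See `docs/methods.md` for models, defaults and caveats.

## Worked example

Evaluate a species-diagnostic panel's hybrid-classification power
(`examples/05_hybrid_power.py`):

```python
from gtpanel import make_species_panel
from gtpanel.hybrid_model import accuracy_vs_missing, power_analysis

panel, _ = make_species_panel(155, 0, seed=8, s_min_delta=0.8)
power = power_analysis(panel, n_per_class=30, replicates=3, thresholds=[0.5, 0.9], seed=9)
amv = accuracy_vs_missing(panel, missing_grid=[0.0, 0.3, 0.6], threshold=0.9,
                          n_per_class=30, seed=10)
```

prints

```
mean accuracy by class and posterior threshold:
threshold  0.5  0.9
class
BxA        1.0  1.0
BxB        1.0  1.0
F1         1.0  1.0
F2         1.0  1.0
PureA      1.0  1.0
PureB      1.0  1.0

accuracy at >= 0.9 posterior under missing data:
missing  0.0  0.3    0.6
class
BxA      1.0  1.0  1.000
BxB      1.0  1.0  0.967
F1       1.0  1.0  1.000
F2       1.0  1.0  1.000
PureA    1.0  1.0  1.000
PureB    1.0  1.0  1.000
```

Every one of the 180 simulated individuals (30 per class) is assigned to
its true class with posterior ≥ 0.9 on full data, and the panel still
classifies essentially everything correctly with 60% of genotypes blanked —
the hallmark of a panel built from strongly divergent loci. The parentage
counterpart (`examples/06_parentage_power.py`) shows assignment rate
climbing to 1.0 and critical Δ falling to 0 as the typed-loci proportion
rises from 0.5 to 0.9 on a 112-locus high-heterozygosity panel.

The other examples cover marker selection (`01`), primer-pool screening
(`02`), FASTQ-to-genotype calling (`03`) and panel QC with imputation
(`04`); each runs in seconds and prints what its numbers mean.

A thin CLI wraps the same library calls
(`gtpanel simulate | select | primers | genotype | qc | curate-baseline |
hybrid-power | parentage-power`); every run writes a JSON manifest of its
inputs, parameters and seed.

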