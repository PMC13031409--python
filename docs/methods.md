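# Methods

`gtpanel` implements the full design-and-evaluation loop for a targeted
amplicon (GT-seq) SNP panel aimed at a pair of closely related, hybridising
species: marker ranking and selection, multiplex primer screening, genotype
calling from amplicon reads, panel quality control, and simulation-based
power analysis for six-class hybrid detection and parent-pair assignment.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data do and do not establish.

## Genotype data model

Genotypes are unordered diploid allele pairs over small positive integer
codes (Genepop convention), with `0` as the missing sentinel; a call is
missing if and only if both slots are 0 (half-missing calls are rejected at
construction). Coordinates are 1-based inclusive; strands are not tracked
because panel loci are strand-fixed by their probes. Population and species
identity travel only through opaque sample labels. Genepop (2- and 3-digit
codes, auto-detected), VCF (GT field only; REF→1, ALT→2), a delimited
genotype table and the NewHybrids individual-data format (with `z`
designation flags for known pure individuals) are supported, and all
writers round-trip through their readers.

## Marker selection

Between-species divergence is the per-locus Weir–Cockerham (1984) theta for
two populations, computed from the a/b/c variance components summed over
alleles (the per-site convention of the standard VCF toolchain). Negative
estimates are kept unclipped so ranking semantics match that tool's output;
loci monomorphic across both populations, or with fewer than two called
genotypes in either, are *undefined* (NaN), never zero. Within-species
diversity is the unbiased pairwise-difference form
`pi = sum_{i<j} 2 n_i n_j / (n (n-1))` over called allele counts, which for
a biallelic SNP equals unbiased expected heterozygosity.

Selection proceeds: (1) one SNP per contig, keeping the SNP that maximises
the ranking criterion (theta for species loci, pi for parentage loci), ties
to the lowest position — the criterion-maximising choice preserves ranking
power and is deterministic; (2) greedy linkage thinning in descending rank
order, dropping any candidate strictly closer than 50 cM (configurable) to
a retained locus on the same linkage group; the boundary distance is kept,
unmapped loci pass through; (3) a minimum 15-bp flank on both sides of the
target SNP (primer design needs the sequence); (4) top-N by theta (S-panel,
default 303) and by pi (P-panel, default 291), selected independently —
overlap is permitted and reported, and a shortfall is reported rather than
silently truncated.

## Primer screening

Melting temperatures are unified nearest-neighbour values (Allawi &
SantaLucia parameters) with the entropy-based salt correction, at
configurable monovalent salt (default 50 mM) and oligo concentration
(default 0.25 µM). The screening thresholds, not the absolute temperature
scale, are the design contract, so every decision records its
parameterisation. Filters per candidate: Tm in [58, 64] °C (adapter tags
excluded by construction), amplicon length in [80, 150] bp, SNP within the
first 75 bases of the amplicon (so a 75-bp forward read covers it). Pool
assembly is sequential and greedy in locus priority order: a pair is
accepted when both primers pass the hairpin rule (no stem ≥ 3 bp with loop
3–8 nt whose stem duplex Tm exceeds 50 °C) and the cross-dimer rule in
*both* directions against the growing pool — the candidate's 3'-terminal 10
bases must not form a gap-free antiparallel duplex above 15 °C with any
accepted primer, nor any accepted primer's 3' end with the candidate. The
cross-dimer temperature is the NN duplex Tm of the best complementary
stretch (≥ 4 nt) of the 3' decamer; whether the published rule meant duplex
Tm or a ΔG-derived annealing temperature is not documented anywhere we
could find, so the duplex-Tm reading is used and logged. A final audit
re-checks every accepted primer against the whole pool, so the greedy
order cannot leave a dimer-incompatible pair in place.

## Amplicon genotyping

Reads are assigned to at most one locus by exact forward-primer prefix
match (first match in panel order; panels with prefix-sharing primers are
rejected as ambiguous). Allele probes are exact substring matches within
the first 75 bases of the forward read; a read pair "agrees" when the
reverse read starts with the locus's reverse primer. Genotypes come from
the allele-count ratio r = n1/n2 at minimum depth 10×:

| condition | call |
|---|---|
| depth < 10 | missing |
| r ≥ 10 | homozygous allele 1 |
| r ≤ 0.1 | homozygous allele 2 |
| 0.2 ≤ r ≤ 5 | heterozygous |
| otherwise | missing (ambiguous zone) |

These windows reproduce the documented defaults of the reference GT-seq
calling pipeline and are fully configurable; all thresholds are echoed into
output manifests. Per-locus primer metrics are the on-target read fraction
and the forward/reverse agreement rate (pair-matched over probe-matched
reads); loci under 50% agreement are removal candidates. The
duplicated-locus screen formalises what is usually a visual check: a locus
is flagged when more than 10% (configurable) of its depth-passing samples
fall in the ambiguous ratio zones (0.1 < r < 0.2 or 5 < r < 10), the
signature of duplicated/tetrasomic loci whose "heterozygotes" sit near 1:3.
The 10% rule is our formalisation, not a published constant.

## Panel QC

Concordance between a reference genotype set and the amplicon genotypes is
scored per cell on five levels: 2 identical, 1 only the reference missing,
0 only the new call missing, −1 both missing, −2 both called but
different. A locus passes with at most 4 discordant cells ("fewer than
five" of 85 reference samples, i.e., < 5%); the per-locus score histogram
always partitions the sample count. Loci with no genotype variation among
called samples, or no calls at all, are dropped as non-informative. For the
parentage panel, a one-sided exact conditional test flags heterozygote
excess (the duplication/artefact signature); loci with p < 0.05 or more
than 20% missing data are removed. Both thresholds are exposed because the
source protocol states only "significant excess heterozygosity" and "high
levels of missing data". The excess-het test runs within the focal
population by default; whether it should instead pool populations is a
judgement call we resolved toward the population where parentage will be
performed. Missing calls are imputed with the modal genotype of the
sample's reference population at that locus (ties to the lexicographically
smallest allele pair); imputation never alters a called cell, leaves allele
frequencies over called genotypes unchanged, and is used only for
simulation inputs, never for empirical assignment. Every filter logs
(filter, locus, reason) so a panel's attrition is fully auditable.

## Hybrid model

The six two-generation classes — pure A, pure B, F1, F2, backcross-to-A,
backcross-to-B — are characterised by gene-pair origin proportions
φ = (φ_AA, φ_AB, φ_BB):

| class | φ_AA | φ_AB | φ_BB |
|---|---|---|---|
| PureA | 1 | 0 | 0 |
| PureB | 0 | 0 | 1 |
| F1 | 0 | 1 | 0 |
| F2 | ¼ | ½ | ¼ |
| BxA | ½ | ½ | 0 |
| BxB | 0 | ½ | ½ |

Expected genotype frequencies per class combine φ with parental allele
frequencies: P(i,i) = φ_AA p_Ai² + φ_AB p_Ai p_Bi + φ_BB p_Bi², and
analogously for heterozygotes. Classification is a **plug-in Bayes rule**:
parental frequencies are fixed from the curated baseline (optionally
z-anchored to designated pure individuals) rather than integrated over, the
per-sample log-likelihood sums over called loci (missing loci skipped,
loci treated as unlinked), and the posterior is prior × likelihood with a
uniform six-class prior. This deliberately replaces the usual MCMC
machinery: with a large anchored baseline the frequency uncertainty the
sampler integrates over is small, the plug-in posterior is deterministic
given frequencies, and it is auditable against exhaustive enumeration —
which the test suite does to 1e-12. The cost is mild overconfidence when
baselines are small; that approximation is the central caveat for applying
these posteriors to real data. Frequencies are smoothed with a pseudo-count
(ε = 1/(2n+2) per allele, n the number of diploids behind the estimate;
analytic baselines are treated as n = 100) so sampling zeros never produce
−∞ log-likelihoods. A sample with zero called loci is reported
*unclassified*, not as a uniform posterior.

Class individuals are simulated gamete-by-gamete: pure parents draw two
gametes from their population, F1 one from each, and F2/backcross
individuals are children of independently simulated parents under Mendelian
segregation — so simulated F2 genotype frequencies arise from segregation,
not from plugging φ into the genotype-frequency formula the classifier
uses. Power analysis simulates 30 individuals per class (3 replicates),
classifies them against the same baseline, and reports, per class and
posterior threshold (0.5–1.0), the proportion whose posterior for the true
class reaches the threshold. Missing-data robustness blanks each called
cell independently at rates 0–0.9 and re-classifies at the 0.9 posterior
threshold.

## Parentage

Parent-pair LOD uses the trio likelihood with a genotype-replacement error
model: each observed genotype is, independently with probability e (default
0.02), a random Hardy–Weinberg draw from the population frequencies. Under
this convention the marginal law of an observed genotype is unchanged, so
the non-parentage likelihood is the plain HW product and per-locus LOD
contributions reduce to precomputable 3×3×3 tables (missing genotypes skip
the locus). With e = 0, an offspring allele absent from both candidates
excludes the pair outright (LOD = −∞). Δ is the LOD gap between the best
and second-best pair over all mother × father combinations (sexes known);
a lone candidate pair's Δ equals its LOD so assignment stays defined, and
a sole *compatible* pair has Δ = ∞. The critical Δ* at a confidence level
is the smallest threshold at which the retained assignments reach that
fraction correct (0 if no thresholding is needed, ∞ if none suffices), and
the assignment rate is the proportion of scored offspring correctly
assigned at Δ ≥ Δ* — the proportion-correct reading, under which a rate
can exceed the confidence label when the panel is strong. Simulations
draw candidate parents from HW frequencies (defaults: 100 per sex, 10,000
offspring), apply typing dropout (1 − t per genotype, all individuals) and
genotyping error to every individual, drop offspring typed at fewer than
the minimum typed-loci fraction, and remove both true parents from the
candidate pool with probability 1 − s. Numeric parity with any specific
parentage program is not claimed; correctness is asserted against a
brute-force trio-likelihood enumeration and an exhaustive Δ* scan.

## Synthetic data

The generator exists so every stage can be exercised without external
data. Two-population baselines follow the Balding–Nichols model: per-locus
population frequencies are Beta draws with mean equal to a shared ancestral
frequency (uniform on [0.05, 0.95]) and drift scale F; F defaults to 0.3,
which puts the upper tail of the simulated FST spectrum in the range a
diagnostic panel would be mined from, and genotypes are Hardy–Weinberg
within populations. Idealised panels mirror the real design targets: 155
S-like loci with |p_A − p_B| ≥ 0.8 by construction (the selected
high-divergence tail; the constructor's floor is 0.5 and the power studies
use 0.8) and 112 P-like loci with expected heterozygosity ≥ 0.4 in the
focal population. Read counts are negative-binomial in depth (mean 100,
dispersion 5 — amplicon pools are overdispersed and no depth law is
published, so dispersion is a modelling choice), split binomially between
alleles for heterozygotes, with a per-read allele-flip error (default
0.01); reads can be rendered as 75-bp paired FASTQ with the forward primer
and allele probe embedded. Not modelled: base-quality profiles, index
hopping, chimeras, locus-specific amplification bias beyond the NB
dispersion, physical linkage between panel loci, and population structure
beyond the two-population island model. Consequently, passing power tests
demonstrate the statistical machinery under ideal Mendelian, unlinked,
HW conditions — they bound what a real panel can do from above and do not
certify any particular wet-lab panel.

## Problem sizes and numerical choices

The shipped analyses use 155-locus hybrid panels (30 individuals × 6
classes × 3 replicates), 112-locus parentage panels with 1,000 offspring
against 100 candidates per sex (500 per sensitivity grid point), and
10,000-call genotyper concordance checks; these sizes give binomial
standard errors well under the effects being measured while keeping any
single analysis in seconds. Posteriors are normalised in log space
(max-subtraction) and checked to 1e-9; oracle parity tests run at 1e-12;
ties everywhere break deterministically (lowest position, lexicographic
locus id or allele pair) so every pipeline stage is reproducible bit-for-bit
under a fixed seed. All randomness flows through explicitly seeded
generators; derived seeds stay below 2³¹.

## Known limitations

- The plug-in classifier ignores baseline-frequency uncertainty (see
  above); posteriors on small baselines are overconfident.
- Exact-match probe counting (a one-mismatch mode exists but is off by
  default) undercounts reads with sequencing errors inside the probe;
  the ratio windows absorb this at realistic error rates.
- The parentage error model replaces whole genotypes; allele-level dropout
  is not modelled.
- Linkage between panel loci is not corrected for in either the hybrid
  classifier or the parentage likelihood.
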