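"""Parentage assignment power: LOD, Delta and the sensitivity grid.

Simulates offspring from 100 candidate mothers and 100 candidate fathers
drawn from a 112-locus high-heterozygosity panel, scores every parent pair
by LOD, and reports assignment rate and critical Delta at the relaxed (80%)
and strict (95%) confidence levels across typed-loci proportions.
"""

from gtpanel import ParentageSimConfig, make_species_panel
from gtpanel.parentage import sensitivity_grid

panel, _ = make_species_panel(0, 112, seed=11)

cfg = ParentageSimConfig(n_offspring=500, n_males=100, n_females=100,
                         error_rate=0.02, min_typed_frac=0.5, seed=12)
grid = sensitivity_grid(panel, cfg, typed_props=[0.5, 0.7, 0.9])
print(grid.round(3).to_string(index=False))
# Assignment rate climbs toward 1.0 as more loci are typed while the
# critical Delta shrinks to 0: with enough typed loci the best pair is so
# clearly separated that no Delta threshold is needed for confidence.
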