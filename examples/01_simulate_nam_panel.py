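"""Simulate a NAM panel: map, RIL families, trait, and a blocked field trial.

Builds a 10-chromosome genetic map at 1.6 cM spacing, four RIL families
sharing a common parent (B73), a trait controlled by one additive QTL
explaining 12% of variance, and a two-year augmented incomplete-block
trial (blocks of 20 lines + 2 checks).
"""

import numpy as np

import namqtl as nq

gmap = nq.simulate_map(n_chromosomes=10, markers_per_chromosome=20,
                       mean_spacing_cm=1.6, seed=1)
print(f"map: {gmap.n_markers} markers on {len(gmap.chromosomes)} chromosomes")

specs = [("CML103", 154), ("CML333", 159), ("NC358", 151), ("Tx303", 160)]
geno = nq.simulate_nam(gmap, specs, residual_het_rate=0.001, seed=2)
print(f"panel: {geno.n_rils} RILs in {len(geno.families())} families")

het = (geno.codes == 1).mean()
print(f"residual heterozygosity: {het:.4%} (near-fixed selfed RILs)")

truth = nq.SimTruth(qtl=[(24, 1.0)], h2=0.12,
                    family_offsets={f: o for f, o in zip(
                        [s[0] for s in specs], [0.4, -0.2, 0.0, 0.6])})
values = nq.simulate_phenotype(geno, truth, seed=3)
print(f"trait simulated for {len(values)} genotypes; "
      f"QTL at marker index 24 targeting h2 = {truth.h2}")

design = nq.FieldDesign(block_size=22, checks_per_block=2, years=(2015, 2019),
                        block_effect_sd=0.6, year_effect_sd=0.5, residual_sd=0.4)
plots = nq.simulate_field_trial(values, design, seed=4)
print(f"field trial: {len(plots)} plots, {plots['is_check'].mean():.1%} checks "
      f"(common parent B73 replicated in every block)")

# The generator writes standard formats for downstream tools:
# nq.write_hapmap(geno, "genotypes.hmp.txt"); values.to_csv(...); truth.to_json(...)
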