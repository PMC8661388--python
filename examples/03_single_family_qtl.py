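"""Single-family stepwise QTL mapping with a permutation threshold.

Simulates one RIL family of 156 lines with two unlinked QTL, derives the
genome-wide p-value threshold from 200 phenotype permutations at
alpha = 0.05, and runs forward stepwise selection. The output table has
one row per accepted QTL: step, marker, chromosome, peak position (Mb),
p-value at acceptance, cumulative TPVE (%), effect size (trait units per
allele-code unit; positive = alternative-parent allele increases the
trait), and the 1-LOD support interval.
"""

import namqtl as nq

gmap = nq.simulate_map(10, 20, 1.6, seed=1)
geno = nq.simulate_ril_family(gmap, 156, seed=2)

truth = nq.SimTruth(qtl=[(24, 1.0), (150, -0.9)], h2=0.30)
pheno = nq.simulate_phenotype(geno, truth, seed=3).set_index("genotype")["trait"]
print("simulated QTL at marker indices 24 (+) and 150 (-), joint h2 = 0.30")

config = nq.ScanConfig(n_permutations=200, alpha=0.05, seed=4)
model = nq.stepwise_qtl(pheno, geno, config)
print(f"permutation threshold: p < {model.threshold:.2e}")
print(model.to_frame().to_string(index=False))
print(f"final model R^2 = {model.final_r2:.4f}")
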