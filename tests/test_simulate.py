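"""Synthetic-data generator: maps, RIL genotypes, phenotypes, field trials."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import namqtl as nq


# ---------------------------------------------------------------- genetic map

def test_map_two_markers_spacing():
    gmap = nq.simulate_map(1, 2, 10.0, seed=0)
    assert gmap.n_markers == 2
    assert np.isclose(np.diff(gmap.genetic_pos)[0], 10.0)


def test_map_study_scale_spacing():
    # ~836 approximately evenly spaced markers at 1.6 cM
    gmap = nq.simulate_map(10, 84, 1.6, seed=0)
    assert gmap.n_markers == 840
    for c in gmap.chromosomes:
        gaps = np.diff(gmap.genetic_pos[gmap.chromosome == c])
        assert abs(gaps.mean() - 1.6) < 0.05 * 1.6
        assert (gaps > 0).all()


def test_map_deterministic_and_monotone():
    a = nq.simulate_map(3, 15, 2.0, seed=42)
    b = nq.simulate_map(3, 15, 2.0, seed=42)
    assert np.array_equal(a.genetic_pos, b.genetic_pos)
    assert np.array_equal(a.physical_pos, b.physical_pos)
    for c in a.chromosomes:
        sel = a.chromosome == c
        g, p = a.genetic_pos[sel], a.physical_pos[sel]
        # physical order matches genetic order
        assert np.array_equal(np.argsort(g), np.argsort(p))


@pytest.mark.parametrize(
    "args", [(0, 10, 1.0), (2, 1, 1.0), (2, 10, 0.0), (2, 10, -1.0)]
)
def test_map_invalid_parameters(args):
    with pytest.raises(ValueError):
        nq.simulate_map(*args, seed=0)


# ------------------------------------------------------------- RIL genotypes

def test_zero_distance_markers_identical():
    gmap = nq.GeneticMap(["a", "b"], [1, 1], [5.0, 5.0], [100, 200])
    geno = nq.simulate_ril_family(gmap, 500, residual_het_rate=0.0, seed=1)
    assert np.array_equal(geno.codes[:, 0], geno.codes[:, 1])


def test_cross_chromosome_independence():
    gmap = nq.GeneticMap(["a", "b"], [1, 2], [0.0, 0.0], [1, 1])
    geno = nq.simulate_ril_family(gmap, 20000, residual_het_rate=0.0, seed=2)
    R = (geno.codes[:, 0] != geno.codes[:, 1]).mean()
    se = np.sqrt(0.25 / 20000)
    assert abs(R - 0.5) <= 3 * se


def _two_locus_ril_oracle(r, n, rng, generations=25):
    """Monte-Carlo selfed-RIL chain for two linked loci.

    Tracks both homologs from the F1; each selfing generation draws two
    gametes with crossover probability r between the loci (Haldane, no
    interference needed for two loci). Returns the fraction of lines whose
    (near-)fixed haplotype is recombinant.
    """
    # haplotypes encoded as (allele at locus 1, allele at locus 2), 0/1
    h1 = np.zeros((n, 2), dtype=int)  # from common parent
    h2 = np.ones((n, 2), dtype=int)
    for _ in range(generations):
        gametes = []
        for _gam in range(2):
            pick = rng.random(n) < 0.5  # which homolog at locus 1
            rec = rng.random(n) < r
            a1 = np.where(pick, h1[:, 0], h2[:, 0])
            # locus 2 follows the same homolog unless a crossover occurred
            from1 = pick ^ rec
            a2 = np.where(from1, h1[:, 1], h2[:, 1])
            gametes.append(np.column_stack([a1, a2]))
        h1, h2 = gametes
    # after many selfing generations each line is fixed; take homolog 1
    return float((h1[:, 0] != h1[:, 1]).mean())


def test_adjacent_recombination_matches_two_locus_oracle():
    """Observed RIL recombination at 10 cM matches R = 2r/(1+2r)."""
    d = 10.0
    r = float(nq.haldane_r(d))
    expected = 2 * r / (1 + 2 * r)
    gmap = nq.GeneticMap(["a", "b"], [1, 1], [0.0, d], [1, int(d * 1e6)])
    n = 10000
    geno = nq.simulate_ril_family(gmap, n, residual_het_rate=0.0, seed=3)
    observed = float((geno.codes[:, 0] != geno.codes[:, 1]).mean())
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) <= 3 * se
    # the independent forward-simulation oracle agrees with the closed form
    oracle = _two_locus_ril_oracle(r, n, np.random.default_rng(4))
    assert abs(oracle - expected) <= 3 * se


def test_allele_frequency_half(family156):
    freq0 = (family156.codes == 0).mean(axis=0)
    se = np.sqrt(0.25 / family156.n_rils)
    assert (np.abs(freq0 - 0.5) <= 4 * se).mean() > 0.95


def test_recombination_monotone_in_distance(nam_map):
    geno = nq.simulate_ril_family(nam_map, 4000, residual_het_rate=0.0, seed=6)
    dists, Rs = [], []
    for c in nam_map.chromosomes:
        cols = np.flatnonzero(nam_map.chromosome == c)
        for a, b in zip(cols[:-1], cols[1:]):
            dists.append(nam_map.genetic_pos[b] - nam_map.genetic_pos[a])
            Rs.append((geno.codes[:, a] != geno.codes[:, b]).mean())
    rho, _ = stats.spearmanr(dists, Rs)
    assert rho > 0.5


def test_residual_heterozygosity_rate(nam_map):
    geno = nq.simulate_ril_family(nam_map, 2000, residual_het_rate=0.01, seed=7)
    rate = (geno.codes == 1).mean()
    assert abs(rate - 0.01) < 0.002


def test_ril_family_invalid_parameters(small_map):
    with pytest.raises(ValueError):
        nq.simulate_ril_family(small_map, 0, seed=0)
    with pytest.raises(ValueError):
        nq.simulate_ril_family(small_map, 10, residual_het_rate=0.6, seed=0)


def test_determinism_same_seed(nam_map):
    a = nq.simulate_ril_family(nam_map, 50, seed=9)
    b = nq.simulate_ril_family(nam_map, 50, seed=9)
    assert np.array_equal(a.codes, b.codes)


# ------------------------------------------------------------------ NAM panel

def test_nam_study_sizes(nam_panel):
    assert nam_panel.n_rils == 624
    sizes = pd.Series(nam_panel.family).value_counts()
    assert sizes["CML103"] == 154 and sizes["Tx303"] == 160


def test_nam_family_labels_partition(nam_panel):
    rows = np.concatenate([nam_panel.rows_of(f) for f in nam_panel.families()])
    assert np.array_equal(np.sort(rows), np.arange(nam_panel.n_rils))


def test_nam_single_family_matches_ril_family(small_map):
    one = nq.simulate_nam(small_map, [("famA", 40)], seed=13)
    ref = nq.simulate_ril_family(small_map, 40, seed=13, family="famA")
    assert np.array_equal(one.codes, ref.codes)


def test_nam_duplicate_family_names(small_map):
    with pytest.raises(ValueError):
        nq.simulate_nam(small_map, [("famA", 5), ("famA", 5)], seed=0)


# ----------------------------------------------------------------- phenotypes

def test_phenotype_h2_one_is_exact_linear(family156):
    truth = nq.SimTruth(qtl=[(3, 0.7), (40, -0.4)], h2=1.0)
    df = nq.simulate_phenotype(family156, truth, seed=1)
    g = 0.7 * family156.codes[:, 3] - 0.4 * family156.codes[:, 40]
    assert np.allclose(df["trait"].to_numpy(), g)


def test_phenotype_h2_one_requires_genetic_variance(family156):
    with pytest.raises(ValueError):
        nq.simulate_phenotype(family156, nq.SimTruth(qtl=[], h2=1.0), seed=1)


def test_phenotype_null_has_no_marker_association(family156):
    truth = nq.SimTruth(qtl=[], h2=0.0)
    df = nq.simulate_phenotype(family156, truth, seed=21)
    res = nq.marker_scan(df.set_index("genotype")["trait"], family156)
    # under the null the minimum p over 200 markers is rarely extreme
    assert np.nanmin(res.p_values) > 1e-6


def test_phenotype_realized_r2_matches_target():
    """Single QTL targeting 12% of variance realizes R^2 ~ 0.12 at n=1000."""
    gmap = nq.simulate_map(1, 5, 20.0, seed=30)
    geno = nq.simulate_ril_family(gmap, 1000, seed=31)
    r2s = []
    for s in range(5):
        df = nq.simulate_phenotype(geno, nq.SimTruth(qtl=[(2, 1.0)], h2=0.12), seed=40 + s)
        y = df["trait"].to_numpy()
        x = geno.codes[:, 2]
        r2s.append(np.corrcoef(x, y)[0, 1] ** 2)
    assert abs(np.mean(r2s) - 0.12) < 0.03


def test_phenotype_heritability_calibration(family156):
    """Realized heritability across replicates stays within 3 SE of target."""
    truth = nq.SimTruth(qtl=[(10, 1.0), (100, 0.8)], h2=0.3)
    x = family156.codes[:, [10, 100]] @ np.array([1.0, 0.8])
    r2 = []
    for s in range(30):
        df = nq.simulate_phenotype(family156, truth, seed=100 + s)
        y = df["trait"].to_numpy()
        resid = y - x
        r2.append(np.var(x) / (np.var(x) + np.var(resid)))
    se = np.std(r2, ddof=1) / np.sqrt(len(r2))
    assert abs(np.mean(r2) - 0.3) <= 3 * se


def test_phenotype_deterministic(family156, qtl_pheno):
    y1, truth = qtl_pheno
    y2 = nq.simulate_phenotype(family156, truth, seed=3).set_index("genotype")["trait"]
    assert y1.equals(y2)


def test_phenotype_family_offsets(nam_panel):
    offs = {"CML103": 2.0, "CML333": -1.0, "NC358": 0.0, "Tx303": 5.0}
    truth = nq.SimTruth(qtl=[], h2=0.0, family_offsets=offs, null_sd=0.1)
    df = nq.simulate_phenotype(nam_panel, truth, seed=2)
    means = df.groupby("family")["trait"].mean()
    for f, o in offs.items():
        assert abs(means[f] - o) < 0.05


# ---------------------------------------------------------------- field trial

def _genotype_values(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "genotype": [f"g{i:03d}" for i in range(n)],
            "family": ["famA"] * (n // 2) + ["famB"] * (n - n // 2),
            "trait": rng.normal(size=n),
        }
    )


def test_field_trial_noiseless_recovers_values():
    vals = _genotype_values(60)
    design = nq.FieldDesign(years=(1,), block_effect_sd=0.0, year_effect_sd=0.0,
                            residual_sd=0.0)
    plots = nq.simulate_field_trial(vals, design, seed=1)
    test_plots = plots[~plots["is_check"]].set_index("genotype")
    truth = vals.set_index("genotype")["trait"]
    assert np.allclose(test_plots["trait"], truth.loc[test_plots.index])


def test_field_trial_block_and_check_structure():
    vals = _genotype_values(200)
    design = nq.FieldDesign(block_size=22, checks_per_block=2, years=(1, 2))
    plots = nq.simulate_field_trial(vals, design, seed=2)
    y1 = plots[plots["year"] == 1]
    assert y1["block"].nunique() == 10
    # 2 of 22 plots per block are checks (~10%)
    assert abs(plots["is_check"].mean() - 2 / 22) < 1e-9
    # the common parent appears in every block
    for (_, _), blk in plots.groupby(["year", "block"]):
        assert "B73" in set(blk["genotype"])
        assert (blk["is_check"]).sum() == 2


def test_field_trial_deterministic():
    vals = _genotype_values(60)
    design = nq.FieldDesign(years=(1, 2))
    a = nq.simulate_field_trial(vals, design, seed=5)
    b = nq.simulate_field_trial(vals, design, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_field_trial_too_few_genotypes():
    vals = _genotype_values(10)
    with pytest.raises(ValueError):
        nq.simulate_field_trial(vals, nq.FieldDesign(block_size=22, checks_per_block=2), seed=0)


def test_field_design_invariants():
    with pytest.raises(ValueError):
        nq.FieldDesign(block_size=2, checks_per_block=2)
    with pytest.raises(ValueError):
        nq.FieldDesign(residual_sd=-1.0)
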