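"""Synthetic NAM/RIL data generator.

Generates the inputs the mapping models assume: multi-chromosome genetic
maps, selfed recombinant-inbred-line (RIL) genotypes from biparental
crosses sharing a common parent, additive trait values with a target
heritability, and plot-level observations from an augmented
incomplete-block field trial (blocks of test lines plus replicated
checks, multiple years).

RIL transmission model
----------------------
Genotypes along a chromosome follow the two-state (near-fixed) RIL Markov
chain: the first marker is 0 or 2 with probability 1/2, and adjacent
markers at genetic distance d cM switch state with probability

    R = 2r / (1 + 2r),   r = (1 - exp(-2 d / 100)) / 2   (Haldane),

the classical recombination fraction between fully inbred selfed RILs
under no crossover interference (map expansion relative to a single
meiosis). Residual heterozygosity is injected afterwards as independent
per-cell replacement with code 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FieldDesign, GeneticMap, GenotypeMatrix, SimTruth

__all__ = [
    "haldane_r",
    "ril_recombination_fraction",
    "simulate_map",
    "simulate_ril_family",
    "simulate_nam",
    "simulate_phenotype",
    "simulate_field_trial",
]

PHYSICAL_BP_PER_CM = 1_000_000  # reporting-only convention: 1 Mb per cM


def haldane_r(d_cm) -> np.ndarray:
    """Single-meiosis recombination fraction from Haldane's map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recombination_fraction(d_cm) -> np.ndarray:
    """Expected recombination fraction between selfed RILs, R = 2r/(1+2r)."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    mean_spacing_cm: float,
    seed,
) -> GeneticMap:
    """Simulate an approximately evenly spaced multi-chromosome genetic map.

    Adjacent spacings are jittered uniformly and rescaled so that the mean
    spacing on every chromosome equals ``mean_spacing_cm`` exactly.
    Physical positions are genetic positions scaled by 1 Mb/cM (physical
    coordinates are used only for ordering and reporting).
    """
    if n_chromosomes < 1 or markers_per_chromosome < 2:
        raise ValueError("need >= 1 chromosome and >= 2 markers per chromosome")
    if mean_spacing_cm <= 0:
        raise ValueError("mean spacing must be positive")
    rng = np.random.default_rng(seed)
    ids, chroms, gpos = [], [], []
    k = markers_per_chromosome
    counter = 1
    for c in range(1, n_chromosomes + 1):
        gaps = rng.uniform(0.5, 1.5, size=k - 1)
        gaps *= mean_spacing_cm * (k - 1) / gaps.sum()
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        for p in pos:
            ids.append(f"m{counter:04d}")
            counter += 1
        chroms.extend([c] * k)
        gpos.extend(pos)
    gpos = np.asarray(gpos)
    phys = np.rint(gpos * PHYSICAL_BP_PER_CM).astype(np.int64) + 1  # 1-based bp
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms), gpos, phys)


def _family_codes(rng: np.random.Generator, gmap: GeneticMap, n_rils: int,
                  residual_het_rate: float) -> np.ndarray:
    codes = np.empty((n_rils, gmap.n_markers))
    for c in np.unique(gmap.chromosome):
        cols = np.flatnonzero(gmap.chromosome == c)
        d = np.diff(gmap.genetic_pos[cols])
        R = ril_recombination_fraction(d)
        state = rng.random(n_rils) < 0.5  # True -> alternative-parent allele
        block = np.empty((n_rils, cols.size), dtype=bool)
        block[:, 0] = state
        for j in range(1, cols.size):
            switch = rng.random(n_rils) < R[j - 1]
            block[:, j] = block[:, j - 1] ^ switch
        codes[:, cols] = block * 2.0
    if residual_het_rate > 0:
        het = rng.random(codes.shape) < residual_het_rate
        codes[het] = 1.0
    return codes


def simulate_ril_family(
    gmap: GeneticMap,
    n_rils: int,
    residual_het_rate: float = 0.001,
    seed=0,
    family: str = "fam1",
    ref_parent: str = "B73",
) -> GenotypeMatrix:
    """Simulate one biparental selfed RIL family on a genetic map.

    Codes are 0 (common-parent homozygote) or 2 (alternative-parent
    homozygote) with residual heterozygous calls (code 1) at rate
    ``residual_het_rate``.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if n_rils < 1:
        raise ValueError("n_rils must be >= 1")
    if not 0.0 <= residual_het_rate < 0.5:
        raise ValueError("residual_het_rate must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _family_codes(rng, gmap, n_rils, residual_het_rate)
    ril_ids = np.array([f"{family}_r{i + 1:04d}" for i in range(n_rils)], dtype=object)
    alleles = _marker_alleles(rng, gmap.n_markers)
    return GenotypeMatrix(
        codes,
        ril_ids,
        np.array([family] * n_rils, dtype=object),
        gmap,
        ref_parent=ref_parent,
        alt_parents={family: f"{family}_founder"},
        ref_alleles=alleles[0],
        alt_alleles=alleles[1],
    )


def _marker_alleles(rng: np.random.Generator, m: int):
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    return ref.astype(object), alt.astype(object)


def simulate_nam(
    gmap: GeneticMap,
    family_specs: Sequence,
    residual_het_rate: float = 0.001,
    seed=0,
    ref_parent: str = "B73",
) -> GenotypeMatrix:
    """Simulate a NAM panel: several RIL families sharing a common parent.

    ``family_specs`` is a sequence of ``(family_name, n_rils)``. Families
    are drawn sequentially from a single random stream, so a one-family
    panel reproduces :func:`simulate_ril_family` with the same seed.
    """
    if len(family_specs) < 1:
        raise ValueError("at least one family required")
    names = [f for f, _ in family_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names")
    rng = np.random.default_rng(seed)
    parts = [
        simulate_ril_family(gmap, n, residual_het_rate, rng, family=name,
                            ref_parent=ref_parent)
        for name, n in family_specs
    ]
    codes = np.vstack([p.codes for p in parts])
    ril_ids = np.concatenate([p.ril_ids for p in parts])
    family = np.concatenate([p.family for p in parts])
    alt_parents = {}
    for p in parts:
        alt_parents.update(p.alt_parents)
    return GenotypeMatrix(
        codes, ril_ids, family, gmap,
        ref_parent=ref_parent,
        alt_parents=alt_parents,
        ref_alleles=parts[0].ref_alleles,
        alt_alleles=parts[0].alt_alleles,
    )


def simulate_phenotype(
    geno: GenotypeMatrix,
    truth: SimTruth,
    seed=0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Simulate genotype-level trait values from an additive QTL model.

    ``y_i = family_offset + sum_k a_k x_ik + e_i`` with normal residuals
    scaled so the QTL genetic values account for the target fraction
    ``truth.h2`` of phenotypic variance (computed from the realized
    genetic-value variance, so the expected marker R^2 matches the
    target). With ``h2 == 0`` the phenotype is family offsets plus pure
    noise of sd ``truth.null_sd``; with ``h2 == 1`` it is an exact linear
    function of the QTL codes.

    Returns a genotype-level table with columns ``genotype``, ``family``
    and the trait.
    """
    truth.validate_for(geno)
    rng = np.random.default_rng(seed)
    g = np.zeros(geno.n_rils)
    for i, a in truth.qtl:
        x = geno.codes[:, i]
        if np.isnan(x).any():
            raise ValueError("QTL marker has missing genotype codes")
        g += a * x
    var_g = float(np.var(g))
    if truth.h2 == 0.0:
        y = rng.normal(0.0, truth.null_sd, size=geno.n_rils)
    elif truth.h2 == 1.0:
        if var_g == 0.0:
            raise ValueError("h2 = 1 requires nonzero genetic variance")
        y = g.copy()
    else:
        sd_e = np.sqrt(var_g * (1.0 - truth.h2) / truth.h2)
        y = g + rng.normal(0.0, sd_e, size=geno.n_rils)
    offsets = np.array([truth.family_offsets.get(f, 0.0) for f in geno.family])
    y = y + offsets
    return pd.DataFrame({"genotype": geno.ril_ids, "family": geno.family, trait: y})


def simulate_field_trial(
    genotype_values: pd.DataFrame,
    design: FieldDesign,
    seed=0,
    trait: str = "trait",
    checks: dict | None = None,
    common_check: str = "B73",
) -> pd.DataFrame:
    """Lay out an augmented incomplete-block trial and add design noise.

    Test genotypes are randomized into blocks of ``design.entries_per_block``
    entries; every block additionally carries ``checks_per_block`` check
    plots — the common parent plus, when families are labelled, one
    rotating founder check. Observation = genotype value + year effect +
    block-within-year effect + residual.

    ``checks`` maps check names to their genotype values; by default the
    common parent is assigned the grand mean of the test genotypes and
    each ``<family>_founder`` the corresponding family mean (a RIL family
    mean approximates the midparent).

    Returns a plot-level table: genotype, family, year, block, is_check,
    trait.
    """
    df = genotype_values
    n_geno = len(df)
    if n_geno < design.entries_per_block:
        raise ValueError("fewer genotypes than one block of test entries")
    values = dict(zip(df["genotype"], df[trait]))
    fam_of = dict(zip(df["genotype"], df.get("family", pd.Series(["-"] * n_geno))))
    if checks is None:
        checks = {common_check: float(df[trait].mean())}
        if "family" in df.columns:
            for fam, sub in df.groupby("family", sort=True):
                checks[f"{fam}_founder"] = float(sub[trait].mean())
    check_names = [c for c in checks if c != common_check]
    rng = np.random.default_rng(seed)
    rows = []
    for year in design.years:
        order = rng.permutation(n_geno)
        year_eff = rng.normal(0.0, design.year_effect_sd) if len(design.years) > 1 else 0.0
        n_blocks = int(np.ceil(n_geno / design.entries_per_block))
        for b in range(n_blocks):
            entries = order[b * design.entries_per_block:(b + 1) * design.entries_per_block]
            block_id = f"b{b + 1:03d}"
            block_eff = rng.normal(0.0, design.block_effect_sd)
            plot_geno = [df["genotype"].iloc[i] for i in entries]
            block_checks = [common_check]
            while len(block_checks) < design.checks_per_block:
                if check_names:
                    block_checks.append(check_names[(b + len(block_checks) - 1) % len(check_names)])
                else:
                    block_checks.append(common_check)
            for name in plot_geno + block_checks:
                is_check = name in checks
                base = checks[name] if is_check else values[name]
                obs = base + year_eff + block_eff + rng.normal(0.0, design.residual_sd)
                rows.append(
                    {
                        "genotype": name,
                        "family": "check" if is_check else fam_of[name],
                        "year": year,
                        "block": block_id,
                        "is_check": is_check,
                        trait: obs,
                    }
                )
    return pd.DataFrame(rows)
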