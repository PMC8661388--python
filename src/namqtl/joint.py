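"""Joint-linkage QTL mapping across NAM families.

The joint model regresses the phenotype on a family mean term plus
marker-within-family slopes,

    y ~ family + marker:family  (+ conditioned markers nested in family),

so every QTL is allowed a distinct allelic effect in each biparental
family while the family term absorbs between-family mean differences.
The test for a marker is the joint partial F-test over its family-nested
slope block (degrees of freedom = number of families where the marker
segregates). Because the nested columns of different families have
disjoint support, the fit decomposes into per-family regressions, which
is what the implementation exploits.

Permutation thresholds shuffle the phenotype within each family
independently (preserving family means exactly); the threshold is the
alpha-order statistic of the permutation distribution of the genome-wide
minimum p.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, QTLModel, QTLRecord, ScanConfig, ScanResult
from .scan import (
    _as_pheno,
    _cond_indices,
    _residualize,
    lod_support_interval,
    permutation_matrix,
)

__all__ = [
    "joint_scan",
    "joint_permutation_threshold",
    "joint_stepwise",
    "drop_family",
]

_COLLINEAR_REL_TOL = 1e-12


def _family_blocks(geno: GenotypeMatrix, ok: np.ndarray):
    fams = geno.families()
    return [(f, np.flatnonzero((geno.family == f) & ok)) for f in fams]


def joint_scan(pheno, geno: GenotypeMatrix, conditioned: Sequence = ()) -> ScanResult:
    """Scan every marker with the family + marker:family model.

    Returns per-marker p (joint F over the nested slope block) and
    LOD = (n/2) log10(RSS_reduced/RSS_full). Families where the test
    marker does not segregate (zero residual variance given the
    conditioned design) are dropped from the block, reducing its degrees
    of freedom; a marker segregating nowhere gets p = 1 with the
    collinear flag.
    """
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 phenotyped individuals")
    cond = _cond_indices(geno, conditioned)
    if np.isnan(geno.codes[ok]).any():
        raise ValueError("joint scan requires complete genotype codes; impute first")
    m = geno.n_markers
    blocks = _family_blocks(geno, ok)

    rss_red = 0.0
    rank_total = 0
    gains = np.zeros(m)
    nseg = np.zeros(m, dtype=int)
    ssx_raw_max = np.zeros(m)
    for _, rows in blocks:
        yf = y[rows]
        D = np.column_stack([np.ones(rows.size)] + [geno.codes[rows, c] for c in cond])
        R, rank = _residualize(D, np.column_stack([yf, geno.codes[rows]]))
        rank_total += rank
        ry = R[:, 0]
        RX = R[:, 1:]
        rss_red += float(ry @ ry)
        ssx = np.einsum("ij,ij->j", RX, RX)
        raw = np.var(geno.codes[rows], axis=0) * rows.size
        seg = ssx > _COLLINEAR_REL_TOL * np.maximum(raw, 1.0)
        cross = ry @ RX
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(seg, cross**2 / np.where(seg, ssx, 1.0), 0.0)
        gains += g
        nseg += seg.astype(int)
        ssx_raw_max = np.maximum(ssx_raw_max, raw)

    p_values = np.full(m, np.nan)
    lod = np.full(m, np.nan)
    collinear = np.zeros(m, dtype=bool)
    test_cols = np.setdiff1d(np.arange(m), np.array(cond, dtype=int))
    q = nseg[test_cols]
    dfe = n - rank_total - q
    rss_full = np.maximum(rss_red - gains[test_cols], 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (gains[test_cols] / np.maximum(q, 1)) / (rss_full / np.maximum(dfe, 1))
    pv = np.where((q > 0) & (dfe > 0), stats.f.sf(F, np.maximum(q, 1), np.maximum(dfe, 1)), 1.0)
    lods = np.where(q > 0, (n / 2.0) * np.log10(rss_red / rss_full), 0.0)
    p_values[test_cols] = pv
    lod[test_cols] = lods
    collinear[test_cols] = q == 0
    return ScanResult(geno.gmap, p_values, lod, list(conditioned), n, collinear)


def joint_permutation_threshold(
    pheno, geno: GenotypeMatrix, conditioned: Sequence, config: ScanConfig
) -> float:
    """Threshold from within-family phenotype permutations of the joint scan."""
    k = int(np.ceil(config.alpha * config.n_permutations))
    if k < 1 or config.n_permutations * config.alpha < 1:
        raise ValueError("n_permutations * alpha must be >= 1 for the quantile")
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    rng = np.random.default_rng(config.seed)
    fams_ok = np.asarray(geno.family)[ok]
    idx = permutation_matrix(rng, n, config.n_permutations, fams_ok)
    cond = _cond_indices(geno, conditioned)

    if cond:
        sub = geno.subset_rils(np.flatnonzero(ok))
        yok = y[ok]
        minima = np.empty(config.n_permutations)
        for p in range(config.n_permutations):
            perm_geno = sub.subset_rils(np.arange(n))
            perm_geno.codes = perm_geno.codes.copy()
            perm_geno.codes[:, cond] = sub.codes[idx[p]][:, cond]
            res = joint_scan(yok[idx[p]], perm_geno, conditioned)
            minima[p] = np.nanmin(res.p_values)
        minima.sort()
        return float(minima[k - 1])

    yok = y[ok]
    m = geno.n_markers
    blocks = _family_blocks(geno, ok)
    # center within family once; permuting within family preserves centering
    ycf = yok.copy()
    pos_of = np.flatnonzero(ok)
    row_in_ok = {r: i for i, r in enumerate(pos_of)}
    P = config.n_permutations
    rss_red = 0.0
    gains = np.zeros((P, m))
    nseg = np.zeros(m, dtype=int)
    rank_total = 0
    fam_slices = []
    for f, rows in blocks:
        loc = np.array([row_in_ok[r] for r in rows])
        ycf[loc] -= ycf[loc].mean()
        fam_slices.append((f, rows, loc))
    Yperm = ycf[idx]  # (P, n), still within-family centered
    for f, rows, loc in fam_slices:
        Xf = geno.codes[rows]
        Xc = Xf - Xf.mean(axis=0)
        ssx = np.einsum("ij,ij->j", Xc, Xc)
        raw = np.var(Xf, axis=0) * rows.size
        seg = ssx > _COLLINEAR_REL_TOL * np.maximum(raw, 1.0)
        yv = Yperm[:, loc]
        rss_red += float(np.einsum("j,j->", ycf[loc], ycf[loc]))
        cross = yv @ Xc
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(seg[None, :], cross**2 / np.where(seg, ssx, 1.0)[None, :], 0.0)
        gains += g
        nseg += seg.astype(int)
        rank_total += 1
    q = nseg
    dfe = n - rank_total - q
    rss_full = np.maximum(rss_red - gains, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (gains / np.maximum(q, 1)[None, :]) / (rss_full / np.maximum(dfe, 1)[None, :])
    pv = np.where(
        ((q > 0) & (dfe > 0))[None, :],
        stats.f.sf(F, np.maximum(q, 1)[None, :], np.maximum(dfe, 1)[None, :]),
        1.0,
    )
    minima = pv.min(axis=1)
    minima.sort()
    return float(minima[k - 1])


def _per_family_fit(y, geno: GenotypeMatrix, markers: Sequence, ok: np.ndarray):
    """Per-family OLS of the final nested model; returns effects, marginal p, RSS."""
    cols = _cond_indices(geno, markers)
    effects = {}
    marg_p = {}
    rss = 0.0
    for f, rows in _family_blocks(geno, ok):
        yf = y[rows]
        D = np.column_stack([np.ones(rows.size)] + [geno.codes[rows, c] for c in cols])
        coef, _, rank, _ = np.linalg.lstsq(D, yf, rcond=None)
        resid = yf - D @ coef
        rss_f = float(resid @ resid)
        rss += rss_f
        dfe = rows.size - rank
        if dfe > 0 and rss_f > 0:
            s2 = rss_f / dfe
            XtX_inv = np.linalg.pinv(D.T @ D)
            se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
            t = coef / se
            pvals = 2.0 * stats.t.sf(np.abs(t), dfe)
        else:
            pvals = np.ones(len(coef))
        for k_i, mk in enumerate(markers):
            effects[(mk, f)] = float(coef[k_i + 1])
            marg_p[(mk, f)] = float(pvals[k_i + 1])
    return effects, marg_p, rss


def joint_stepwise(pheno, geno: GenotypeMatrix, config: ScanConfig,
                   threshold: float | None = None) -> QTLModel:
    """Forward stepwise joint-linkage mapping with family-nested effects.

    Selection mirrors single-family stepwise but on joint-scan p-values,
    with the threshold from within-family permutations. Each record
    reports the assigned family (the family whose nested effect has the
    smallest marginal p in the final model), that family's effect size,
    cumulative TPVE (variance explained by the QTL terms beyond family
    means, as a percent of total phenotypic variance), and the 1-LOD
    interval from a final conditional joint scan. The full nested-effect
    table is attached as ``nested_effects``.
    """
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    if threshold is None:
        threshold = joint_permutation_threshold(pheno, geno, (), config)
    selected: list = []
    step_p: list = []
    max_steps = config.max_steps if config.max_steps is not None else geno.n_markers
    while len(selected) < max_steps:
        scan = joint_scan(pheno, geno, selected)
        j = scan.best_marker()
        pj = scan.p_values[j]
        if not pj < threshold:
            break
        selected.append(str(geno.gmap.marker_id[j]))
        step_p.append(float(pj))
        if config.recompute_threshold:
            threshold = joint_permutation_threshold(pheno, geno, selected, config)

    yok_all = y[ok]
    tss = float(np.sum((yok_all - yok_all.mean()) ** 2))
    _, _, rss_fam = _per_family_fit(y, geno, [], ok)
    effects, marg_p, _ = _per_family_fit(y, geno, selected, ok)

    records = []
    nested_rows = []
    for step, mk in enumerate(selected, start=1):
        jdx = geno.gmap.index_of(mk)
        _, _, rss_step = _per_family_fit(y, geno, selected[:step], ok)
        tpve = 100.0 * (rss_fam - rss_step) / tss if tss > 0 else 0.0
        fam_ps = {f: marg_p[(mk, f)] for f, _ in _family_blocks(geno, ok)}
        assigned = min(fam_ps, key=lambda f: (fam_ps[f], str(f)))
        others = [m for m in selected if m != mk]
        cond_scan = joint_scan(pheno, geno, others)
        interval = lod_support_interval(cond_scan, mk, config.lod_drop)
        records.append(
            QTLRecord(
                step=step,
                marker_id=mk,
                family=str(assigned),
                chromosome=int(geno.gmap.chromosome[jdx]),
                peak_position_mb=float(geno.gmap.physical_pos[jdx] / 1e6),
                p_value=step_p[step - 1],
                tpve=tpve,
                effect_size=effects[(mk, assigned)],
                interval_mb=interval,
            )
        )
        for f, _ in _family_blocks(geno, ok):
            nested_rows.append(
                {
                    "marker": mk,
                    "family": f,
                    "effect": effects[(mk, f)],
                    "p_marginal": marg_p[(mk, f)],
                }
            )
    _, _, rss_final = _per_family_fit(y, geno, selected, ok)
    final_r2 = (1.0 - rss_final / tss) if tss > 0 else 0.0
    nested = pd.DataFrame(nested_rows, columns=["marker", "family", "effect", "p_marginal"])
    return QTLModel(records=records, threshold=threshold, final_r2=final_r2, nested_effects=nested)


def drop_family(geno: GenotypeMatrix, pheno, family_name: str):
    """Remove one family's rows from the genotype matrix and phenotype."""
    rows = geno.rows_of(family_name)  # KeyError if unknown
    keep = np.setdiff1d(np.arange(geno.n_rils), rows)
    y = _as_pheno(pheno, geno)
    sub = geno.subset_rils(keep)
    return sub, pd.Series(y[keep], index=sub.ril_ids)
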