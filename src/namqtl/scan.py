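"""Single-family QTL mapping by marker regression and stepwise selection.

The scan regresses the phenotype on each marker's 0/1/2 code (optionally
conditioning on an already-selected marker set), records the partial
F-test p-value for the test marker, and derives a LOD score from the
nested linear models,

    LOD = (n/2) * log10(RSS_reduced / RSS_full).

Genome-wide significance is the empirical alpha-quantile of the minimum
p-value over random phenotype permutations (order statistic
ceil(alpha * n_perm) of the sorted minima). Forward stepwise selection
adds the minimum-p marker while it beats the threshold; the final model
reports per-step p-values, cumulative TPVE (100 * R^2 of the model up to
that step), effect sizes from the joint final model (trait units per
allele-code unit; positive = alternative-parent allele increases the
trait), and 1-LOD support intervals from a conditional scan.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import GeneticMap, GenotypeMatrix, QTLModel, QTLRecord, ScanConfig, ScanResult

__all__ = [
    "marker_scan",
    "permutation_threshold",
    "stepwise_qtl",
    "compute_tpve",
    "lod_support_interval",
]

_COLLINEAR_REL_TOL = 1e-12


def _as_pheno(pheno, geno: GenotypeMatrix) -> np.ndarray:
    """Align a phenotype vector (array or Series indexed by RIL id) to rows."""
    if hasattr(pheno, "reindex"):
        y = pheno.reindex(geno.ril_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(pheno, dtype=float)
        if y.shape != (geno.n_rils,):
            raise ValueError("phenotype length does not match genotype rows")
    return y


def _cond_indices(geno: GenotypeMatrix, conditioned: Sequence) -> list:
    idx = []
    for m in conditioned:
        idx.append(geno.gmap.index_of(m) if isinstance(m, str) else int(m))
    return idx


def _residualize(D: np.ndarray, M: np.ndarray):
    """Residuals of columns of M on the design D, plus rank(D)."""
    coef, _, rank, _ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef, rank


def marker_scan(pheno, geno: GenotypeMatrix, conditioned: Sequence = ()) -> ScanResult:
    """Scan every marker outside ``conditioned`` for association.

    Fits phenotype ~ intercept + conditioned markers + test marker (all as
    numeric codes); p is the partial F-test for the test marker. Rows with
    missing phenotype are dropped; rows missing the test marker's genotype
    are dropped for that marker only. A test marker collinear with the
    conditioned design gets p = 1 with the ``collinear`` flag.
    """
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    cond = _cond_indices(geno, conditioned)
    X = geno.codes
    yok = y[ok]
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 phenotyped individuals")
    if np.var(yok) == 0:
        raise ValueError("phenotype is constant")

    m = geno.n_markers
    p_values = np.full(m, np.nan)
    lod = np.full(m, np.nan)
    collinear = np.zeros(m, dtype=bool)
    test_cols = np.setdiff1d(np.arange(m), np.array(cond, dtype=int))

    Xok = X[ok]
    if not np.isnan(Xok[:, test_cols]).any() and not np.isnan(Xok[:, cond]).any():
        # fast path: no missing genotypes
        D = np.column_stack([np.ones(n)] + [Xok[:, j] for j in cond])
        R, rank = _residualize(D, np.column_stack([yok, Xok[:, test_cols]]))
        ry = R[:, 0]
        RX = R[:, 1:]
        ssy = float(ry @ ry)
        ssx = np.einsum("ij,ij->j", RX, RX)
        ssx_raw = np.var(Xok[:, test_cols], axis=0) * n
        cross = ry @ RX
        dfe = n - rank - 1
        if dfe <= 0:
            raise ValueError("no residual degrees of freedom for the scan")
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ssx > 0, cross**2 / (ssy * np.where(ssx > 0, ssx, 1.0)), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        bad = ssx <= _COLLINEAR_REL_TOL * np.maximum(ssx_raw, 1.0)
        F = dfe * r2 / (1.0 - r2)
        pv = stats.f.sf(F, 1, dfe)
        lods = -(n / 2.0) * np.log10(1.0 - r2)
        pv[bad] = 1.0
        lods[bad] = 0.0
        p_values[test_cols] = pv
        lod[test_cols] = lods
        collinear[test_cols] = bad
        return ScanResult(geno.gmap, p_values, lod, list(conditioned), n, collinear)

    # general path: per-marker row masks
    for j in test_cols:
        rows = ok & ~np.isnan(X[:, j])
        for c in cond:
            rows &= ~np.isnan(X[:, c])
        nj = int(rows.sum())
        if nj < 3:
            p_values[j] = 1.0
            collinear[j] = True
            lod[j] = 0.0
            continue
        yj = y[rows]
        D = np.column_stack([np.ones(nj)] + [X[rows, c] for c in cond])
        R, rank = _residualize(D, np.column_stack([yj, X[rows, j]]))
        ry, rx = R[:, 0], R[:, 1]
        ssy = float(ry @ ry)
        ssx = float(rx @ rx)
        ssx_raw = float(np.var(X[rows, j]) * nj)
        dfe = nj - rank - 1
        if ssx <= _COLLINEAR_REL_TOL * max(ssx_raw, 1.0) or dfe <= 0:
            p_values[j] = 1.0
            lod[j] = 0.0
            collinear[j] = True
            continue
        r2 = min((ry @ rx) ** 2 / (ssy * ssx), 1.0 - 1e-15)
        F = dfe * r2 / (1.0 - r2)
        p_values[j] = stats.f.sf(F, 1, dfe)
        lod[j] = -(nj / 2.0) * np.log10(1.0 - r2)
    return ScanResult(geno.gmap, p_values, lod, list(conditioned), n, collinear)


def permutation_matrix(rng: np.random.Generator, n: int, n_perm: int,
                       families: np.ndarray | None = None) -> np.ndarray:
    """Row-permutation indices, shuffling within family blocks when given.

    With ``families=None`` (or a single family) each row is a uniform
    permutation of all indices; otherwise indices are permuted within each
    family independently, preserving every family's phenotype mean exactly.
    """
    idx = np.tile(np.arange(n), (n_perm, 1))
    if families is None:
        groups = [np.arange(n)]
    else:
        fams = np.asarray(families)
        groups = [np.flatnonzero(fams == f) for f in dict.fromkeys(fams)]
    for p in range(n_perm):
        for rows in groups:
            idx[p, rows] = rows[rng.permutation(rows.size)]
    return idx


def _scan_min_p_vectorized(Yperm: np.ndarray, Xc: np.ndarray, n: int) -> np.ndarray:
    """Minimum single-marker p per permuted phenotype (no conditioning).

    ``Yperm`` rows are centered permuted phenotypes; ``Xc`` columns are
    centered marker codes.
    """
    ssy = np.einsum("ij,ij->i", Yperm, Yperm)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    poly = ssx > 0
    cross = Yperm @ Xc[:, poly]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cross**2 / (ssy[:, None] * ssx[poly][None, :])
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    dfe = n - 2
    F = dfe * r2 / (1.0 - r2)
    pv = stats.f.sf(F, 1, dfe)
    return pv.min(axis=1)


def permutation_threshold(
    pheno, geno: GenotypeMatrix, conditioned: Sequence, config: ScanConfig,
    families: np.ndarray | None = None,
) -> float:
    """Genome-wide p-value threshold from phenotype permutations.

    For each permutation the phenotype is shuffled across RILs (within
    family blocks when ``families`` is given, preserving family means) and
    the scan's minimum p recorded; the threshold is the order statistic
    ceil(alpha * n_perm) of the sorted minima. When ``conditioned`` is
    non-empty the conditioned marker rows are permuted together with the
    phenotype, preserving their joint relationship.
    """
    k = int(np.ceil(config.alpha * config.n_permutations))
    if k < 1 or config.n_permutations * config.alpha < 1:
        raise ValueError("n_permutations * alpha must be >= 1 for the quantile")
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    yok = y[ok]
    n = int(ok.sum())
    rng = np.random.default_rng(config.seed)
    fams = None if families is None else np.asarray(families)[ok]
    idx = permutation_matrix(rng, n, config.n_permutations, fams)

    cond = _cond_indices(geno, conditioned)
    if not cond and not np.isnan(geno.codes[ok]).any():
        Xc = geno.codes[ok] - geno.codes[ok].mean(axis=0)
        Yperm = yok[idx] - yok.mean()
        minima = _scan_min_p_vectorized(Yperm, Xc, n)
    else:
        sub = geno.subset_rils(np.flatnonzero(ok))
        minima = np.empty(config.n_permutations)
        for p in range(config.n_permutations):
            # permute phenotype and conditioned-marker rows together,
            # leaving the test markers in place
            perm_geno = sub.subset_rils(np.arange(n))
            if cond:
                perm_geno.codes = perm_geno.codes.copy()
                perm_geno.codes[:, cond] = sub.codes[idx[p]][:, cond]
            res = marker_scan(yok[idx[p]], perm_geno, conditioned)
            minima[p] = np.nanmin(res.p_values)
    minima.sort()
    return float(minima[k - 1])


def compute_tpve(pheno, geno: GenotypeMatrix, markers: Sequence) -> float:
    """Total percent of variation explained: 100 * R^2 of the joint model."""
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    if not markers:
        return 0.0
    cols = _cond_indices(geno, markers)
    X = geno.codes[ok][:, cols]
    rows = ~np.isnan(X).any(axis=1)
    yv = y[ok][rows]
    D = np.column_stack([np.ones(rows.sum()), X[rows]])
    resid, _ = _residualize(D, yv[:, None])
    tss = float(np.sum((yv - yv.mean()) ** 2))
    rss = float(resid[:, 0] @ resid[:, 0])
    if tss == 0:
        return 0.0
    return 100.0 * (1.0 - rss / tss)


def lod_support_interval(scan: ScanResult, peak_marker: str, lod_drop: float = 1.0):
    """1-LOD (or ``lod_drop``-LOD) support interval around a peak marker.

    Returns the physical positions (Mb) of the leftmost and rightmost
    markers of the maximal contiguous run around the peak whose LOD stays
    within ``lod_drop`` of the peak's LOD, restricted to the peak's
    chromosome. Conditioned markers (no LOD of their own) do not break
    the run.
    """
    gmap = scan.gmap
    j = gmap.index_of(peak_marker)  # KeyError if absent
    if np.isnan(scan.lod[j]):
        raise ValueError(f"peak marker {peak_marker!r} was not scanned")
    chrom = gmap.chromosome[j]
    cols = np.flatnonzero(gmap.chromosome == chrom)
    lods = scan.lod[cols]
    peak_pos = int(np.flatnonzero(cols == j)[0])
    peak_lod = lods[peak_pos]
    keep = np.isnan(lods) | (lods >= peak_lod - lod_drop)
    left = peak_pos
    while left > 0 and keep[left - 1]:
        left -= 1
    right = peak_pos
    while right < len(cols) - 1 and keep[right + 1]:
        right += 1
    pos_mb = gmap.physical_pos[cols] / 1e6
    return float(pos_mb[left]), float(pos_mb[right])


def _final_effects(pheno, geno: GenotypeMatrix, markers: Sequence) -> np.ndarray:
    y = _as_pheno(pheno, geno)
    ok = ~np.isnan(y)
    cols = _cond_indices(geno, markers)
    X = geno.codes[ok][:, cols]
    rows = ~np.isnan(X).any(axis=1)
    D = np.column_stack([np.ones(int(rows.sum())), X[rows]])
    coef, _, _, _ = np.linalg.lstsq(D, y[ok][rows], rcond=None)
    return coef[1:]


def stepwise_qtl(pheno, geno: GenotypeMatrix, config: ScanConfig,
                 threshold: float | None = None) -> QTLModel:
    """Forward stepwise QTL selection against a permutation threshold.

    Scans, takes the minimum-p marker (ties broken by lowest chromosome
    then position), and accepts it while its p-value beats the
    permutation threshold; the threshold is computed once from the
    unconditioned scan unless ``config.recompute_threshold``. Each
    accepted record carries the p-value at its acceptance step, the
    cumulative TPVE after that step, the effect size from the final joint
    model, and a 1-LOD support interval from a final scan conditioned on
    the other selected markers.
    """
    fams = geno.families()
    family_label = fams[0] if len(fams) == 1 else "pooled"
    if threshold is None:
        threshold = permutation_threshold(pheno, geno, (), config)
    selected: list = []
    step_p: list = []
    max_steps = config.max_steps if config.max_steps is not None else geno.n_markers
    while len(selected) < max_steps:
        scan = marker_scan(pheno, geno, selected)
        j = scan.best_marker()
        pj = scan.p_values[j]
        if not pj < threshold:
            break
        selected.append(str(geno.gmap.marker_id[j]))
        step_p.append(float(pj))
        if config.recompute_threshold:
            threshold = permutation_threshold(pheno, geno, selected, config)

    effects = _final_effects(pheno, geno, selected) if selected else np.array([])
    records = []
    for step, mk in enumerate(selected, start=1):
        j = geno.gmap.index_of(mk)
        others = [m for m in selected if m != mk]
        cond_scan = marker_scan(pheno, geno, others)
        interval = lod_support_interval(cond_scan, mk, config.lod_drop)
        records.append(
            QTLRecord(
                step=step,
                marker_id=mk,
                family=family_label,
                chromosome=int(geno.gmap.chromosome[j]),
                peak_position_mb=float(geno.gmap.physical_pos[j] / 1e6),
                p_value=step_p[step - 1],
                tpve=compute_tpve(pheno, geno, selected[:step]),
                effect_size=float(effects[step - 1]),
                interval_mb=interval,
            )
        )
    final_r2 = compute_tpve(pheno, geno, selected) / 100.0
    return QTLModel(records=records, threshold=threshold, final_r2=final_r2)
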