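"""Best linear unbiased estimates (BLUEs) of genotype trait values.

Model: plot observation = genotype (fixed) + year (random) + block nested
within year (random) + residual. Variance components are estimated by
REML with the residual variance profiled out, leaving a two-dimensional
optimization over the variance ratios gamma_year = s2_year/s2_e and
gamma_block = s2_block/s2_e (log-parametrized, so components are floored
at zero). Genotype estimates are the generalized-least-squares solution
at the converged components under cell-means coding, i.e. each BLUE is
the genotype's estimated expected value at average random effects
(least-squares-means convention). With a single year the year component
is dropped automatically.

Replicated check genotypes shared across blocks connect the incomplete
blocks; a disconnected design triggers a warning (estimates are still
returned, but contrasts across disconnected groups are not estimable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = ["BLUEResult", "fit_blue"]

_LOG_GAMMA_BOUNDS = (-16.0, 12.0)
_CONV_TOL = 1e-10
_MAX_ITER = 200


@dataclass
class BLUEResult:
    """Genotype BLUEs with standard errors and REML variance components."""

    blues: pd.DataFrame  # index genotype; columns: blue, se
    varcomp: dict  # year, block_within_year, residual
    n_obs: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return self.blues.reset_index().rename(columns={"index": "genotype"})


def _check_connectivity(df: pd.DataFrame) -> bool:
    """Union-find over blocks joined by genotypes appearing in >1 block."""
    blocks = {b: i for i, b in enumerate(df["_yb"].unique())}
    parent = list(range(len(blocks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for _, sub in df.groupby("genotype", sort=False):
        bs = [blocks[b] for b in sub["_yb"].unique()]
        for b in bs[1:]:
            ra, rb = find(bs[0]), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = {find(i) for i in range(len(blocks))}
    return len(roots) == 1


def _neg2_reml(log_gammas, y, X, ZZts):
    n, p = X.shape
    W = np.eye(n)
    for lg, ZZt in zip(np.clip(log_gammas, *_LOG_GAMMA_BOUNDS), ZZts):
        W += np.exp(lg) * ZZt
    L = linalg.cholesky(W, lower=True)
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    XtX = Xt.T @ Xt
    beta = linalg.solve(XtX, Xt.T @ yt, assume_a="pos")
    r = yt - Xt @ beta
    rss = max(float(r @ r), 1e-300)
    logdet_W = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf, None
    val = logdet_W + logdet_XtX + (n - p) * np.log(rss)
    return val, (beta, rss, XtX)


def fit_blue(table: pd.DataFrame, trait: str) -> BLUEResult:
    """Fit the genotype-fixed / year + block-within-year random model.

    ``table`` needs columns ``genotype``, ``year``, ``block`` and the
    trait; multiple plants measured within a (genotype, year, block) plot
    are averaged to one plot value before fitting. Returns genotype BLUEs
    with standard errors and the REML variance components.
    """
    required = {"genotype", "year", "block", trait}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"trait table lacks columns: {sorted(missing_cols)}")
    df = table.dropna(subset=[trait]).copy()
    if df.empty:
        raise ValueError("no observations for trait")
    # average plants within plot
    df = (
        df.groupby(["genotype", "year", "block"], sort=False, as_index=False)[trait]
        .mean()
    )
    df["_yb"] = df["year"].astype(str) + ":" + df["block"].astype(str)

    genotypes = pd.Index(df["genotype"].unique())
    years = pd.Index(df["year"].unique())
    yb = pd.Index(df["_yb"].unique())
    n = len(df)
    p = len(genotypes)
    if n - p <= 0:
        raise ValueError("zero residual degrees of freedom (no replication)")
    if not _check_connectivity(df):
        warnings.warn(
            "incomplete blocks are not connected by shared genotypes; "
            "genotype comparisons across groups are not estimable",
            UserWarning,
        )

    y = df[trait].to_numpy(dtype=float)
    X = (df["genotype"].to_numpy()[:, None] == genotypes.to_numpy()[None, :]).astype(float)
    Zs, names = [], []
    if len(years) > 1:
        Zs.append((df["year"].to_numpy()[:, None] == years.to_numpy()[None, :]).astype(float))
        names.append("year")
    if len(yb) > 1:
        Zs.append((df["_yb"].to_numpy()[:, None] == yb.to_numpy()[None, :]).astype(float))
        names.append("block_within_year")

    converged = True
    ZZts = [Z @ Z.T for Z in Zs]
    if Zs:
        obj = lambda lg: _neg2_reml(lg, y, X, ZZts)[0]
        x0 = np.zeros(len(Zs))
        res = optimize.minimize(
            obj,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": _CONV_TOL, "maxiter": _MAX_ITER * len(Zs)},
        )
        converged = bool(res.success)
        log_g = np.clip(res.x, *_LOG_GAMMA_BOUNDS)
    else:
        log_g = np.array([])

    _, aux = _neg2_reml(log_g, y, X, ZZts)
    beta, rss, XtX = aux
    sigma_e2 = rss / (n - p)
    gammas = np.exp(log_g)
    # floor negligible components at exactly zero for reporting
    comps = {name: (0.0 if g < 1e-8 else float(g * sigma_e2)) for name, g in zip(names, gammas)}
    varcomp = {
        "year": comps.get("year", 0.0),
        "block_within_year": comps.get("block_within_year", 0.0),
        "residual": float(sigma_e2),
    }
    cov = sigma_e2 * linalg.inv(XtX)
    blues = pd.DataFrame(
        {"blue": beta, "se": np.sqrt(np.diag(cov))}, index=genotypes
    )
    blues.index.name = "genotype"
    return BLUEResult(blues=blues, varcomp=varcomp, n_obs=n, converged=converged)
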