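"""Pearson trait correlations with Holm familywise-error adjustment.

Correlations between genotype-level trait means (e.g. delta-13C vs SLA
and leaf elemental concentrations) are computed pairwise on the
genotypes where both traits are observed; two-sided p-values come from
the exact t-distribution of the Pearson statistic, and Holm's step-down
adjustment is applied across all off-diagonal pairs tested. A strict
listwise-complete mode (all traits observed) is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationResult", "holm_adjust", "pearson_matrix"]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Equivalent to sorting ascending and taking
    ``adj_(i) = max_{j<=i} min(1, (m-j+1) * p_(j))``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class CorrelationResult:
    """Pairwise correlation matrices: r, n used, raw and Holm-adjusted p."""

    traits: list
    r: pd.DataFrame
    n_used: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    degenerate: list = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        rows = []
        ts = self.traits
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                a, b = ts[i], ts[j]
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "n": int(self.n_used.loc[a, b]),
                        "r": self.r.loc[a, b],
                        "p_raw": self.p_raw.loc[a, b],
                        "p_holm": self.p_adjusted.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def pearson_matrix(
    traits: pd.DataFrame,
    trait_names: Sequence | None = None,
    listwise: bool = False,
) -> CorrelationResult:
    """Pearson correlation matrix over genotype-level trait means.

    ``traits`` is a wide table (one row per genotype, one column per
    trait; a ``genotype`` column, if present, is ignored as an index).
    Each pair uses the genotypes where both traits are observed
    (``listwise=True`` restricts to genotypes complete for *all* requested
    traits). Pairs with fewer than 3 complete observations or a
    zero-variance trait get ``r = nan`` and are listed in ``degenerate``;
    Holm adjustment spans all testable off-diagonal pairs.
    """
    df = traits.copy()
    if "genotype" in df.columns:
        df = df.set_index("genotype")
    names = list(trait_names) if trait_names is not None else list(df.columns)
    df = df[names]
    if listwise:
        df = df.dropna()
    k = len(names)
    r = np.full((k, k), np.nan)
    n_used = np.zeros((k, k), dtype=int)
    p_raw = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p_raw, 0.0)
    degenerate = []
    pairs = []
    for i in range(k):
        n_used[i, i] = df[names[i]].notna().sum()
        for j in range(i + 1, k):
            sub = df[[names[i], names[j]]].dropna()
            n = len(sub)
            n_used[i, j] = n_used[j, i] = n
            x = sub[names[i]].to_numpy(dtype=float)
            y = sub[names[j]].to_numpy(dtype=float)
            if n < 3 or np.var(x) == 0 or np.var(y) == 0:
                degenerate.append((names[i], names[j]))
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p_raw[i, j] = p_raw[j, i] = res.pvalue
            pairs.append((i, j))
    p_adj = np.full((k, k), np.nan)
    np.fill_diagonal(p_adj, 0.0)
    if pairs:
        adj = holm_adjust([p_raw[i, j] for i, j in pairs])
        for (i, j), a in zip(pairs, adj):
            p_adj[i, j] = p_adj[j, i] = a

    def f(a):
        return pd.DataFrame(a, index=names, columns=names)

    return CorrelationResult(
        traits=names,
        r=f(r),
        n_used=f(n_used),
        p_raw=f(p_raw),
        p_adjusted=f(p_adj),
        degenerate=degenerate,
    )
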