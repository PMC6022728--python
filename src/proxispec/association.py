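"""Associate vegetation indices with plot attributes.

Continuous traits are related to each index by the Pearson correlation,
with a two-sided p-value from the exact t transform
``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.  Discrete
traits use classical one-way ANOVA: ``F = (SSB/(g-1)) / (SSW/(n-g))`` with
p from the F(g-1, n-g) distribution.  Both statistics are computed directly
from their defining sums so the scipy implementations remain available as
independent cross-checks.

Because a sweep spans up to 140 indices, raw p-values are always
accompanied by Benjamini–Hochberg adjusted values.  Missing index values
are dropped pairwise per index; indices with too little data or zero
variance yield a missing result carrying the reason.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import UsageError

logger = logging.getLogger(__name__)

__all__ = ["correlate", "anova_oneway", "associate"]

_RESULT_COLUMNS = ["method", "statistic", "p_value", "adjusted_p_value", "n_used", "note"]


def _finish(rows: dict[str, dict]) -> pd.DataFrame:
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=_RESULT_COLUMNS)
    out.index.name = "index"
    ok = out["p_value"].notna()
    if ok.any():
        adj = multipletests(out.loc[ok, "p_value"].to_numpy(), method="fdr_bh")[1]
        out.loc[ok, "adjusted_p_value"] = adj
    return out


def correlate(index_matrix: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of every index column against a continuous trait.

    Returns one row per index with columns
    ``method, statistic (r), p_value, adjusted_p_value, n_used, note``.
    Pairwise-complete observations are used; indices with fewer than 3
    complete pairs or zero variance give a missing result with a reason.
    """
    trait = pd.to_numeric(trait.reindex(index_matrix.index), errors="coerce")
    rows: dict[str, dict] = {}
    for name in index_matrix.columns:
        x = pd.to_numeric(index_matrix[name], errors="coerce")
        ok = x.notna() & trait.notna()
        n = int(ok.sum())
        row = {"method": "pearson", "statistic": np.nan, "p_value": np.nan,
               "adjusted_p_value": np.nan, "n_used": n, "note": ""}
        if n < 3:
            row["note"] = "insufficient complete pairs"
            logger.warning("correlate: %s skipped (%d complete pairs)", name, n)
        else:
            xv = x[ok].to_numpy(dtype=float)
            yv = trait[ok].to_numpy(dtype=float)
            sx = xv.std(ddof=1)
            sy = yv.std(ddof=1)
            if sx == 0 or sy == 0:
                row["note"] = "zero variance"
                logger.warning("correlate: %s skipped (zero variance)", name)
            else:
                r = float(np.cov(xv, yv, ddof=1)[0, 1] / (sx * sy))
                r = max(-1.0, min(1.0, r))
                row["statistic"] = r
                if abs(r) == 1.0:
                    row["p_value"] = 0.0
                else:
                    t = r * math.sqrt((n - 2) / (1 - r * r))
                    row["p_value"] = 2 * _sps.t.sf(abs(t), df=n - 2)
        rows[name] = row
    return _finish(rows)


def anova_oneway(index_matrix: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of every index column across a discrete trait's levels.

    Levels with fewer than 2 complete observations are dropped with a
    warning; if fewer than 2 levels remain, or the within-group variance is
    zero, the index's result is missing with a reason.
    """
    trait = trait.reindex(index_matrix.index)
    rows: dict[str, dict] = {}
    for name in index_matrix.columns:
        x = pd.to_numeric(index_matrix[name], errors="coerce")
        ok = x.notna() & trait.notna()
        row = {"method": "anova", "statistic": np.nan, "p_value": np.nan,
               "adjusted_p_value": np.nan, "n_used": int(ok.sum()), "note": ""}
        groups = []
        for level, sub in x[ok].groupby(trait[ok].astype(str)):
            if len(sub) < 2:
                logger.warning(
                    "anova: %s level %r dropped (<2 observations)", name, level
                )
                continue
            groups.append(sub.to_numpy(dtype=float))
        if len(groups) < 2:
            row["note"] = "fewer than 2 usable levels"
            row["n_used"] = int(sum(len(g) for g in groups))
            rows[name] = row
            continue
        n = sum(len(g) for g in groups)
        g = len(groups)
        row["n_used"] = int(n)
        grand = sum(gr.sum() for gr in groups) / n
        ssb = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
        ssw = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
        if ssw == 0:
            row["note"] = "zero within-group variance"
            logger.warning("anova: %s skipped (zero within-group variance)", name)
        else:
            F = (ssb / (g - 1)) / (ssw / (n - g))
            row["statistic"] = float(F)
            row["p_value"] = float(_sps.f.sf(F, g - 1, n - g))
        rows[name] = row
    return _finish(rows)


def associate(
    index_matrix: pd.DataFrame,
    attributes,
    trait_name: str,
    method: str = "auto",
) -> pd.DataFrame:
    """Dispatch to pearson/anova based on the attribute's type tag."""
    from .io import CONTINUOUS

    trait = attributes.values_for(list(index_matrix.index), trait_name)
    tag = attributes.type_of(trait_name)
    if method == "auto":
        method = "pearson" if tag == CONTINUOUS else "anova"
    if method == "pearson":
        if tag != CONTINUOUS:
            raise UsageError(
                f"attribute {trait_name!r} is discrete; correlation requires a "
                "continuous trait"
            )
        return correlate(index_matrix, trait)
    if method == "anova":
        if tag == CONTINUOUS:
            raise UsageError(
                f"attribute {trait_name!r} is continuous; one-way ANOVA requires "
                "a discrete trait"
            )
        return anova_oneway(index_matrix, trait)
    raise UsageError(f"unknown association method {method!r}")
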