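"""N-way fixed-effects ANOVA with eta-squared effect sizes and
Bonferroni-corrected post-hoc mean comparisons.

The observation unit is one voxel inside a lobule mask, its response being
that voxel's field value (Ex, Ey, Ez or Enorm in V/m); factors are the
lobule, the montage and optionally the head model.  Lobule voxel counts are
inherently unbalanced, so Type III sums of squares (with sum-to-zero factor
coding) are the default; the type is switchable and recorded in the result.
Classical eta-squared is reported per term: eta^2 = SS_term / SS_total, the
proportion of total response variability attributable to the term.  Note the
decomposition SS_terms + SS_residual = SS_total is exact for Type I always
and for Type III only on balanced designs; the result carries the additivity
gap as a diagnostic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .phantom import ParcellationVolume
from .roi import FieldVolume

__all__ = [
    "AnovaResult",
    "anova_eta",
    "bonferroni_posthoc",
    "field_observations",
]


def field_observations(
    fieldvol: FieldVolume,
    parc: ParcellationVolume,
    montage: str,
    head_model: str | None = None,
    responses: tuple[str, ...] = ("Ex", "Ey", "Ez", "Enorm"),
    max_voxels_per_lobule: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long observation table: one row per valid voxel inside a lobule mask.

    ``max_voxels_per_lobule`` subsamples each lobule (seeded) to keep tables
    desk-sized; concatenate the frames of several montages/head models to
    build a factorial design.
    """
    comp = fieldvol.components()
    rng = np.random.default_rng(seed)
    frames = []
    for rid in parc.lobule_ids:
        sel = (parc.labels == rid) & fieldvol.mask
        idx = np.nonzero(sel.ravel())[0]
        if idx.size == 0:
            continue
        if max_voxels_per_lobule is not None and idx.size > max_voxels_per_lobule:
            idx = rng.choice(idx, size=max_voxels_per_lobule, replace=False)
        row = {r: comp[r].ravel()[idx] for r in responses}
        row["lobule"] = parc.names.get(rid, f"region_{rid}")
        row["montage"] = montage
        if head_model is not None:
            row["head_model"] = head_model
        frames.append(pd.DataFrame(row))
    if not frames:
        raise ValueError("no valid voxels inside any lobule mask")
    return pd.concat(frames, ignore_index=True)


@dataclass
class AnovaResult:
    """Per-term decomposition with effect sizes.

    ``table`` columns: sum_sq, df, F, p, eta_sq (plus a Residual row).
    """

    table: pd.DataFrame
    ss_total: float
    ss_type: int
    response: str
    factors: tuple[str, ...]
    mse: float
    df_resid: float
    additivity_gap: float  # |sum SS - SS_total| / SS_total
    metadata: dict = field(default_factory=dict)

    def eta_squared(self, term: str) -> float:
        return float(self.table.loc[term, "eta_sq"])


def _check_estimable(table: pd.DataFrame, factors: list[str], interactions: bool) -> None:
    if not interactions or len(factors) < 2:
        return
    empty: list[tuple] = []
    for fa, fb in itertools.combinations(factors, 2):
        counts = table.groupby([fa, fb], observed=True).size()
        full = pd.MultiIndex.from_product(
            [table[fa].unique(), table[fb].unique()], names=[fa, fb]
        )
        missing = full.difference(counts.index)
        empty.extend(missing.tolist())
    if empty:
        raise ValueError(
            f"design has empty cells, interactions are inestimable: {empty[:20]}"
        )


def anova_eta(
    table: pd.DataFrame,
    response: str,
    factors: list[str] | tuple[str, ...],
    interactions: bool = True,
    ss_type: int = 3,
) -> AnovaResult:
    """Fixed-effects ANOVA of ``response`` on categorical ``factors`` with
    all main effects and (optionally) all pairwise interactions.

    eta^2 = SS_term / SS_total with SS_total the corrected total sum of
    squares.  Requires >= 2 levels per factor and >= 1 residual df.
    """
    factors = list(factors)
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor column {f!r} not in table")
        nlev = table[f].nunique()
        if nlev < 2:
            raise ValueError(f"factor {f!r} has {nlev} level(s); need >= 2")
    y = table[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    _check_estimable(table, factors, interactions)

    terms = [f"C(Q('{f}'), Sum)" for f in factors]
    rhs = " + ".join(terms)
    if interactions and len(factors) >= 2:
        rhs += " + " + " + ".join(
            f"{a}:{b}" for a, b in itertools.combinations(terms, 2)
        )
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=table).fit()
    if model.df_resid < 1:
        raise ValueError("saturated model: no residual degrees of freedom")
    aov = sm.stats.anova_lm(model, typ=ss_type)
    aov = aov.rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p", "df": "df"}
    )
    if "Intercept" in aov.index:
        aov = aov.drop(index="Intercept")

    # prettify term labels back to factor names
    def clean(term: str) -> str:
        out = term
        for f in factors:
            out = out.replace(f"C(Q('{f}'), Sum)", f)
        return out

    aov.index = [clean(t) for t in aov.index]
    ss_total = float(np.sum((y - y.mean()) ** 2))
    aov["eta_sq"] = aov["sum_sq"] / ss_total
    aov.loc["Residual", "eta_sq"] = np.nan
    resid_ss = float(aov.loc["Residual", "sum_sq"])
    df_resid = float(aov.loc["Residual", "df"])
    term_ss = float(aov.drop(index="Residual")["sum_sq"].sum())
    gap = abs(term_ss + resid_ss - ss_total) / ss_total if ss_total > 0 else 0.0

    if ss_total == 0:
        aov["eta_sq"] = aov["eta_sq"].fillna(0.0)
        aov.loc[aov.index != "Residual", "eta_sq"] = 0.0

    return AnovaResult(
        table=aov[["sum_sq", "df", "F", "p", "eta_sq"] if "F" in aov.columns else ["sum_sq", "df", "eta_sq"]],
        ss_total=ss_total,
        ss_type=ss_type,
        response=response,
        factors=tuple(factors),
        mse=resid_ss / df_resid if df_resid > 0 else np.nan,
        df_resid=df_resid,
        additivity_gap=gap,
        metadata={
            "observation_unit": "voxel",
            "coding": "sum-to-zero",
            "n_obs": int(len(table)),
        },
    )


def bonferroni_posthoc(
    table: pd.DataFrame,
    response: str,
    factor: str,
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """All pairwise mean comparisons of ``factor`` levels with
    Bonferroni-adjusted critical values at family level ``alpha``.

    Each of the k(k-1)/2 pairs is tested at alpha / m.  The standard error
    pools the fitted model's residual mean square when an
    :class:`AnovaResult` is given, otherwise the within-level variance of a
    one-way fit on ``factor``.  Returns level pairs, mean difference,
    adjusted confidence interval, adjusted p and a significance flag.
    """
    levels = list(pd.unique(table[factor]))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels for comparisons")
    groups = {lv: table.loc[table[factor] == lv, response].to_numpy(dtype=float) for lv in levels}
    if anova is not None:
        mse, dfr = anova.mse, anova.df_resid
    else:
        n_total = len(table)
        dfr = n_total - len(levels)
        if dfr < 1:
            raise ValueError("no residual degrees of freedom for the pooled variance")
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / dfr

    m = len(levels) * (len(levels) - 1) // 2
    alpha_adj = alpha / m
    tcrit = scipy.stats.t.ppf(1 - alpha_adj / 2, dfr)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ga, gb = groups[a], groups[b]
        diff = ga.mean() - gb.mean()
        se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
        if se == 0:
            tstat, p_raw = (np.inf if diff != 0 else 0.0), (0.0 if diff != 0 else 1.0)
        else:
            tstat = diff / se
            p_raw = 2 * scipy.stats.t.sf(abs(tstat), dfr)
        p_adj = min(1.0, p_raw * m)
        lo, hi = diff - tcrit * se, diff + tcrit * se
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": diff,
                "se": se,
                "t": tstat,
                "ci_low": lo,
                "ci_high": hi,
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["n_comparisons"] = m
    out.attrs["per_comparison_alpha"] = alpha_adj
    return out
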