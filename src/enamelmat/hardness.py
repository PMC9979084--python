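"""Vickers microhardness and factorial hardness statistics.

Hardness is analysed as a two-way factorial: animal age (weeks) crossed
with position relative to the gingival emergence plane (below / at / above,
i.e. pre-eruptive to post-eruptive). Sums of squares are Type III with
sum-to-zero contrasts — the convention of the commercial software the
protocol was designed around — so results are invariant to cell imbalance
in the usual marginal-means sense; for balanced designs Types I/II/III
coincide with the classical decomposition. Pairwise comparisons use the
Tukey (studentized range) adjustment, by default on the two-way model's
residual variance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .errors import EstimabilityError, ValidationError

#: Vickers geometry constant for load in gf and diagonals in um
VICKERS_CONSTANT = 1854.4

LEVELS = ("below", "at", "above")
REGIONS = ("inner", "mid", "outer")
SIDES = ("buccal", "lingual")

#: plausibility window for enamel hardness; values outside are flagged, kept
HV_PLAUSIBLE = (10.0, 600.0)

_SS_TOL = 1e-10


def vickers_hv(load_gf, mean_diagonal_um):
    """Vickers hardness number HV = 1854.4 * load / d^2.

    ``load_gf`` is the indentation load in gram-force, ``mean_diagonal_um``
    the mean of the two indent diagonals in micrometres. Accepts scalars or
    arrays.
    """
    load = np.asarray(load_gf, dtype=float)
    diag = np.asarray(mean_diagonal_um, dtype=float)
    if np.any(load <= 0) or np.any(diag <= 0):
        raise ValidationError("load and diagonal must be positive")
    out = VICKERS_CONSTANT * load / diag**2
    return float(out) if out.ndim == 0 else out


def flag_implausible_hv(table: pd.DataFrame, response: str = "hv") -> pd.Series:
    """Boolean Series marking HV values outside the plausibility window."""
    hv = table[response]
    return (hv < HV_PLAUSIBLE[0]) | (hv > HV_PLAUSIBLE[1])


def aggregate_by_animal(
    table: pd.DataFrame,
    factor_a: str = "age_weeks",
    factor_b: str = "level",
    response: str = "hv",
    animal_col: str = "animal_id",
) -> pd.DataFrame:
    """Mean response per animal x cell — one value per animal and level.

    Indent-level replicates within an animal are pseudo-replicates for
    between-animal inference; aggregating to animal means gives residual
    degrees of freedom of (number of animal-level observations) minus
    (number of cells), the convention behind site-mean F tests.
    """
    return (
        table.groupby([animal_col, factor_a, factor_b], as_index=False)[response]
        .mean()
    )


@dataclass
class EffectTest:
    """One ANOVA effect: sum of squares, df, F and p.

    ``infinite`` flags a perfect fit (zero residual variance with non-zero
    effect SS), where F is unbounded and p is reported as 0.
    """

    name: str
    ss: float
    df: int
    f: float
    p: float
    infinite: bool = False


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition with residual variance for post hocs."""

    effects: dict[str, EffectTest]
    df_resid: int
    ss_resid: float
    ss_total: float
    factor_a: str
    factor_b: str
    response: str
    ss_type: str = "III (sum-to-zero contrasts)"
    tukey: pd.DataFrame | None = None

    @property
    def ms_resid(self) -> float:
        return self.ss_resid / self.df_resid if self.df_resid > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": e.name, "ss": e.ss, "df": e.df, "F": e.f, "p": e.p}
            for e in self.effects.values()
        ]
        rows.append(
            {"effect": "residual", "ss": self.ss_resid, "df": self.df_resid,
             "F": np.nan, "p": np.nan}
        )
        return pd.DataFrame(rows)


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "age_weeks",
    factor_b: str = "level",
    response: str = "hv",
    aggregate: str | None = None,
) -> AnovaResult:
    """Two-way ANOVA with interaction, Type III SS, sum-to-zero contrasts.

    ``aggregate`` may name an identifier column (e.g. ``"animal_id"``): the
    table is first reduced to per-identifier cell means, which is how
    indent-level tables are conventionally analysed between animals.
    Unbalanced designs are allowed; empty cells raise
    :class:`EstimabilityError` because the interaction is inestimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if aggregate is not None:
        table = aggregate_by_animal(
            table, factor_a=factor_a, factor_b=factor_b,
            response=response, animal_col=aggregate,
        )
    for col in (factor_a, factor_b, response):
        if col not in table.columns:
            raise ValidationError(f"table lacks column {col!r}")
    if table[factor_a].nunique() < 2 or table[factor_b].nunique() < 2:
        raise ValidationError("each factor needs at least 2 levels")
    counts = table.groupby([factor_a, factor_b], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise EstimabilityError(
            "design has empty cells; interaction is not estimable"
        )

    y = table[response].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())

    formula = f"Q('{response}') ~ C(Q('{factor_a}'), Sum) * C(Q('{factor_b}'), Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits emit harmless RuntimeWarnings
        model = smf.ols(formula, data=table).fit()
        aov = sm.stats.anova_lm(model, typ=3)

    ss_resid = float(model.ssr)
    df_resid = int(model.df_resid)
    a_term = f"C(Q('{factor_a}'), Sum)"
    b_term = f"C(Q('{factor_b}'), Sum)"
    term_map = {
        a_term: factor_a,
        b_term: factor_b,
        f"{a_term}:{b_term}": "interaction",
    }
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    degenerate_resid = ss_resid <= _SS_TOL * max(ss_total, 1.0)
    effects: dict[str, EffectTest] = {}
    for term, name in term_map.items():
        ss = float(aov.loc[term, "sum_sq"])
        df = int(aov.loc[term, "df"])
        if ss <= _SS_TOL * max(ss_total, 1.0):
            f_val, p_val, inf = 0.0, 1.0, False
        elif degenerate_resid:
            f_val, p_val, inf = float("inf"), 0.0, True
        else:
            f_val = (ss / df) / ms_resid
            p_val = float(aov.loc[term, "PR(>F)"])
            inf = False
        effects[name] = EffectTest(name, ss, df, f_val, p_val, inf)
    return AnovaResult(
        effects=effects,
        df_resid=df_resid,
        ss_resid=ss_resid,
        ss_total=ss_total,
        factor_a=factor_a,
        factor_b=factor_b,
        response=response,
    )


def tukey_hsd(
    table: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    response: str = "hv",
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons of a factor with Tukey(-Kramer) adjustment.

    When an :class:`AnovaResult` is supplied its residual mean square and df
    are used (comparisons within the factorial model); otherwise the one-way
    within-group variance pooled over the factor's levels is used. Adjusted
    p-values come from the studentized range distribution with k = number of
    levels.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    groups = table.groupby(factor, observed=True)[response]
    means = groups.mean()
    ns = groups.size()
    k = len(means)
    if k < 2:
        raise ValidationError("factor needs at least 2 levels")
    if anova is not None:
        mse, df = anova.ms_resid, anova.df_resid
    else:
        df = int(ns.sum()) - k
        if df < 1:
            raise ValidationError("no residual degrees of freedom")
        mse = float(
            sum(((g - g.mean()) ** 2).sum() for _, g in groups) / df
        )
    rows = []
    levels = list(means.index)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[b] - means[a]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                q = np.inf if diff != 0 else 0.0
            else:
                q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
            p = min(max(p, 0.0), 1.0)
            rows.append(
                {"group1": a, "group2": b, "estimate": float(diff),
                 "se": float(se), "q": float(q), "p_adj": p,
                 "reject": p < alpha}
            )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["df_resid"] = df
    out.attrs["ms_resid"] = mse
    return out
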