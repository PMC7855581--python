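"""Group-level inference for the four genotype x sex groups.

The battery mirrors common practice for this kind of study: measures are
gated through a per-group normality check into either a one-way ANOVA with
Bonferroni-adjusted planned contrasts or a Kruskal-Wallis test with Dunn's
multiple-comparison z-tests; entries-to-criterion are compared with the
Mantel-Cox (log-rank) test with censoring; reversal-error counts get a
full-factorial genotype x sex x day ANOVA; and Y-maze alternation is
tested per group against chance with one-sample t-tests.  Planned
contrasts are restricted to the within-sex genotype pairs (wildtype vs mdx
for each sex); significance threshold 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CriterionResult, ValidationError

__all__ = [
    "GroupComparison",
    "MantelCoxResult",
    "PLANNED_PAIRS",
    "normality_gate",
    "compare_groups",
    "bonferroni",
    "mantel_cox",
    "three_way_errors",
    "one_sample_vs_chance",
]

PLANNED_PAIRS = (
    ("wildtype_male", "mdx_male"),
    ("wildtype_female", "mdx_female"),
)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Omnibus test plus planned within-sex contrasts for one measure."""

    measure: str
    test: str  # "one_way_anova" or "kruskal_wallis"
    statistic: float
    p_value: float
    adjustment: str  # "bonferroni" or "dunn"
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: List[str] = field(default_factory=list)


@dataclass
class MantelCoxResult:
    """Log-rank comparison of entries-to-criterion distributions."""

    statistic: Optional[float]
    p_value: Optional[float]
    df: int
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    note: Optional[str] = None


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: ``min(1, m * p)``."""
    return float(min(1.0, m * p_raw))


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------


def normality_gate(values_by_group: Mapping[str, Sequence[float]],
                   alpha: float = ALPHA) -> Tuple[str, pd.DataFrame]:
    """Choose the parametric or nonparametric branch for a measure.

    Shapiro-Wilk is run per group at ``alpha``; if any group fails (or is
    too small or degenerate to test), the measure is routed to the
    nonparametric branch.  Returns the decision plus the per-group test
    table.
    """
    rows = []
    decision = "parametric"
    for group, vals in values_by_group.items():
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            rows.append({"group": group, "n": len(vals), "W": np.nan,
                         "p": np.nan, "normal": False,
                         "note": "n < 3: forced nonparametric"})
            warnings.warn(f"group {group!r}: n < 3, forcing nonparametric branch",
                          stacklevel=2)
            decision = "nonparametric"
            continue
        if np.ptp(vals) == 0.0:
            rows.append({"group": group, "n": len(vals), "W": np.nan,
                         "p": np.nan, "normal": False,
                         "note": "degenerate (constant values)"})
            warnings.warn(f"group {group!r}: constant values, forcing "
                          "nonparametric branch", stacklevel=2)
            decision = "nonparametric"
            continue
        w, p = sps.shapiro(vals)
        ok = p >= alpha
        rows.append({"group": group, "n": len(vals), "W": float(w),
                     "p": float(p), "normal": bool(ok), "note": ""})
        if not ok:
            decision = "nonparametric"
    return decision, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# omnibus + planned contrasts
# ---------------------------------------------------------------------------


def _pooled_t_contrast(values_by_group, pair, m):
    """Two-group contrast using the pooled within-group variance (ANOVA MSE)."""
    all_groups = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    n_tot = sum(len(v) for v in all_groups.values())
    k = len(all_groups)
    mse = sum((len(v) - 1) * np.var(v, ddof=1) for v in all_groups.values())
    df = n_tot - k
    mse /= df
    a, b = (all_groups[g] for g in pair)
    se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
    if se == 0.0:
        t = 0.0
    else:
        t = (a.mean() - b.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p, bonferroni(p, m)


def _dunn_contrast(values_by_group, pair, m):
    """Dunn's z-test on joint ranks, with tie correction.

    Standard rank-sum multiple-comparison statistic:
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` with
    tie term ``T = sum(t^3 - t) / (12 (N - 1))``; p-values from the normal
    and Bonferroni-style multiplied by the number of planned comparisons.
    """
    groups = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in groups])
    ranks = sps.rankdata(pooled)
    n_tot = len(pooled)
    mean_ranks = {}
    start = 0
    for g in groups:
        n = len(values_by_group[g])
        mean_ranks[g] = ranks[start:start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_tot - 1))
    a, b = pair
    na, nb = len(values_by_group[a]), len(values_by_group[b])
    var = (n_tot * (n_tot + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
    if var <= 0:
        return 0.0, 1.0, 1.0
    z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p), bonferroni(p, m)


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   gate: Optional[str] = None,
                   measure: str = "measure",
                   planned_pairs: Optional[Iterable[Tuple[str, str]]] = None
                   ) -> GroupComparison:
    """Omnibus group comparison plus the two planned within-sex contrasts.

    ``gate`` is the branch decision from :func:`normality_gate` (computed
    here when omitted): the parametric branch runs a one-way ANOVA with
    Bonferroni-adjusted pooled-variance t contrasts, the nonparametric
    branch a Kruskal-Wallis test with Dunn's multiple-comparison z-tests.
    Planned pairs default to wildtype-vs-mdx within each sex, restricted to
    groups actually present.
    """
    groups = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    if not groups:
        raise ValidationError("no groups supplied")
    for g, v in groups.items():
        if len(v) == 0:
            raise ValidationError(f"group {g!r} is empty")
    if planned_pairs is None:
        planned_pairs = [p for p in PLANNED_PAIRS
                         if p[0] in groups and p[1] in groups]
    else:
        planned_pairs = list(planned_pairs)
        for pair in planned_pairs:
            for g in pair:
                if g not in groups:
                    raise ValidationError(f"planned contrast names missing group {g!r}")
    if gate is None:
        gate, _ = normality_gate(groups)
    m = max(len(planned_pairs), 1)
    notes: List[str] = []

    arrays = list(groups.values())
    degenerate = np.ptp(np.concatenate(arrays)) == 0.0
    if gate == "parametric":
        test, adj = "one_way_anova", "bonferroni"
        if degenerate:
            stat, p = 0.0, 1.0
            notes.append("degenerate: all values identical")
        else:
            stat, p = sps.f_oneway(*arrays)
        contrast_fn = _pooled_t_contrast
    else:
        test, adj = "kruskal_wallis", "dunn"
        if degenerate:
            stat, p = 0.0, 1.0
            notes.append("degenerate: all values identical")
        else:
            stat, p = sps.kruskal(*arrays)
        contrast_fn = _dunn_contrast

    rows = []
    for pair in planned_pairs:
        if degenerate:
            s, praw, padj = 0.0, 1.0, 1.0
        else:
            s, praw, padj = contrast_fn(groups, pair, m)
        rows.append({"contrast": f"{pair[0]} vs {pair[1]}",
                     "statistic": float(s), "p_raw": float(praw),
                     "p_adj": float(padj)})
    return GroupComparison(
        measure=measure, test=test, statistic=float(stat), p_value=float(p),
        adjustment=adj, contrasts=pd.DataFrame(rows), warnings=notes,
    )


# ---------------------------------------------------------------------------
# Mantel-Cox (log-rank)
# ---------------------------------------------------------------------------


def _as_survival_frame(results_by_group) -> pd.DataFrame:
    rows = []
    for group, results in results_by_group.items():
        for r in results:
            rows.append({"group": str(group), "duration": r.duration,
                         "event": bool(r.event)})
    return pd.DataFrame(rows)


def mantel_cox(results_by_group: Mapping[str, Iterable[CriterionResult]],
               pairwise_pairs: Optional[Iterable[Tuple[str, str]]] = None
               ) -> MantelCoxResult:
    """Log-rank test of entries-to-criterion distributions across groups.

    Computes the omnibus statistic over all supplied groups plus pairwise
    log-rank tests for the planned within-sex pairs (or any pairs given).
    Subjects that never reached the criterion enter as censored at their
    total entry count.  If no events were observed anywhere the statistic
    is undefined and reported as such rather than raising.
    """
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    results_by_group = {g: list(v) for g, v in results_by_group.items()}
    if len(results_by_group) < 2:
        raise ValidationError("need at least two groups for a log-rank test")
    df = _as_survival_frame(results_by_group)
    k = df["group"].nunique()
    if not df["event"].any():
        return MantelCoxResult(None, None, k - 1,
                               note="all subjects censored: log-rank undefined")
    res = multivariate_logrank_test(df["duration"], df["group"], df["event"])
    if pairwise_pairs is None:
        pairwise_pairs = [p for p in PLANNED_PAIRS
                          if p[0] in results_by_group and p[1] in results_by_group]
    rows = []
    for a, b in pairwise_pairs:
        da = df[df["group"] == a]
        db = df[df["group"] == b]
        if not (da["event"].any() or db["event"].any()):
            rows.append({"pair": f"{a} vs {b}", "statistic": np.nan, "p": np.nan})
            continue
        pr = logrank_test(da["duration"], db["duration"],
                          event_observed_A=da["event"],
                          event_observed_B=db["event"])
        rows.append({"pair": f"{a} vs {b}",
                     "statistic": float(pr.test_statistic),
                     "p": float(pr.p_value)})
    return MantelCoxResult(float(res.test_statistic), float(res.p_value),
                           k - 1, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# three-way ANOVA on reversal errors
# ---------------------------------------------------------------------------


def three_way_errors(errors: pd.DataFrame,
                     measures: Sequence[str] = ("perseverative", "neutral")
                     ) -> Dict[str, pd.DataFrame]:
    """Full-factorial genotype x sex x day ANOVA on reversal error counts.

    ``errors`` needs columns ``genotype``, ``sex``, ``day`` plus the error
    measures.  Day is a within-subject factor in the design but is analysed
    as a crossed factor here.  Raises if any design cell is empty, naming
    the cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"genotype", "sex", "day"}
    missing = required - set(errors.columns)
    if missing:
        raise ValidationError(f"errors table missing columns {sorted(missing)}")
    cells = errors.groupby(["genotype", "sex", "day"], observed=True).size()
    levels = [errors[c].unique() for c in ("genotype", "sex", "day")]
    for g in levels[0]:
        for s in levels[1]:
            for d in levels[2]:
                if (g, s, d) not in cells.index:
                    raise ValidationError(
                        f"empty design cell genotype={g!r}, sex={s!r}, day={d!r}"
                    )
    out: Dict[str, pd.DataFrame] = {}
    for measure in measures:
        if measure not in errors.columns:
            raise ValidationError(f"errors table missing measure {measure!r}")
        data = errors.rename(columns={measure: "y"})
        if np.ptp(data["y"].to_numpy(float)) == 0.0:
            warnings.warn(f"{measure}: degenerate (zero variance); "
                          "no effects estimable", stacklevel=2)
            table = pd.DataFrame(
                {"sum_sq": np.nan, "df": np.nan, "F": np.nan, "PR(>F)": np.nan},
                index=["C(genotype)", "C(sex)", "C(day)"],
            )
            out[measure] = table
            continue
        model = smf.ols("y ~ C(genotype) * C(sex) * C(day)", data=data).fit()
        out[measure] = sm.stats.anova_lm(model, typ=2)
    return out


# ---------------------------------------------------------------------------
# one-sample t against chance
# ---------------------------------------------------------------------------


def one_sample_vs_chance(values_by_group: Mapping[str, Sequence[float]],
                         chance_pct: float = 200.0 / 9.0) -> pd.DataFrame:
    """Per-group one-sample t-test of alternation percentage against chance.

    ``chance_pct`` defaults to the analytic 2/9 level (22.22%); pass 25.0
    to test against the permutation-style round figure instead.
    """
    rows = []
    for group, vals in values_by_group.items():
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValidationError(f"group {group!r}: need n >= 2 for a t-test")
        if np.ptp(vals) == 0.0:
            t = 0.0 if vals[0] == chance_pct else np.inf * np.sign(vals[0] - chance_pct)
            p = 1.0 if vals[0] == chance_pct else 0.0
        else:
            t, p = sps.ttest_1samp(vals, chance_pct)
        rows.append({"group": group, "n": len(vals), "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)), "t": float(t), "p": float(p),
                     "chance_pct": chance_pct})
    return pd.DataFrame(rows)
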