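"""Group-comparison statistics for the cohort analysis.

Implements the study's analysis plan: Shapiro–Wilk-gated choice between
one-way ANOVA (with Tukey HSD post-hoc) and Kruskal–Wallis (with Dunn's
post-hoc, Bonferroni-corrected) for three-group comparisons; normality-
gated two-group tests; two-way random-effects absolute-agreement
single-measures ICC (ICC(2,1)) for interobserver agreement; and the
ordinary least-squares association between horizontal rim width and lamina
curvature. No correction is applied across variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "GroupComparison",
    "ICCResult",
    "compare_three_groups",
    "compare_two_groups",
    "dunn_posthoc",
    "icc_two_observers",
    "regress_hrw_on_lcci",
    "build_tables",
]

ALPHA_DEFAULT = 0.05


class StatsError(ValueError):
    """Statistical routine cannot run on the given data."""


@dataclass
class GroupComparison:
    variable: str
    test_used: str  # "ANOVA" | "KruskalWallis"
    omnibus_p: float
    statistic: float
    pairwise: dict[tuple[str, str], float]
    pattern: str
    group_means: dict[str, float]


@dataclass
class ICCResult:
    variable: str
    icc: float
    ci_low: float
    ci_high: float


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in clean.items():
        if v.ndim != 1 or len(v) < 2:
            raise StatsError(f"group {name!r} needs >= 2 observations")
        if np.any(np.isnan(v)):
            raise StatsError(f"group {name!r} contains NaN")
    if all(np.var(v) == 0 for v in clean.values()):
        raise StatsError("zero variance in every group")
    return clean


def _all_normal(groups: dict[str, np.ndarray], alpha: float) -> bool:
    """Shapiro–Wilk gate: parametric tests only if every group passes."""
    for v in groups.values():
        if len(v) < 3 or np.var(v) == 0:
            return False
        if sps.shapiro(v).pvalue < alpha:
            return False
    return True


def dunn_posthoc(
    groups: dict[str, np.ndarray], correction: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise test after Kruskal–Wallis.

    z_ij = (mean rank_i − mean rank_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))
    with tie correction T = Σ(t³−t) / (12(N−1)); two-sided normal p-values,
    Bonferroni-multiplied over the number of pairs (clipped at 1).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        if se == 0:
            raise StatsError("degenerate rank variance in Dunn's test")
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if correction == "bonferroni":
            p = min(p * m, 1.0)
        out[(a, b)] = float(p)
    return out


def _pattern(
    means: dict[str, float],
    pairwise: dict[tuple[str, str], float],
    alpha: float,
) -> str:
    """Ordering string such as ``"A < B = C"`` from means and pairwise tests.

    Groups are sorted by mean; adjacent groups are joined with ``<`` only
    when their pairwise difference is significant at ``alpha``, else ``=``.
    """
    order = sorted(means, key=lambda g: means[g])

    def pair_p(a: str, b: str) -> float:
        return pairwise.get((a, b), pairwise.get((b, a), 1.0))

    parts = [order[0]]
    for prev, cur in zip(order, order[1:]):
        sig = pair_p(prev, cur) < alpha and means[prev] < means[cur]
        parts.append("<" if sig else "=")
        parts.append(cur)
    return " ".join(parts)


def compare_three_groups(
    groups: dict[str, np.ndarray],
    alpha: float = ALPHA_DEFAULT,
    posthoc: str | None = None,
) -> GroupComparison:
    """Normality-gated omnibus comparison of three groups with post-hoc pattern.

    If every group passes Shapiro–Wilk at ``alpha``: one-way ANOVA with
    Tukey HSD pairwise p-values. Otherwise: Kruskal–Wallis with Dunn's
    pairwise test (Bonferroni). ``posthoc`` may force ``"tukey"`` or
    ``"dunn"`` regardless of the gate.
    """
    clean = _check_groups(groups)
    if len(clean) != 3:
        raise StatsError(f"expected 3 groups, got {len(clean)}")
    names = list(clean)
    means = {g: float(np.mean(v)) for g, v in clean.items()}

    use_anova = _all_normal(clean, alpha)
    if use_anova:
        stat, p = sps.f_oneway(*clean.values())
        test = "ANOVA"
    else:
        stat, p = sps.kruskal(*clean.values())
        test = "KruskalWallis"

    method = posthoc or ("tukey" if use_anova else "dunn")
    if method == "tukey":
        res = sps.tukey_hsd(*clean.values())
        pairwise = {
            (names[i], names[j]): float(res.pvalue[i, j])
            for i, j in combinations(range(3), 2)
        }
    elif method == "dunn":
        pairwise = dunn_posthoc(clean)
    else:
        raise StatsError(f"unknown post-hoc method {method!r}")

    return GroupComparison(
        variable="",
        test_used=test,
        omnibus_p=float(p),
        statistic=float(stat),
        pairwise=pairwise,
        pattern=_pattern(means, pairwise, alpha),
        group_means=means,
    )


def compare_two_groups(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[float, str]:
    """Normality-gated two-group comparison; returns (two-sided p, test name).

    Unpaired: t-test (Welch) when both samples pass Shapiro–Wilk, else
    Mann–Whitney U. Paired: paired t-test when the differences pass, else
    Wilcoxon signed-rank. All-zero paired differences are a degenerate
    perfect-agreement case and return p = 1 (the Wilcoxon zero-rule leaves
    no ranks to test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each sample needs >= 2 observations")
    if paired:
        if len(x) != len(y):
            raise StatsError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return 1.0, "wilcoxon"
        if _all_normal({"d": d}, alpha):
            return float(sps.ttest_rel(x, y).pvalue), "paired_t"
        return float(sps.wilcoxon(x, y).pvalue), "wilcoxon"
    if _all_normal({"x": x, "y": y}, alpha):
        return float(sps.ttest_ind(x, y, equal_var=False).pvalue), "t"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue), "mannwhitney"


def icc_two_observers(
    obs1: np.ndarray, obs2: np.ndarray, variable: str = ""
) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    The standard model for interobserver agreement of continuous
    measurements; returns the ICC with its F-based 95% confidence bounds.
    """
    obs1 = np.asarray(obs1, dtype=float)
    obs2 = np.asarray(obs2, dtype=float)
    if obs1.shape != obs2.shape or obs1.ndim != 1 or len(obs1) < 3:
        raise StatsError("ICC needs two equal-length vectors with n >= 3")
    data = np.column_stack([obs1, obs2])
    if np.allclose(data, data.mean()):
        raise StatsError("zero total variance: ICC undefined")

    import pingouin as pg

    n = len(obs1)
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), 2),
            "raters": np.tile(["A", "B"], n),
            "score": data.reshape(-1),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # duplicated measurements give mse = 0: a legitimate degenerate case
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="score"
        ).set_index("Type")
    # absolute-agreement, single measures: labelled ICC(A,1) (= ICC(2,1))
    icc = float(tab.loc["ICC(A,1)", "ICC"])

    # Duplicated data gives a numerically exact 1 with a degenerate interval.
    if np.allclose(obs1, obs2):
        return ICCResult(variable=variable, icc=1.0, ci_low=1.0, ci_high=1.0)

    # 95% CI from the mean squares (McGraw & Wong); the library table only
    # reports the interval rounded to two decimals, too coarse near 1.
    k = 2
    grand = data.mean()
    msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    ss_err = np.sum((data - grand) ** 2) - (n - 1) * msr - (k - 1) * msc
    mse = ss_err / ((n - 1) * (k - 1))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * (k * icc * fj) ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = sps.f.ppf(0.975, n - 1, v)
    f_l = sps.f.ppf(0.975, v, n - 1)
    ci_low = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr
    )
    ci_low = min(float(ci_low), icc)
    ci_high = max(min(float(ci_high), 1.0), icc)
    return ICCResult(variable=variable, icc=icc, ci_low=ci_low, ci_high=ci_high)


def regress_hrw_on_lcci(
    table: pd.DataFrame,
    groups: tuple[str, ...] = ("NTG", "CRAO"),
    hrw_col: str = "mean_hrw",
    lcci_col: str = "mean_lcci",
) -> dict[str, float]:
    """OLS of horizontal rim width on lamina curvature, pooled over groups.

    Returns slope, intercept, r² and the two-sided p-value of the slope.
    """
    sub = table[table["group"].isin(groups)]
    if len(sub) < 3:
        raise StatsError("regression needs >= 3 rows")
    x = sub[lcci_col].to_numpy(dtype=float)
    y = sub[hrw_col].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise StatsError("constant predictor: regression undefined")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(len(sub)),
    }


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

ONH_TABLE_VARS = (
    ("disc_area", "Disc area, mm2"),
    ("ovality", "Disc ovality"),
    ("mean_hrw", "Mean HRW, um"),
    ("mean_mrw", "Mean MRW, um"),
    ("mean_hmr", "Mean HMR"),
    ("mean_lcci", "Mean LCCI"),
)
TEMPORAL_TABLE_VARS = (
    ("temporal_hrw", "Mean temporal HRW, um"),
    ("temporal_mrw", "Mean temporal MRW, um"),
    ("temporal_hmr", "Mean temporal HMR"),
)
CLINICAL_TABLE_VARS = (
    ("age", "Age, years"),
    ("spherical_equivalent", "Spherical equivalent, D"),
    ("iop_at_oct", "IOP at OCT, mmHg"),
    ("rnfl_global", "RNFL global, um"),
    ("rnfl_temporal_superior", "RNFL temporal-superior, um"),
    ("rnfl_temporal", "RNFL temporal, um"),
    ("rnfl_temporal_inferior", "RNFL temporal-inferior, um"),
    ("rnfl_nasal_inferior", "RNFL nasal-inferior, um"),
    ("rnfl_nasal", "RNFL nasal, um"),
    ("rnfl_nasal_superior", "RNFL nasal-superior, um"),
)


def build_tables(
    table: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    posthoc: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-variable group summaries (mean ± SD) with omnibus and post-hoc results.

    Emits three frames mirroring the study's reporting layout: clinical
    covariates, optic-nerve-head indices, and temporal-rim-only indices.
    ``table`` must carry ``group`` plus the variable columns (cohort merged
    with per-eye morphometry).
    """
    if "group" not in table.columns:
        raise StatsError("table is missing required column 'group'")
    groups_present = [g for g in ("NTG", "CRAO", "healthy") if g in set(table["group"])]
    out: dict[str, pd.DataFrame] = {}
    specs = {
        "clinical": CLINICAL_TABLE_VARS,
        "onh": ONH_TABLE_VARS,
        "temporal": TEMPORAL_TABLE_VARS,
    }
    for name, variables in specs.items():
        rows = []
        for col, label in variables:
            if col not in table.columns:
                raise StatsError(f"table is missing variable column {col!r}")
            row: dict[str, object] = {"variable": label}
            data = {
                g: table.loc[table["group"] == g, col].to_numpy(dtype=float)
                for g in groups_present
            }
            for g in groups_present:
                row[f"{g}_mean"] = float(np.mean(data[g]))
                row[f"{g}_sd"] = float(np.std(data[g], ddof=1))
            if col == "age" and {"NTG", "CRAO"} <= set(groups_present):
                # healthy fellow eyes share subject age with their CRAO
                # partner, so age is compared between the two subject groups
                p, test = compare_two_groups(data["NTG"], data["CRAO"], alpha=alpha)
                row["test"] = test
                row["p_value"] = p
                rows.append(row)
                continue
            if len(groups_present) == 3:
                cmp_res = compare_three_groups(data, alpha=alpha, posthoc=posthoc)
                row["test"] = cmp_res.test_used
                row["p_value"] = cmp_res.omnibus_p
                for (a, b), p in cmp_res.pairwise.items():
                    row[f"p_{a}_vs_{b}"] = p
                row["pattern"] = (
                    cmp_res.pattern if cmp_res.omnibus_p < alpha else ""
                )
            rows.append(row)
        out[name] = pd.DataFrame(rows)
    return out


def format_table_text(frames: dict[str, pd.DataFrame]) -> str:
    """Human-readable mean ± SD report of the frames from :func:`build_tables`."""
    lines: list[str] = []
    for name, df in frames.items():
        lines.append(f"== {name} ==")
        for _, row in df.iterrows():
            cells = [f"{row['variable']:<28s}"]
            for g in ("NTG", "CRAO", "healthy"):
                if f"{g}_mean" in row:
                    cells.append(f"{row[f'{g}_mean']:8.2f} ± {row[f'{g}_sd']:.2f}")
            if "p_value" in row and not pd.isna(row["p_value"]):
                p = row["p_value"]
                cells.append("P < 0.001" if p < 0.001 else f"P = {p:.3f}")
                if isinstance(row.get("pattern"), str) and row["pattern"]:
                    cells.append(row["pattern"])
            lines.append("  ".join(cells))
        lines.append("")
    return "\n".join(lines)
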