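"""Group-comparison statistics with normality gating.

Implements the decision scheme used throughout the mechanophenotyping
figures: samples are tested for normality (Shapiro–Wilk per group) before
analysis; normal data go to the parametric branch (t-test / ANOVA, with the
Welch and Brown–Forsythe corrections when group variances are unequal by
Levene's test) with Tukey or Dunnett post-hocs, non-normal data go to the
nonparametric branch (Mann–Whitney / Kruskal–Wallis with Dunn's pairwise
z-tests, Holm-adjusted). Paired first-vs-last comparisons use the Wilcoxon
signed-rank test with zeros dropped.

The omnibus machinery delegates to scipy/statsmodels/pingouin; the module's
own contribution is the gating scheme and Dunn's test (no installed
implementation exists), which is verified against rank oracles in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonDesign",
    "GateDecision",
    "StatResult",
    "normality_gate",
    "compare_groups",
    "paired_test",
    "dunn_posthoc",
]


@dataclass
class ComparisonDesign:
    """A labelled multi-group comparison.

    ``groups`` maps label → 1-D sample. ``reference_group`` switches the
    parametric post-hoc from all-pairs Tukey to Dunnett-vs-reference (and
    restricts Dunn's comparisons to the reference on the nonparametric
    branch). ``branch`` forces "parametric" or "nonparametric" explicitly —
    useful when the analysis protocol fixes the family up front — and
    defaults to the normality-gated choice.
    """

    groups: dict[str, np.ndarray]
    paired: bool = False
    reference_group: str | None = None
    alpha: float = 0.05
    branch: str | None = None

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if len(v) < 3:
                raise ValueError(f"group {k!r} has n < 3")
        if self.reference_group is not None and self.reference_group not in self.groups:
            raise ValueError(f"reference group {self.reference_group!r} absent")
        if self.branch not in (None, "parametric", "nonparametric"):
            raise ValueError(f"unknown branch {self.branch!r}")


@dataclass
class GateDecision:
    branch: str                      # "parametric" | "nonparametric"
    equal_variances: bool
    shapiro_p: dict[str, float]
    levene_p: float | None
    warnings: list[str] = field(default_factory=list)


@dataclass
class StatResult:
    family: str          # t | welch_t | anova | welch_bf_anova | mann_whitney
    #                    # | kruskal_wallis | wilcoxon_signed_rank
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None   # comparison, p_unadjusted, p_adjusted, method
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def normality_gate(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> GateDecision:
    """Choose the analysis branch.

    Shapiro–Wilk per group at ``alpha``; all groups normal → parametric,
    any non-normal → nonparametric. On the parametric branch Levene's test
    (median-centered) decides whether the Welch/Brown–Forsythe corrections
    are needed. A constant-valued group cannot be tested for normality and
    routes to the nonparametric branch with a warning.
    """
    notes: list[str] = []
    shapiro_p: dict[str, float] = {}
    all_normal = True
    for k, v in groups.items():
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            notes.append(f"group {k!r} is constant; normality untestable")
            warnings.warn(notes[-1])
            shapiro_p[k] = np.nan
            all_normal = False
            continue
        p = float(sps.shapiro(v).pvalue)
        shapiro_p[k] = p
        if p < alpha:
            all_normal = False
    if not all_normal:
        return GateDecision("nonparametric", False, shapiro_p, None, notes)
    lev = float(sps.levene(*groups.values(), center="median").pvalue)
    return GateDecision("parametric", lev >= alpha, shapiro_p, lev, notes)


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    res = sps.tukey_hsd(*groups.values())
    labels = list(groups)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "comparison": f"{labels[i]} vs {labels[j]}",
                    "p_unadjusted": np.nan,  # Tukey p is jointly adjusted
                    "p_adjusted": float(res.pvalue[i, j]),
                    "method": "tukey",
                }
            )
    return pd.DataFrame(rows)


def _dunnett(groups: dict[str, np.ndarray], reference: str) -> pd.DataFrame:
    others = {k: v for k, v in groups.items() if k != reference}
    res = sps.dunnett(*others.values(), control=groups[reference])
    rows = [
        {
            "comparison": f"{k} vs {reference}",
            "p_unadjusted": np.nan,  # Dunnett p is jointly adjusted
            "p_adjusted": float(p),
            "method": "dunnett",
        }
        for k, p in zip(others, res.pvalue)
    ]
    return pd.DataFrame(rows)


def dunn_posthoc(
    groups: dict[str, np.ndarray], reference: str | None = None
) -> pd.DataFrame:
    """Dunn's pairwise rank z-tests after Kruskal–Wallis, Holm-adjusted.

    The statistic for groups i, j is
    z = (R̄_i − R̄_j) / √[(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)],
    with R̄ the mean pooled mid-ranks and T = Σ(t³ − t) over tie groups.
    With ``reference`` given, only comparisons against it are made.
    """
    labels = list(groups)
    sizes = {k: len(groups[k]) for k in labels}
    pooled = np.concatenate([groups[k] for k in labels])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in labels:
        mean_rank[k] = float(np.mean(ranks[start : start + sizes[k]]))
        start += sizes[k]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var0 = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    pairs = (
        [(k, reference) for k in labels if k != reference]
        if reference is not None
        else [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    )
    rows = []
    for a, b in pairs:
        se = np.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"comparison": f"{a} vs {b}", "z": z, "p_unadjusted": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_unadjusted"], method="holm")[1]
    df["method"] = "dunn"
    return df[["comparison", "z", "p_unadjusted", "p_adjusted", "method"]]


def _welch_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    import pingouin as pg

    df = pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups), [len(v) for v in groups.values()]),
        }
    )
    res = pg.welch_anova(data=df, dv="value", between="group")
    return float(res["F"].iloc[0]), float(res["p-unc"].iloc[0])


def _brown_forsythe_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Brown–Forsythe F* ANOVA (heteroscedasticity-robust denominator)."""
    vals = list(groups.values())
    n = np.array([len(v) for v in vals], dtype=float)
    m = np.array([np.mean(v) for v in vals])
    s2 = np.array([np.var(v, ddof=1) for v in vals])
    N = n.sum()
    grand = np.sum(n * m) / N
    num = np.sum(n * (m - grand) ** 2)
    c = (1 - n / N) * s2
    den = c.sum()
    if den == 0:
        return np.nan, np.nan
    Fstar = num / den
    df2 = den**2 / np.sum(c**2 / (n - 1))
    p = float(sps.f.sf(Fstar, len(vals) - 1, df2))
    return float(Fstar), p


def compare_groups(design: ComparisonDesign) -> StatResult:
    """Run the gated comparison and the matching post-hoc.

    Two groups: t / Welch t / Mann–Whitney (or Wilcoxon signed-rank when
    paired). Three or more: ANOVA (+Tukey or Dunnett) on the parametric
    branch, Welch ANOVA (Brown–Forsythe F* reported alongside) when
    variances are unequal, Kruskal–Wallis + Dunn otherwise.
    """
    g = design.groups
    gate = normality_gate(g, design.alpha)
    if design.branch is not None:
        gate = GateDecision(design.branch, gate.equal_variances,
                            gate.shapiro_p, gate.levene_p,
                            gate.warnings + ["branch forced by design"])
    labels = list(g)
    two = len(g) == 2

    if design.paired and two:
        return paired_test(g[labels[0]], g[labels[1]])

    if gate.branch == "parametric":
        if two:
            equal = gate.equal_variances
            r = sps.ttest_ind(g[labels[0]], g[labels[1]], equal_var=equal)
            return StatResult(
                family="t" if equal else "welch_t",
                statistic=float(r.statistic),
                p=float(r.pvalue),
                extra={"gate": gate},
            )
        if gate.equal_variances:
            r = sps.f_oneway(*g.values())
            family, stat, p = "anova", float(r.statistic), float(r.pvalue)
        else:
            stat, p = _welch_anova(g)
            family = "welch_bf_anova"
        posthoc = (
            _dunnett(g, design.reference_group)
            if design.reference_group
            else _tukey(g)
        )
        extra = {"gate": gate}
        if family == "welch_bf_anova":
            extra["brown_forsythe"] = _brown_forsythe_anova(g)
        return StatResult(family, stat, p, posthoc=posthoc, extra=extra)

    # nonparametric branch
    if two:
        if np.ptp(np.concatenate(list(g.values()))) == 0:
            return StatResult("mann_whitney", np.nan, 1.0, degenerate=True,
                              extra={"gate": gate})
        r = sps.mannwhitneyu(g[labels[0]], g[labels[1]], alternative="two-sided")
        return StatResult("mann_whitney", float(r.statistic), float(r.pvalue),
                          extra={"gate": gate})
    if np.ptp(np.concatenate(list(g.values()))) == 0:
        return StatResult("kruskal_wallis", np.nan, 1.0, degenerate=True,
                          extra={"gate": gate})
    r = sps.kruskal(*g.values())
    posthoc = dunn_posthoc(g, design.reference_group)
    return StatResult(
        "kruskal_wallis", float(r.statistic), float(r.pvalue),
        posthoc=posthoc, extra={"gate": gate},
    )


def paired_test(before: np.ndarray, after: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon signed-rank on paired samples, zeros dropped.

    All-zero differences are a degenerate no-effect case reported as p = 1
    rather than an error. Uses the exact null distribution when feasible
    (small n, no ties), the normal approximation otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if len(before) < 6:
        raise ValueError("need at least 6 pairs")
    diff = after - before
    if np.all(diff == 0):
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, degenerate=True)
    r = sps.wilcoxon(before, after, zero_method="wilcox", method="auto")
    return StatResult(
        "wilcoxon_signed_rank", float(r.statistic), float(r.pvalue)
    )
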