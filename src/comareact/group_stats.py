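"""Between-group and condition-wise statistics.

Mann–Whitney U for morphometry comparisons; a classical mixed-design
(split-plot) repeated-measures ANOVA — one between factor GROUP, one within
factor CONDITION (rest + four stimulus types) — on electrode-averaged PSD;
Bonferroni-adjusted post-hoc pairwise comparisons against the appropriate
ANOVA error term.

The mixed ANOVA uses the textbook sums-of-squares decomposition: the
between-subjects factor is tested against subjects-within-groups error, the
within factor and the interaction against the condition × subject error.
No sphericity correction is applied by default (plain degrees of freedom,
as reported in the study design this mirrors); Greenhouse–Geisser is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Exact Mann–Whitney p-values are enumerated up to this combined size
#: (tie-free samples only); beyond it the normal approximation with tie and
#: continuity corrections is used.
EXACT_LIMIT = 12


@dataclass
class TestResult:
    """One test: statistic, df, p, and an effect descriptor."""

    name: str                      # statistic name: U, Z, F or t
    statistic: float
    p: float
    df: tuple[int, ...] | None = None
    effect: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def mann_whitney_u(sample_a, sample_b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U by rank summation with midrank ties.

    The p-value is exact (full enumeration) when the combined sample size
    is at most 12 and there are no ties, otherwise a normal approximation
    with tie and continuity corrections.  The standardized Z is reported
    alongside U in the effect descriptor.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= EXACT_LIMIT and not has_ties) \
        else "asymptotic"
    # standardized statistic with midrank tie correction
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma = np.sqrt(max(0.0, n1 * n2 / 12.0 * (n + 1 - tie_term)))
    if sigma == 0.0:
        # every pooled value identical: no evidence either way
        return TestResult(name="U", statistic=mu, p=1.0, df=None,
                          effect={"z": 0.0, "median_a": float(np.median(a)),
                                  "median_b": float(np.median(b)),
                                  "zero_variance": 1.0})
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    u = float(res.statistic)
    z = (u - mu - 0.5 * np.sign(u - mu)) / sigma
    return TestResult(
        name="U", statistic=u, p=float(res.pvalue), df=None,
        effect={
            "z": float(z),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
        },
    )


@dataclass
class AnovaDesign:
    """Balanced within-subject design: one response per subject × condition.

    ``table`` is long format with columns subject, group, condition,
    response.  Subjects missing any condition are excluded listwise (with a
    warning) before fitting.
    """

    table: pd.DataFrame

    def complete(self) -> tuple[pd.DataFrame, list[str]]:
        conditions = sorted(self.table["condition"].unique())
        counts = self.table.groupby("subject")["condition"].nunique()
        keep = counts[counts == len(conditions)].index
        dropped = sorted(set(self.table["subject"]) - set(keep))
        return self.table[self.table["subject"].isin(keep)], dropped


def rm_anova_2x5(design: AnovaDesign,
                 sphericity_correction: bool = False) -> dict[str, TestResult]:
    """Mixed-design ANOVA: GROUP (between) × CONDITION (within).

    Returns TestResults for ``group``, ``condition`` and ``interaction``,
    each carrying F, degrees of freedom, p and the effect mean square.
    With all responses equal, every F is reported as 0 with p = 1.
    """
    import warnings as _warnings

    table, dropped = design.complete()
    if dropped:
        _warnings.warn(f"excluded subjects missing conditions: {dropped}")
    if table.empty:
        raise ValueError("no complete subjects")
    groups = sorted(table["group"].unique())
    conditions = sorted(table["condition"].unique())
    subj_group = table.drop_duplicates("subject").set_index("subject")["group"]
    n_per_group = subj_group.value_counts()
    if len(groups) < 2 or (n_per_group < 2).any():
        raise ValueError("need at least 2 subjects per group after exclusions")

    y = table.set_index(["subject", "condition"])["response"]
    c = len(conditions)
    n_total = subj_group.size
    grand = y.mean()

    ss_total = float(((y - grand) ** 2).sum())
    subj_means = y.groupby("subject").mean()
    group_means = subj_means.groupby(subj_group).mean()
    cond_means = y.groupby(level="condition").mean()
    cell = y.groupby([subj_group.reindex(y.index.get_level_values("subject")).values,
                      y.index.get_level_values("condition")]).mean()

    ss_between_subj = float(c * ((subj_means - grand) ** 2).sum())
    ss_group = float(c * (n_per_group * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = float(n_total * ((cond_means - grand) ** 2).sum())
    ss_int = 0.0
    for g in groups:
        for cond in conditions:
            dev = cell[(g, cond)] - group_means[g] - cond_means[cond] + grand
            ss_int += n_per_group[g] * dev ** 2
    ss_int = float(ss_int)
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_cond - ss_int

    df_group = len(groups) - 1
    df_subj = n_total - len(groups)
    df_cond = c - 1
    df_int = df_group * df_cond
    df_err = df_subj * df_cond

    eps = 1.0
    if sphericity_correction:
        eps = _greenhouse_geisser_epsilon(table, conditions)

    def _f_test(label, ss_eff, df_eff, ss_err, df_err_) -> TestResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err_
        if ms_err <= 0:
            if ms_eff <= 0:
                return TestResult(name="F", statistic=0.0, p=1.0,
                                  df=(df_eff, df_err_), effect={"ms": 0.0},
                                  label=label)
            return TestResult(name="F", statistic=float("inf"), p=0.0,
                              df=(df_eff, df_err_), effect={"ms": ms_eff},
                              label=label)
        f = ms_eff / ms_err
        p = float(stats.f.sf(f, df_eff * eps, df_err_ * eps))
        return TestResult(name="F", statistic=float(f), p=p,
                          df=(df_eff, df_err_),
                          effect={"ms": float(ms_eff), "ms_error": float(ms_err),
                                  "ss": float(ss_eff)},
                          label=label)

    results = {
        "group": _f_test("group", ss_group, df_group, ss_subj_within, df_subj),
        "condition": _f_test("condition", ss_cond, df_cond, ss_err_within, df_err),
        "interaction": _f_test("interaction", ss_int, df_int, ss_err_within, df_err),
    }
    # exact decomposition is exposed for verification
    results["condition"].effect["ss_total"] = ss_total
    results["condition"].effect["ss_parts"] = (
        ss_group + ss_subj_within + ss_cond + ss_int + ss_err_within
    )
    return results


def _greenhouse_geisser_epsilon(table: pd.DataFrame, conditions) -> float:
    wide = table.pivot_table(index="subject", columns="condition",
                             values="response")
    cov = np.cov(wide.to_numpy(), rowvar=False)
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(cov ** 2) - 2 * k * np.sum(row_means ** 2)
                     + k ** 2 * mean_all ** 2)
    return float(num / den) if den > 0 else 1.0


def posthoc_bonferroni(cell_means: dict[str, tuple[float, int]],
                       ms_error: float, df_error: int,
                       comparisons: list[tuple[str, str]] | None = None
                       ) -> list[TestResult]:
    """Pairwise t tests against the ANOVA error term, Bonferroni-adjusted.

    ``cell_means`` maps a cell label to (mean, n).  Each raw p is
    multiplied by the number of comparisons and capped at 1.
    """
    labels = list(cell_means)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels)
                       for b in labels[i + 1:]]
    m = len(comparisons)
    if m == 0:
        raise ValueError("no comparisons requested")
    results = []
    for a, b in comparisons:
        (ma, na), (mb, nb) = cell_means[a], cell_means[b]
        se = np.sqrt(ms_error * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / se if se > 0 else 0.0
        raw = float(2.0 * stats.t.sf(abs(t), df_error)) if se > 0 else 1.0
        results.append(
            TestResult(
                name="t", statistic=float(t), p=min(1.0, raw * m),
                df=(df_error,),
                effect={"raw_p": raw, "mean_diff": float(ma - mb),
                        "m": float(m)},
                label=f"{a} vs {b}",
            )
        )
    return results
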