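"""Cohort statistics: normality-gated zone comparisons, gradient contrasts,
ANCOVA and demographics.

Every comparison passes through a Shapiro-Wilk gate at alpha = 0.05:
within-group inner-vs-outer contrasts use a paired t-test when the paired
differences look normal and a Wilcoxon signed-rank test (Pratt
zero-handling) otherwise; between-group contrasts of OZ-IZ gradients use
Welch's t-test when both groups pass and a Mann-Whitney U test otherwise.
The ANCOVA models gradient ~ group + edema volume and reports the group
effect.  No multiple-testing correction is applied (single-test alpha
0.05 throughout); a Holm adjustment helper is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import InsufficientDataError

__all__ = ["TestResult", "normality_gate", "within_group_compare",
           "between_group_compare", "ancova_gradient", "demographics",
           "run_battery", "report_markdown"]

ALPHA_NORMALITY = 0.05


@dataclass
class TestResult:
    metric: str
    contrast: str
    test_name: str
    statistic: float
    p_value: float
    estimates: dict[str, str] = field(default_factory=dict)
    gate: str = ""
    note: str = ""

    def as_row(self) -> dict:
        return {"metric": self.metric, "contrast": self.contrast,
                "test": self.test_name, "statistic": self.statistic,
                "p_value": self.p_value, "gate": self.gate,
                **{f"est_{k}": v for k, v in self.estimates.items()},
                "note": self.note}


def _fmt_mean_sd(x) -> str:
    return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.2g}"


def _fmt_median_iqr(x) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.3g} [{q1:.3g}–{q3:.3g}]"


def normality_gate(values, alpha: float = ALPHA_NORMALITY) -> str:
    """Shapiro-Wilk decision: ``"normal"`` or ``"non-normal"``.

    Constant input is non-normal by convention (the test is undefined).
    Requires n >= 3.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise InsufficientDataError("normality gate needs n >= 3")
    if np.ptp(x) == 0:
        return "non-normal"
    _, p = sps.shapiro(x)
    return "normal" if p > alpha else "non-normal"


def within_group_compare(iz, oz, metric: str = "", group: str = "") -> TestResult:
    """Paired inner-vs-outer comparison within one group.

    Paired t-test when the paired differences pass the normality gate,
    Wilcoxon signed-rank (Pratt) otherwise.
    """
    iz = np.asarray(iz, float)
    oz = np.asarray(oz, float)
    keep = ~(np.isnan(iz) | np.isnan(oz))
    iz, oz = iz[keep], oz[keep]
    if iz.size < 3:
        raise InsufficientDataError("paired comparison needs >= 3 complete pairs")
    diff = oz - iz
    gate = normality_gate(diff) if np.ptp(diff) > 0 else "normal"
    if gate == "normal":
        if np.ptp(diff) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_rel(iz, oz)
        name = "paired t"
        est = {"IZ": _fmt_mean_sd(iz), "OZ": _fmt_mean_sd(oz)}
    else:
        stat, p = sps.wilcoxon(diff, zero_method="pratt")
        name = "Wilcoxon signed-rank"
        est = {"IZ": _fmt_median_iqr(iz), "OZ": _fmt_median_iqr(oz)}
    return TestResult(metric=metric, contrast=f"IZ vs OZ ({group})",
                      test_name=name, statistic=float(stat), p_value=float(p),
                      estimates=est, gate=gate)


def between_group_compare(grad_a, grad_b, metric: str = "",
                          labels: tuple[str, str] = ("gbm", "met"),
                          t_flavor: str = "welch") -> TestResult:
    """Two-sample comparison of OZ-IZ gradients between groups.

    Welch's t-test (default; Student optional) when both groups pass the
    gate, Mann-Whitney U otherwise.
    """
    a = np.asarray(grad_a, float); a = a[~np.isnan(a)]
    b = np.asarray(grad_b, float); b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("between-group comparison needs n >= 3 per group")
    gate_a, gate_b = normality_gate(a), normality_gate(b)
    gate = "normal" if (gate_a == "normal" and gate_b == "normal") else "non-normal"
    if gate == "normal":
        stat, p = sps.ttest_ind(a, b, equal_var=(t_flavor == "student"))
        name = "Welch t" if t_flavor == "welch" else "Student t"
        est = {labels[0]: _fmt_mean_sd(a), labels[1]: _fmt_mean_sd(b)}
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
        est = {labels[0]: _fmt_median_iqr(a), labels[1]: _fmt_median_iqr(b)}
    return TestResult(metric=metric, contrast="OZ-IZ between groups",
                      test_name=name, statistic=float(stat), p_value=float(p),
                      estimates=est, gate=gate)


def ancova_gradient(gradient, group_labels, edema_volume_ml,
                    metric: str = "") -> TestResult:
    """ANCOVA: gradient ~ group + edema volume; reports the group effect.

    A constant covariate is dropped with a note (the model then reduces to
    a two-group comparison).
    """
    df = pd.DataFrame({"y": np.asarray(gradient, float),
                       "group": np.asarray(group_labels),
                       "vol": np.asarray(edema_volume_ml, float)}).dropna()
    if df["group"].nunique() != 2:
        raise InsufficientDataError("ANCOVA needs exactly two groups")
    if df.groupby("group").size().min() < 3:
        raise InsufficientDataError("ANCOVA needs n >= 3 per group")
    note = ""
    formula = "y ~ C(group) + vol"
    if np.ptp(df["vol"].to_numpy()) == 0:
        formula = "y ~ C(group)"
        note = "constant edema-volume covariate dropped"
    fit = smf.ols(formula, data=df).fit()
    term = [t for t in fit.params.index if t.startswith("C(group)")][0]
    return TestResult(metric=metric, contrast="OZ-IZ between groups | edema volume",
                      test_name="ANCOVA", statistic=float(fit.tvalues[term]),
                      p_value=float(fit.pvalues[term]),
                      estimates={"coef": f"{fit.params[term]:.4g}",
                                 "vol_p": f"{fit.pvalues.get('vol', np.nan):.3g}"},
                      gate="", note=note)


def demographics(age_a, age_b, sex_counts: tuple[tuple[int, int], tuple[int, int]],
                 vol_a, vol_b, labels: tuple[str, str] = ("gbm", "met"),
                 chi2_correction: bool = False) -> list[TestResult]:
    """Age (gated t / MWU), sex (chi-square on the 2x2 table), edema volume (MWU).

    The chi-square defaults to no continuity correction, which reproduces
    standard 2x2 results on moderate samples; Yates' correction is
    available via ``chi2_correction``.
    """
    results = []
    a = np.asarray(age_a, float); b = np.asarray(age_b, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty group")
    gate = "normal" if (normality_gate(a) == "normal"
                        and normality_gate(b) == "normal") else "non-normal"
    if gate == "normal":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        name = "Welch t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
    results.append(TestResult(metric="age", contrast="between groups",
                              test_name=name, statistic=float(stat),
                              p_value=float(p), gate=gate,
                              estimates={labels[0]: _fmt_mean_sd(a),
                                         labels[1]: _fmt_mean_sd(b)}))

    table = np.asarray(sex_counts)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=chi2_correction)
    results.append(TestResult(metric="sex", contrast="between groups",
                              test_name="chi-square", statistic=float(chi2),
                              p_value=float(p),
                              estimates={labels[0]: f"{table[0,0]}/{table[0,1]}",
                                         labels[1]: f"{table[1,0]}/{table[1,1]}"}))

    va = np.asarray(vol_a, float); vb = np.asarray(vol_b, float)
    stat, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
    results.append(TestResult(metric="edema_volume_ml", contrast="between groups",
                              test_name="Mann-Whitney U", statistic=float(stat),
                              p_value=float(p),
                              estimates={labels[0]: _fmt_median_iqr(va),
                                         labels[1]: _fmt_median_iqr(vb)}))
    return results


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; not applied by default)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def run_battery(summary_df: pd.DataFrame,
                groups: tuple[str, str] = ("gbm", "met")) -> pd.DataFrame:
    """Full statistical battery on a tidy zone-summary table.

    Expects columns subject, group, metric, zone, value, edema_volume_ml.
    Produces one row per TestResult: within-group IZ-vs-OZ per metric and
    group, between-group OZ-IZ comparison and ANCOVA per metric.
    """
    results: list[TestResult] = []
    metrics = sorted(summary_df["metric"].unique())
    wide = summary_df.pivot_table(index=["subject", "group", "metric"],
                                  columns="zone", values="value").reset_index()
    vols = summary_df.drop_duplicates("subject").set_index("subject")["edema_volume_ml"]
    for metric in metrics:
        sub = wide[wide["metric"] == metric]
        grads = {}
        for g in groups:
            gsub = sub[sub["group"] == g].set_index("subject")
            results.append(within_group_compare(gsub["IZ"], gsub["OZ"],
                                                metric=metric, group=g))
            grads[g] = gsub["OZ"] - gsub["IZ"]
        results.append(between_group_compare(grads[groups[0]], grads[groups[1]],
                                             metric=metric, labels=groups))
        all_g = pd.concat([grads[g] for g in groups])
        labels = sum(([g] * len(grads[g]) for g in groups), [])
        results.append(ancova_gradient(all_g.to_numpy(), labels,
                                       vols.loc[all_g.index].to_numpy(),
                                       metric=metric))
    return pd.DataFrame([r.as_row() for r in results])


def report_markdown(results_df: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable markdown report of the battery results."""
    lines = ["# Peritumoral zone statistics", ""]
    for contrast, block in results_df.groupby("contrast", sort=False):
        lines.append(f"## {contrast}")
        for _, r in block.iterrows():
            flag = " *" if r["p_value"] < alpha else ""
            ests = ", ".join(f"{c[4:]}: {r[c]}" for c in block.columns
                             if c.startswith("est_") and pd.notna(r[c]))
            lines.append(f"- **{r['metric']}** ({r['test']}): "
                         f"stat = {r['statistic']:.3g}, p = {r['p_value']:.3g}{flag}"
                         + (f" — {ests}" if ests else ""))
        lines.append("")
    return "\n".join(lines)
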