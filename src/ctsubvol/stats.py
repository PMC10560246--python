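"""Method-agreement and group-comparison statistics.

Validating a new volumetric method against an established one calls for
three standard analyses, all implemented here on top of scipy:

* **Bland-Altman agreement** — mean of paired differences (bias) and
  bias +/- 1.96 x SD of the differences (limits of agreement);
* **normality-gated group tests** — Shapiro-Wilk per group decides
  between parametric (t / one-way ANOVA) and non-parametric
  (Mann-Whitney U / Kruskal-Wallis) comparisons;
* **Spearman rank correlation** with the Chan (2003) verbal strength
  scale: |r| = 1.0 perfect, >= 0.8 very strong, >= 0.6 moderate,
  >= 0.3 fair, >= 0.1 weak, else negligible.

No multiple-testing correction is applied; callers comparing many
endpoints should correct externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

#: Conventional 95 % limits-of-agreement multiplier.
LOA_MULTIPLIER = 1.96

CHAN_SCALE = (
    (0.8, "very_strong"),
    (0.6, "moderate"),
    (0.3, "fair"),
    (0.1, "weak"),
)


@dataclass
class AgreementResult:
    """Bland-Altman summary of paired measurements a vs b (differences a - b)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "sd_diff": self.sd_diff,
            "n": self.n,
        }


@dataclass
class GroupTestResult:
    """Outcome of a normality-gated group comparison.

    ``normal`` records the per-group Shapiro-Wilk verdict so the gating
    decision is visible in the result rather than hidden.
    """

    test_name: str
    statistic: float
    p_value: float
    groups: list[tuple[str, int]]
    normal: list[bool]
    shapiro_p: list[float]

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": [{"label": l, "n": n} for l, n in self.groups],
            "normal": self.normal,
            "shapiro_p": self.shapiro_p,
        }


@dataclass
class CorrelationResult:
    """Spearman correlation with its Chan-scale strength label."""

    r: float
    p_value: float
    label: str

    def to_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "label": self.label}


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement between paired measurement vectors.

    Differences are ``a - b``; the SD uses the n-1 denominator.  The
    per-pair ``(mean, difference)`` values are kept on the result for
    plotting.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        n=len(a),
        means=(a + b) / 2.0,
        diffs=d,
    )


def bland_altman_plot(result: AgreementResult, path) -> None:
    """Scatter of differences against pair means with bias and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, color="black")
    ax.axhline(result.bias, color="tab:blue", label=f"bias = {result.bias:.3g}")
    for y, name in ((result.loa_low, "lower LoA"), (result.loa_high, "upper LoA")):
        ax.axhline(y, color="tab:red", linestyle="--", label=f"{name} = {y:.3g}")
    ax.set_xlabel("mean of methods (cm³)")
    ax.set_ylabel("difference between methods (cm³)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _shapiro_gate(values: list[np.ndarray], alpha: float):
    p_values = [float(sps.shapiro(v).pvalue) for v in values]
    normal = [p > alpha for p in p_values]
    return normal, p_values


def compare_groups(
    groups: list[tuple[str, list[float]]],
    paired: bool = False,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Compare >= 2 groups, choosing the test from a Shapiro-Wilk gate.

    All groups normal (every Shapiro-Wilk p > alpha): two-sample t test
    for 2 groups, one-way ANOVA for more.  Any group non-normal:
    Mann-Whitney U (two-sided) for 2 groups, Kruskal-Wallis for more.
    With ``paired=True`` (2 groups of equal length only) the paired
    variants are used instead: paired t or Wilcoxon signed-rank.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [label for label, _ in groups]
    values = [np.asarray(v, dtype=np.float64) for _, v in groups]
    for label, v in zip(labels, values):
        if len(v) < 3:
            raise ValueError(f"insufficient group size: group {label!r} has n={len(v)} < 3")
    normal, shapiro_p = _shapiro_gate(values, alpha)
    all_normal = all(normal)

    if paired:
        if len(values) != 2 or len(values[0]) != len(values[1]):
            raise ValueError("paired comparison needs exactly 2 groups of equal length")
        if all_normal:
            res = sps.ttest_rel(values[0], values[1])
            name = "paired_t"
        else:
            res = sps.wilcoxon(values[0], values[1])
            name = "wilcoxon"
    elif len(values) == 2:
        if all_normal:
            res = sps.ttest_ind(values[0], values[1])
            name = "t_test"
        else:
            res = sps.mannwhitneyu(values[0], values[1], alternative="two-sided")
            name = "mann_whitney_u"
    else:
        if all_normal:
            res = sps.f_oneway(*values)
            name = "anova"
        else:
            res = sps.kruskal(*values)
            name = "kruskal_wallis"

    return GroupTestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=[(label, len(v)) for label, v in zip(labels, values)],
        normal=normal,
        shapiro_p=shapiro_p,
    )


def chan_label(r: float) -> str:
    """Verbal correlation strength on the Chan scale (by absolute value)."""
    magnitude = abs(r)
    if magnitude >= 1.0 - 1e-12:
        return "perfect"
    for threshold, label in CHAN_SCALE:
        if magnitude >= threshold:
            return label
    return "negligible"


def correlate(x, y) -> CorrelationResult:
    """Two-tailed Spearman rank correlation with the Chan strength label."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("Spearman correlation needs at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation: constant input vector")
    res = sps.spearmanr(x, y, alternative="two-sided")
    r = float(res.statistic)
    return CorrelationResult(r=r, p_value=float(res.pvalue), label=chan_label(r))
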