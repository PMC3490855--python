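"""Summary statistics for simulated matching experiments.

Implements the quantities used to characterize direction repulsion and
attraction: perceived-minus-veridical differences, veridically normalized
effects, one-way ANOVA across condition groups, two-way repeated-measures
ANOVA (both factors within subject, tested against their subject-interaction
error terms), and the Wilcoxon signed-rank test with an exact null
distribution for small samples.  The ANOVA and signed-rank routines are
implemented from first principles (sums of squares, rank-sum convolution)
and are cross-checked against independent library implementations in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .experiment import ExperimentDataset
from .stimulus import ValidationError

__all__ = [
    "AnovaRow",
    "WilcoxonResult",
    "effect_metrics",
    "invert_attraction",
    "one_way_anova",
    "two_way_rm_anova",
    "wilcoxon_signed_rank",
    "summarize",
    "condition_table",
    "experiment1_report",
    "experiment2_report",
    "analyze_dataset",
]


@dataclass(frozen=True)
class AnovaRow:
    """One tested effect: F ratio, numerator/denominator df, p value."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float

    def __str__(self) -> str:  # paper-style "F(1,3) = 177, p = 9.1e-04"
        return f"{self.name}: F({self.df_num},{self.df_den}) = {self.F:.3g}, p = {self.p:.2g}"


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    p: float
    n: int
    method: str  # "exact" or "approx"


def effect_metrics(perceived: float, delta: float) -> tuple[float, float]:
    """Difference and veridically normalized effect of one measurement.

    Returns ``(perceived - Δ, (perceived - Δ)/Δ)``; positive values are
    repulsion, negative attraction.  Multiply the normalized value by 100
    for the percent form.
    """
    if delta <= 0:
        raise ValidationError("veridical separation must be > 0 to normalize")
    difference = perceived - delta
    return difference, difference / delta


def invert_attraction(normalized_values) -> np.ndarray:
    """Sign-flip normalized attraction values for magnitude comparison with
    repulsion (involutive)."""
    return -np.asarray(normalized_values, dtype=float)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------


def one_way_anova(groups, name: str = "group") -> AnovaRow:
    """Fixed-effects one-way ANOVA from sums of squares.

    ``groups`` is a sequence of k measurement lists; df = (k-1, N-k).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("at least two groups are required")
    for g in groups:
        if g.size < 2:
            raise ValidationError("every group needs at least two values")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    k = len(groups)
    n_total = all_values.size
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_num = k - 1
    df_den = n_total - k
    ms_between = ss_between / df_num
    ms_within = ss_within / df_den
    if ms_within == 0:
        f_ratio = 0.0 if ms_between == 0 else math.inf
    else:
        f_ratio = ms_between / ms_within
    p = float(sps.f.sf(f_ratio, df_num, df_den))
    return AnovaRow(name, float(f_ratio), df_num, df_den, p)


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from subject×level scores."""
    k = scores.shape[1]
    if k < 3:
        return 1.0
    centered = scores - scores.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (scores.shape[0] - 1)
    # orthonormal contrast basis
    helmert = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    m = helmert.T @ cov @ helmert
    tr = np.trace(m)
    if tr <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * np.trace(m @ m))
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def two_way_rm_anova(
    data: pd.DataFrame,
    subject: str = "subject_id",
    factor_a: str = "coherence",
    factor_b: str = "direction_separation",
    value: str = "value",
    gg_correction: bool = False,
) -> list[AnovaRow]:
    """Two-way repeated-measures ANOVA (both factors within subject).

    Requires a complete balanced table with exactly one value per
    (subject, A, B) cell.  Each effect is tested against its own
    subject-interaction error term:

    * A:   df = (a-1, (a-1)(n-1)),   error = A×S
    * B:   df = (b-1, (b-1)(n-1)),   error = B×S
    * A×B: df = ((a-1)(b-1), (a-1)(b-1)(n-1)), error = A×B×S

    No sphericity correction is applied by default; set ``gg_correction``
    for Greenhouse-Geisser-adjusted p values.
    """
    pivot = data.pivot_table(
        index=subject, columns=[factor_a, factor_b], values=value, aggfunc="mean"
    )
    if pivot.isna().any().any():
        raise ValidationError("missing cells in the repeated-measures design")
    counts = data.groupby([subject, factor_a, factor_b]).size()
    if (counts != 1).any():
        raise ValidationError("exactly one value per (subject, A, B) cell is required")

    a_levels = sorted(data[factor_a].unique())
    b_levels = sorted(data[factor_b].unique())
    subjects = sorted(data[subject].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if n < 2:
        raise ValidationError("at least two subjects are required")

    # y[s, i, j]
    y = np.empty((n, a, b))
    for ii, al in enumerate(a_levels):
        for jj, bl in enumerate(b_levels):
            y[:, ii, jj] = pivot[(al, bl)].loc[subjects].to_numpy()

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = a * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = (resid**2).sum()

    rows = []
    specs = [
        (factor_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (factor_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (
            f"{factor_a} x {factor_b}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
        ),
    ]
    if gg_correction:
        eps_a = _gg_epsilon(m_as)
        eps_b = _gg_epsilon(m_bs)
        # interaction contrast scores: per-subject double-centered cells
        inter = (y - m_as[:, :, None] - m_bs[:, None, :] + m_s[:, None, None]).reshape(
            n, a * b
        )
        eps_ab = _gg_epsilon(inter)
        epsilons = [eps_a, eps_b, eps_ab]
    else:
        epsilons = [1.0, 1.0, 1.0]

    for (name, ss_eff, df_eff, ss_err, df_err), eps in zip(specs, epsilons):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err == 0:
            f_ratio = 0.0 if ms_eff == 0 else math.inf
        else:
            f_ratio = ms_eff / ms_err
        p = float(sps.f.sf(f_ratio, eps * df_eff, eps * df_err))
        rows.append(AnovaRow(name, float(f_ratio), df_eff, df_err, p))
    return rows


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test
# --------------------------------------------------------------------------


def _signed_rank_exact_sf_table(doubled_ranks: np.ndarray) -> np.ndarray:
    """Distribution of the positive-rank sum over all 2^n sign assignments.

    Ranks are doubled to integers (ties give half-ranks); returns the
    probability mass over achievable doubled sums, built by convolution.
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:-r] if r > 0 else pmf
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(
    values, null_median: float = 0.0, method: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test against a hypothesized median.

    Zero differences are discarded.  ``method="exact"`` enumerates the null
    distribution of the positive-rank sum (default for n ≤ 25);
    ``"approx"`` uses the normal approximation with tie and continuity
    corrections (default above 25).
    """
    d = np.asarray(values, dtype=float) - null_median
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValidationError("all values equal the null median; nothing to test")
    if n < 5:
        raise ValidationError("at least 5 nonzero values are required")
    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if n <= 25 else "approx"

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if method == "exact":
        doubled = np.rint(2.0 * ranks).astype(int)
        pmf = _signed_rank_exact_sf_table(doubled)
        w2 = int(round(2.0 * w_plus))
        p_le = pmf[: w2 + 1].sum()
        p_ge = pmf[w2:].sum()
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, method)


# --------------------------------------------------------------------------
# Dataset-level summaries
# --------------------------------------------------------------------------


def _as_table(dataset) -> pd.DataFrame:
    if isinstance(dataset, ExperimentDataset):
        return dataset.table
    return dataset


def condition_table(dataset) -> pd.DataFrame:
    """Per-(subject, condition) perceived separation and effect metrics.

    The subject-level perceived separation is the mean matching angle of
    that subject's staircases (zero-floor staircases enter as 0°).
    """
    table = _as_table(dataset)
    if table["matching_angle"].isna().any():
        raise ValidationError(
            "dataset contains trial-cap staircases with undefined matching angles"
        )
    per_subject = (
        table.groupby(["subject_id", "direction_separation", "coherence"], sort=True)[
            "matching_angle"
        ]
        .mean()
        .rename("perceived")
        .reset_index()
    )
    per_subject["difference"] = (
        per_subject["perceived"] - per_subject["direction_separation"]
    )
    per_subject["normalized"] = (
        per_subject["difference"] / per_subject["direction_separation"]
    )
    return per_subject


def summarize(dataset) -> pd.DataFrame:
    """Across-subject mean ± standard error per condition, raw and normalized."""
    per_subject = condition_table(dataset)
    grouped = per_subject.groupby(["direction_separation", "coherence"], sort=True)
    if (grouped.size() < 2).any():
        raise ValidationError("at least two subjects per condition are required")

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        return pd.Series(
            {
                "n_subjects": n,
                "perceived_mean": g["perceived"].mean(),
                "perceived_se": g["perceived"].std(ddof=1) / math.sqrt(n),
                "difference_mean": g["difference"].mean(),
                "normalized_mean": g["normalized"].mean(),
                "normalized_se": g["normalized"].std(ddof=1) / math.sqrt(n),
            }
        )

    return grouped.apply(_agg, include_groups=False).reset_index()


def experiment1_report(dataset) -> dict:
    """Coherence dependence of the perceived separation at Δ = 30° and 60°:
    per-separation one-way ANOVA across coherence groups."""
    per_subject = condition_table(dataset)
    report: dict = {"anova": {}, "summary": summarize(dataset)}
    for delta, sub in per_subject.groupby("direction_separation"):
        groups = [
            g["perceived"].to_numpy() for _, g in sub.groupby("coherence", sort=True)
        ]
        report["anova"][float(delta)] = one_way_anova(
            groups, name=f"coherence effect at separation {delta:g} deg"
        )
    return report


def experiment2_report(dataset, gg_correction: bool = False) -> dict:
    """Separation dependence of attraction and repulsion.

    Contains the per-coherence one-way ANOVA of the normalized effect
    magnitude across separations, the signed-rank test of the attraction
    differences, the two-way repeated-measures ANOVA of the normalized
    effect (coherence × separation), and the same ANOVA after sign-inverting
    the attraction branch (magnitude comparison).
    """
    per_subject = condition_table(dataset)
    coherences = sorted(per_subject["coherence"].unique())
    if len(coherences) != 2:
        raise ValidationError("experiment-2 analysis expects exactly two coherences")
    low, high = coherences

    report: dict = {"summary": summarize(dataset), "anova": {}}
    for coh, label in ((low, "attraction"), (high, "repulsion")):
        sub = per_subject[per_subject["coherence"] == coh]
        groups = [
            g["normalized"].abs().to_numpy()
            for _, g in sub.groupby("direction_separation", sort=True)
        ]
        report["anova"][label] = one_way_anova(
            groups, name=f"separation effect on normalized {label} (c={coh:g})"
        )

    low_diffs = per_subject.loc[
        per_subject["coherence"] == low, "difference"
    ].to_numpy()
    report["median_attraction_magnitude"] = float(np.median(np.abs(low_diffs)))
    report["signed_rank"] = wilcoxon_signed_rank(low_diffs)

    rm_data = per_subject.rename(columns={"normalized": "value"})
    report["rm_anova"] = two_way_rm_anova(
        rm_data,
        subject="subject_id",
        factor_a="coherence",
        factor_b="direction_separation",
        value="value",
        gg_correction=gg_correction,
    )

    inverted = rm_data.copy()
    mask = inverted["coherence"] == low
    inverted.loc[mask, "value"] = invert_attraction(inverted.loc[mask, "value"])
    report["rm_anova_inverted"] = two_way_rm_anova(
        inverted,
        subject="subject_id",
        factor_a="coherence",
        factor_b="direction_separation",
        value="value",
        gg_correction=gg_correction,
    )
    return report


def analyze_dataset(dataset) -> dict:
    """Dispatch to the experiment-1 or experiment-2 analysis by design shape:
    two separations × many coherences → experiment 1; two coherences × many
    separations → experiment 2."""
    table = _as_table(dataset)
    n_deltas = table["direction_separation"].nunique()
    n_cohs = table["coherence"].nunique()
    if n_cohs > n_deltas:
        return {"design": "experiment1", **experiment1_report(dataset)}
    return {"design": "experiment2", **experiment2_report(dataset)}
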