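"""Densitometry normalization and the group-comparison statistical battery.

Covers the tests used throughout the quantification pipeline: unpaired
Welch t, one-way ANOVA with Dunnett's T3 multiple comparisons (unequal
variances; critical values from the studentized maximum modulus
distribution with per-pair Welch degrees of freedom), one-way ANOVA with
Tukey's HSD, Fisher's LSD, and the two-sample Kolmogorov-Smirnov test.
All p-values are two-tailed; significance is judged at alpha = 0.05.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sem: float


@dataclass
class Comparison:
    group_a: str
    group_b: str
    estimate: float  # mean_a - mean_b
    statistic: float
    df: float
    pvalue: float
    pvalue_adjusted: float
    significant: bool


@dataclass
class StatReport:
    """Result of a group comparison: estimates, test, p-values, post hocs."""

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    groups: list[GroupSummary] = field(default_factory=list)
    comparisons: list[Comparison] = field(default_factory=list)
    alpha: float = ALPHA
    params: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < self.alpha)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def group_summary(values, name: str = "") -> GroupSummary:
    x = np.asarray(values, dtype=float)
    n = x.size
    sem = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(name=name, n=int(n), mean=float(np.mean(x)), sem=sem)


# ---------------------------------------------------------------------------
# densitometry

def normalize_bands(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Normalize band intensities to the loading control and to the control group.

    Each sample's normalized value is ``target_intensity / loading_intensity``
    (loading control = Tuj1/GAPDH-style internal standard); fold change is
    the normalized value divided by the mean normalized value of
    ``control_group``, so the control-group mean fold change is 1 by
    construction.
    """
    required = {"sample_id", "group", "target_intensity", "loading_intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    if (table["loading_intensity"] <= 0).any():
        raise ValueError("loading intensities must be strictly positive")
    if (table["target_intensity"] <= 0).any():
        raise ValueError("target intensities must be strictly positive")
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} not present in table")
    out = table.copy()
    out["normalized"] = out["target_intensity"] / out["loading_intensity"]
    ctl_mean = out.loc[out["group"] == control_group, "normalized"].mean()
    out["fold_change"] = out["normalized"] / ctl_mean
    return out


# ---------------------------------------------------------------------------
# two-sample tests

def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 0.0, float(na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def welch_t(group_a, group_b, names: tuple[str, str] = ("a", "b")) -> StatReport:
    """Unpaired two-tailed t-test with Welch's correction for unequal variances."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 in each group")
    degenerate = a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0
    if degenerate:
        t = 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
        df = float(a.size + b.size - 2)
        p = 1.0 if t == 0.0 else 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        _, df = _welch(a, b)
    return StatReport(
        test="welch_t",
        statistic=t,
        df=df,
        pvalue=p,
        groups=[group_summary(a, names[0]), group_summary(b, names[1])],
        params={"two_tailed": True, "degenerate": degenerate},
    )


def ks_two_sample(sample_a, sample_b, names: tuple[str, str] = ("a", "b")) -> StatReport:
    """Two-sample Kolmogorov-Smirnov test: exact ECDF max-gap D, asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return StatReport(
        test="ks_two_sample",
        statistic=float(res.statistic),
        df=None,
        pvalue=min(1.0, float(res.pvalue)),
        groups=[group_summary(a, names[0]), group_summary(b, names[1])],
    )


# ---------------------------------------------------------------------------
# studentized maximum modulus (Dunnett's T3)

def smm_cdf(m: float, k: int, df: float) -> float:
    """CDF of the studentized maximum modulus: P(max_i |T_i| <= m).

    ``k`` independent standard normals studentized by a shared
    chi(df)/sqrt(df) scale:  integral over the scale s of
    ``(2 Phi(m s) - 1)^k`` against the chi density.  Used for Dunnett's
    T3 adjusted p-values with the per-pair Welch df.
    """
    if m <= 0:
        return 0.0
    if not math.isfinite(df):
        return (2.0 * sps.norm.cdf(m) - 1.0) ** k

    def integrand(s: float) -> float:
        return (2.0 * sps.norm.cdf(m * s) - 1.0) ** k * sps.chi.pdf(s * math.sqrt(df), df) * math.sqrt(df)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return min(1.0, max(0.0, val))


def smm_crit(alpha: float, k: int, df: float) -> float:
    """Upper critical value m with P(max|T_i| > m) = alpha."""
    return float(optimize.brentq(lambda m: smm_cdf(m, k, df) - (1.0 - alpha), 1e-6, 100.0))


def anova_dunnett_t3(
    groups: list,
    control_index: int = 0,
    names: list[str] | None = None,
    alpha: float = ALPHA,
) -> StatReport:
    """One-way ANOVA plus Dunnett's T3 comparisons against a control group.

    The omnibus test is the ordinary one-way ANOVA F.  Each treated group
    is compared with the control by a Welch-type t statistic with
    Welch-Satterthwaite df; the familywise adjustment evaluates the
    studentized maximum modulus distribution at that df, which does not
    assume equal variances across groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("anova_dunnett_t3 requires at least 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group requires n >= 2")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    k = len(arrays) - 1
    comparisons = []
    ctl = arrays[control_index]
    for i, a in enumerate(arrays):
        if i == control_index:
            continue
        t, df = _welch(a, ctl)
        p_raw = 2.0 * sps.t.sf(abs(t), df)
        p_adj = 1.0 - smm_cdf(abs(t), k, df)
        p_adj = min(1.0, max(p_adj, p_raw))
        comparisons.append(
            Comparison(
                group_a=names[i],
                group_b=names[control_index],
                estimate=float(a.mean() - ctl.mean()),
                statistic=t,
                df=df,
                pvalue=float(p_raw),
                pvalue_adjusted=float(p_adj),
                significant=bool(p_adj < alpha),
            )
        )
    return StatReport(
        test="anova_dunnett_t3",
        statistic=float(f),
        df=(float(len(arrays) - 1), float(sum(a.size for a in arrays) - len(arrays))),
        pvalue=float(p),
        groups=[group_summary(a, n) for a, n in zip(arrays, names)],
        comparisons=comparisons,
        alpha=alpha,
        params={"control": names[control_index], "n_comparisons": k},
    )


def anova_tukey(groups: list, names: list[str] | None = None, alpha: float = ALPHA) -> StatReport:
    """One-way ANOVA with Tukey's HSD all-pairs comparisons."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("anova_tukey requires at least 3 groups (use welch_t for two)")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group requires n >= 2")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    df_within = float(sum(a.size for a in arrays) - len(arrays))
    comparisons = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p_adj = float(hsd.pvalue[i, j])
            comparisons.append(
                Comparison(
                    group_a=names[i],
                    group_b=names[j],
                    estimate=float(arrays[i].mean() - arrays[j].mean()),
                    statistic=float(hsd.statistic[i, j]),
                    df=df_within,
                    pvalue=p_adj,
                    pvalue_adjusted=p_adj,
                    significant=bool(p_adj < alpha),
                )
            )
    return StatReport(
        test="anova_tukey",
        statistic=float(f),
        df=(float(len(arrays) - 1), df_within),
        pvalue=float(p),
        groups=[group_summary(a, n) for a, n in zip(arrays, names)],
        comparisons=comparisons,
        alpha=alpha,
    )


def fisher_lsd(groups: list, names: list[str] | None = None, alpha: float = ALPHA) -> StatReport:
    """One-way ANOVA with Fisher's least-significant-difference pairwise tests.

    Pairwise t statistics use the pooled within-group mean square and its
    df; p-values are unadjusted, per the classical LSD procedure.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("fisher_lsd requires >=2 groups with n >= 2 each")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    df_within = float(n_total - len(arrays))
    mse = sum(a.var(ddof=1) * (a.size - 1) for a in arrays) / df_within
    comparisons = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            se = math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            t = (a.mean() - b.mean()) / se if se > 0 else 0.0
            p_ij = 2.0 * sps.t.sf(abs(t), df_within) if se > 0 else 1.0
            comparisons.append(
                Comparison(
                    group_a=names[i],
                    group_b=names[j],
                    estimate=float(a.mean() - b.mean()),
                    statistic=float(t),
                    df=df_within,
                    pvalue=float(p_ij),
                    pvalue_adjusted=float(p_ij),
                    significant=bool(p_ij < alpha),
                )
            )
    return StatReport(
        test="anova_fisher_lsd",
        statistic=float(f),
        df=(float(len(arrays) - 1), df_within),
        pvalue=float(p),
        groups=[group_summary(a, n) for a, n in zip(arrays, names)],
        comparisons=comparisons,
        alpha=alpha,
    )


def percent_change(treated, control) -> tuple[float, float]:
    """Percent change of the treated group mean versus control, with SEM.

    Returns ``100 * (mean_t - mean_c) / mean_c`` and its standard error by
    first-order (delta-method) propagation of the two group SEMs.
    """
    t = group_summary(treated)
    c = group_summary(control)
    if c.mean == 0:
        raise ValueError("control mean is zero; percent change undefined")
    pc = 100.0 * (t.mean - c.mean) / c.mean
    sem = 100.0 * math.hypot(t.sem / c.mean, t.mean * c.sem / c.mean**2)
    return pc, sem
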