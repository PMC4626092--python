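"""Per-animal aggregation, relative normalization, group tests, and ddCt.

The animal (not the image) is the unit of inference: per-image metric
values are averaged within each animal before any normalization or test.
Two-group comparisons use the unpaired Student t test (Welch optional);
three or more groups use one-way ANOVA with Tukey HSD post hoc tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_per_animal",
    "relative_to_control",
    "unpaired_t",
    "anova_tukey",
    "linear_r2",
    "ddct_fold_change",
    "signed_fold",
    "ddct_from_signed_fold",
]


# ---------------------------------------------------------------------------
# aggregation and normalization


def aggregate_per_animal(per_image: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-image rows to one value per animal per metric.

    Expects columns ``animal_id, group, metric, value``; each animal's
    value is the arithmetic mean over its images, so unbalanced image
    counts do not weight animals unequally in group summaries.
    """
    required = {"animal_id", "group", "metric", "value"}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if per_image["animal_id"].isna().any():
        raise ValueError("image row without animal_id")
    out = (
        per_image.groupby(["animal_id", "group", "metric"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out


def relative_to_control(
    measurements: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize per-animal values to the control-group mean, per metric.

    Returns the normalized measurements plus a per-group summary with
    relative mean and SEM (SD/sqrt(n), sample SD).  The control group's
    relative mean is 1 by construction.
    """
    if control_group not in set(measurements["group"]):
        raise ValueError(f"control group {control_group!r} absent")
    norm = measurements.copy()
    for metric, sub in measurements.groupby("metric"):
        ctrl = sub.loc[sub["group"] == control_group, "value"]
        if len(ctrl) == 0:
            raise ValueError(f"control group empty for metric {metric!r}")
        m = ctrl.mean()
        if m == 0:
            raise ValueError(f"control mean is 0 for metric {metric!r}")
        norm.loc[sub.index, "value"] = sub["value"] / m
    summary = (
        norm.groupby(["metric", "group"])["value"]
        .agg(
            relative_mean="mean",
            sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="count",
        )
        .reset_index()
    )
    return norm, summary


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def unpaired_t(a, b, welch: bool = False) -> TTestResult:
    """Two-sample unpaired t test (pooled variance; Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_t(ma, mb, float(na + nb - 2))
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
        if se2 == 0:
            return _degenerate_t(ma, mb, df)
    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def _degenerate_t(ma: float, mb: float, df: float) -> TTestResult:
    if ma == mb:
        return TTestResult(t=0.0, df=df, p=1.0)
    warnings.warn("zero variance with unequal means: p -> 0", stacklevel=3)
    return TTestResult(t=math.copysign(math.inf, ma - mb), df=df, p=0.0)


@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, q, p_adj


def anova_tukey(groups: dict | list) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` is a dict ``label -> values`` or a list of value lists.
    Tukey p-values come from the studentized-range distribution at the
    ANOVA error df, with the Tukey-Kramer correction for unequal n.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [str(i) for i in range(len(data))]
    k = len(data)
    if k < 3:
        raise ValueError("anova_tukey needs >= 3 groups; use unpaired_t")
    if any(len(g) < 2 for g in data):
        raise ValueError("each group needs at least 2 observations")
    ns = np.array([len(g) for g in data])
    means = np.array([g.mean() for g in data])
    n_total = int(ns.sum())
    grand = np.concatenate(data).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in data))
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        warnings.warn("zero within-group variance", stacklevel=2)
        f_stat = 0.0 if ss_between == 0 else math.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_b) / ms_within
        p = float(sps.f.sf(f_stat, df_b, df_w))

    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        if ms_within == 0:
            q = 0.0 if diff == 0 else math.inf
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            se = math.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "q": float(q),
                "p_adj": p_adj,
            }
        )
    return AnovaTukeyResult(
        f=float(f_stat),
        p=p,
        df_between=df_b,
        df_within=df_w,
        pairwise=pd.DataFrame(rows),
    )


def linear_r2(x, y) -> dict:
    """Squared Pearson correlation with two-sided zero-correlation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return {"r_squared": float(r**2), "r": float(r), "p": float(p)}


# ---------------------------------------------------------------------------
# ddCt pipeline


def signed_fold(ddct: float) -> float:
    """2^(-ddCt) when up-regulated (>= 1), else -2^(ddCt) (signed)."""
    up = 2.0 ** (-ddct)
    return up if up >= 1.0 else -(2.0**ddct)


def ddct_from_signed_fold(fold: float) -> float:
    """Inverse of :func:`signed_fold` on both branches."""
    if fold >= 1.0:
        return -math.log2(fold)
    if fold <= -1.0:
        return math.log2(-fold)
    raise ValueError("signed fold changes lie outside (-1, 1)")


def ddct_fold_change(
    ct: pd.DataFrame,
    normalizers: list[str],
    control_group: str,
) -> pd.DataFrame:
    """Relative expression via the ddCt method.

    ``ct`` columns: sample_id, group, gene, replicate, ct.  Per sample and
    gene, Ct is the mean of the successful (non-missing) replicates; dCt is
    Ct(gene) minus the geometric mean of the normalizer Cts of the same
    sample; ddCt is dCt minus the control-group mean dCt for that gene.
    Fold change is reported both unsigned (2^-ddCt) and in the signed
    convention (negative for down-regulation); a gene/sample is flagged DE
    when its signed fold lies more than two control-group SDs from the
    control-group mean signed fold.
    """
    required = {"sample_id", "group", "gene", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not normalizers:
        raise ValueError("at least one normalizer gene is required")
    ct = ct.dropna(subset=["ct"])
    if (ct["ct"] <= 0).any():
        raise ValueError("nonpositive Ct: geometric mean undefined")

    # mean Ct of successful replicates, per sample x gene
    mean_ct = (
        ct.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    norm_ct = mean_ct[mean_ct["gene"].isin(normalizers)]
    geo = (
        norm_ct.groupby("sample_id")["ct"]
        .agg(lambda v: float(np.exp(np.mean(np.log(v)))))
        .rename("norm_geomean")
    )
    n_norm = norm_ct.groupby("sample_id")["gene"].nunique()
    complete = n_norm[n_norm == len(set(normalizers))].index
    dropped = sorted(set(mean_ct["sample_id"]) - set(complete))
    if dropped:
        warnings.warn(
            f"samples dropped for missing normalizer Ct: {dropped}",
            stacklevel=2,
        )
    goi = mean_ct[
        ~mean_ct["gene"].isin(normalizers)
        & mean_ct["sample_id"].isin(complete)
    ].merge(geo, on="sample_id")
    goi["delta_ct"] = goi["ct"] - goi["norm_geomean"]

    ctrl = goi[goi["group"] == control_group]
    if ctrl.groupby("gene")["sample_id"].nunique().min() < 2 or ctrl.empty:
        raise ValueError("control group needs >= 2 samples per gene")
    ctrl_mean_dct = ctrl.groupby("gene")["delta_ct"].mean().rename("ctrl_dct")
    goi = goi.merge(ctrl_mean_dct, on="gene")
    goi["delta_delta_ct"] = goi["delta_ct"] - goi["ctrl_dct"]
    goi["fold_unsigned"] = 2.0 ** (-goi["delta_delta_ct"])
    goi["fold_change"] = goi["delta_delta_ct"].map(signed_fold)

    ctrl_folds = goi[goi["group"] == control_group].groupby("gene")["fold_change"]
    stats_ctrl = ctrl_folds.agg(
        ctrl_fold_mean="mean", ctrl_fold_sd=lambda v: v.std(ddof=1)
    )
    goi = goi.merge(stats_ctrl, on="gene")
    goi["de_flag"] = (
        np.abs(goi["fold_change"] - goi["ctrl_fold_mean"])
        > 2.0 * goi["ctrl_fold_sd"]
    )
    cols = [
        "sample_id",
        "group",
        "gene",
        "ct",
        "norm_geomean",
        "delta_ct",
        "delta_delta_ct",
        "fold_unsigned",
        "fold_change",
        "de_flag",
    ]
    return goi[cols].reset_index(drop=True)
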