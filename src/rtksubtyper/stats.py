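"""Subtype-association statistics.

Per-gene one-way ANOVA across subtypes with Benjamini-Hochberg FDR control,
Tukey studentized-range post-hoc comparisons (to be run only when the
adjusted overall p is below the gate), joint FDR/fold-change screening of
candidate genes, per-gene Pearson correlation with a drug-response vector
(censored IC50s entering at their cap), and two-sided Fisher's exact tests.
All tests are two-sided; fold-changes are computed on the linear scale from
log2 group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_fdr",
    "tukey_posthoc",
    "screen_by_fdr_fc",
    "correlate_with_response",
    "fisher_exact",
    "RtkScreenResult",
]


def _group_masks(labels: pd.Series, columns) -> dict:
    labels = pd.Series(labels).loc[columns].astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    masks = {g: (labels == g).to_numpy() for g in groups}
    small = [g for g in groups if masks[g].sum() < 2]
    if small:
        raise ValueError(f"group(s) with < 2 samples: {', '.join(small)}")
    return masks


def anova_fdr(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per gene with BH-adjusted q-values.

    Returns a frame indexed by gene with columns F, p, q, mean_<group>...,
    and zero_variance (True where both between- and within-group sums of
    squares vanish; p is recorded as 1 there).
    """
    masks = _group_masks(labels, m.columns)
    groups = list(masks)
    X = m.to_numpy(float)
    n = X.shape[1]
    k = len(groups)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    means = {}
    for g in groups:
        sub = X[:, masks[g]]
        mg = sub.mean(axis=1)
        means[g] = mg
        ssb += masks[g].sum() * (mg - grand) ** 2
        ssw += ((sub - mg[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
        p = scipy.stats.f.sf(F, df_b, df_w)
    zero = (ssb == 0) & (ssw == 0)
    degenerate = zero | ((ssb == 0) & (ssw > 0))
    F = np.where(zero, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    # within-variance 0 but real group separation: infinitely significant
    p = np.where((ssw == 0) & (ssb > 0), 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"F": F, "p": p, "q": q}, index=m.index)
    for g in groups:
        out[f"mean_{g}"] = means[g]
    out["zero_variance"] = zero
    return out


def tukey_posthoc(values: np.ndarray, labels: pd.Series) -> pd.DataFrame:
    """Tukey HSD pairwise adjusted p-values for one response vector."""
    labels = pd.Series(labels).astype(str)
    values = np.asarray(values, float)
    groups = sorted(labels.unique())
    samples = [values[(labels == g).to_numpy()] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations for Tukey HSD")
    res = scipy.stats.tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        rows.append(
            (
                groups[i],
                groups[j],
                float(np.mean(samples[i]) - np.mean(samples[j])),
                float(res.pvalue[i, j]),
            )
        )
    return pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_adj"])


@dataclass
class RtkScreenResult:
    """Genes passing the joint FDR + fold-change screen."""

    passing: list[str]
    table: pd.DataFrame  # per gene: q, max_fold_change, passes
    fdr_max: float
    fc_min: float


def screen_by_fdr_fc(
    table: pd.DataFrame, fdr_max: float = 1e-4, fc_min: float = 2.5
) -> RtkScreenResult:
    """Select genes with q < fdr_max and linear fold-change >= fc_min.

    The fold-change of a pairwise contrast is 2**|difference of log2 group
    means|; a gene passes when its largest pairwise fold-change clears
    ``fc_min`` (in at least one contrast).
    """
    mean_cols = [c for c in table.columns if c.startswith("mean_")]
    if len(mean_cols) < 2:
        raise ValueError("table must carry mean_<group> columns from anova_fdr")
    means = table[mean_cols].to_numpy(float)
    max_log2_fc = np.zeros(len(table))
    for i, j in combinations(range(means.shape[1]), 2):
        max_log2_fc = np.maximum(max_log2_fc, np.abs(means[:, i] - means[:, j]))
    fc = 2.0**max_log2_fc
    passes = (table["q"].to_numpy() < fdr_max) & (fc >= fc_min)
    out = pd.DataFrame(
        {"q": table["q"], "max_fold_change": fc, "passes": passes}, index=table.index
    )
    return RtkScreenResult(
        passing=list(table.index[passes]),
        table=out,
        fdr_max=fdr_max,
        fc_min=fc_min,
    )


def correlate_with_response(
    m: pd.DataFrame,
    response: pd.Series,
    censored: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with a per-sample response (e.g. IC50).

    Censored responses (reported at the maximum tested dose) enter at their
    cap value; the output notes how many were censored.
    """
    response = pd.Series(response).loc[m.columns].astype(float)
    if len(response) < 3:
        raise ValueError("need >= 3 paired observations")
    if response.std() == 0:
        raise ValueError("constant response vector")
    y = response.to_numpy()
    X = m.to_numpy(float)
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / denom
    r = np.clip(np.where(denom == 0, np.nan, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame({"r": r, "p": p}, index=m.index)
    out.attrs["n_censored"] = int(pd.Series(censored).sum()) if censored is not None else 0
    return out


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(int)
        if np.any(t_int != t) or np.any(t_int < 0):
            raise ValueError("counts must be non-negative integers")
        t = t_int
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])
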