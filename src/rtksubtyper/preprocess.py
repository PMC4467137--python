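"""Expressed/silenced calling, prevalence filtering and batch merging.

``call_expressed`` dichotomizes a log2 matrix into expressed vs silenced
entries.  The default method fits a two-component Gaussian mixture to all
matrix values and calls an entry expressed when the posterior probability of
the higher-mean component is at least 0.5; a fixed threshold is available as a
fallback and as an explicit method.

``combat_adjust`` merges independently normalized datasets with the
parametric empirical-Bayes location/scale model: genes are standardized
against a batch-free design, batch location (gamma) and scale (delta^2)
effects are shrunk toward normal / inverse-gamma priors by an iterative
posterior solution, and the data are back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "DetectionMatrix",
    "call_expressed",
    "filter_by_prevalence",
    "combat_adjust",
]


@dataclass
class DetectionMatrix:
    """Boolean expressed/silenced calls with the decision metadata."""

    calls: pd.DataFrame  # bool, features x samples
    method: str
    params: dict = field(default_factory=dict)


def call_expressed(
    m: pd.DataFrame,
    method: str = "global_mixture",
    threshold: float | None = None,
    seed: int = 0,
) -> DetectionMatrix:
    """Call each entry of a log2 matrix expressed (True) or silenced (False)."""
    values = m.to_numpy(float)
    if method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold")
        return DetectionMatrix(
            calls=pd.DataFrame(values > threshold, index=m.index, columns=m.columns),
            method="fixed_threshold",
            params={"threshold": float(threshold)},
        )
    if method != "global_mixture":
        raise ValueError(f"unknown method {method!r}")
    if m.shape[1] < 20:
        raise ValueError("global_mixture needs >= 20 samples for a stable fit")
    flat = values.reshape(-1, 1)
    degenerate = flat.var() == 0
    if not degenerate:
        gm = GaussianMixture(n_components=2, n_init=1, random_state=seed)
        gm.fit(flat)
        means = gm.means_.ravel()
        var = gm.covariances_.ravel()
        degenerate = (
            np.min(gm.weights_) < 1e-3
            or np.min(var) < 1e-8
            or abs(means[0] - means[1]) < 1e-6
        )
    if degenerate:
        fallback = float(threshold) if threshold is not None else float(np.median(flat))
        warnings.warn(
            "degenerate mixture fit; falling back to fixed_threshold "
            f"t={fallback:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        return call_expressed(m, "fixed_threshold", threshold=fallback)
    hi = int(np.argmax(means))
    post = gm.predict_proba(flat)[:, hi].reshape(values.shape)
    return DetectionMatrix(
        calls=pd.DataFrame(post >= 0.5, index=m.index, columns=m.columns),
        method="global_mixture",
        params={
            "means": means.tolist(),
            "variances": var.tolist(),
            "weights": gm.weights_.ravel().tolist(),
            "seed": seed,
        },
    )


def filter_by_prevalence(d: DetectionMatrix, min_fraction: float) -> list[str]:
    """Features expressed in at least ``min_fraction`` of samples (inclusive)."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be within [0, 1]")
    frac = d.calls.mean(axis=1)
    return list(d.calls.index[frac >= min_fraction])


def _design(batches: pd.Series, covariates: pd.Series | None) -> tuple[np.ndarray, int]:
    batch_dummies = pd.get_dummies(batches).to_numpy(float)
    n_batch = batch_dummies.shape[1]
    if covariates is not None:
        cov = pd.get_dummies(pd.Series(covariates), drop_first=True).to_numpy(float)
        return np.hstack([batch_dummies, cov]), n_batch
    return batch_dummies, n_batch


def combat_adjust(
    m: pd.DataFrame,
    batches: pd.Series,
    covariates: pd.Series | None = None,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Remove batch effects with the parametric empirical-Bayes model.

    Parameters
    ----------
    m:
        log2 matrix, genes x samples.
    batches:
        sample -> batch label; every sample must be labeled and every batch
        must contain at least two samples.
    covariates:
        optional sample -> group labels protected in the standardization
        design (biological structure that must not be removed).
    """
    missing = sorted(set(m.columns) - set(batches.index))
    if missing:
        raise ValueError(f"samples without batch label: {', '.join(missing)}")
    batches = batches.loc[m.columns].astype(str)
    counts = batches.value_counts()
    if len(counts) < 2:
        raise ValueError("single-batch input: nothing to adjust")
    singles = sorted(counts.index[counts < 2])
    if singles:
        raise ValueError(f"singleton batch(es): {', '.join(singles)}")
    if covariates is not None:
        covariates = pd.Series(covariates).loc[m.columns]

    Y = m.to_numpy(float)
    n_genes, n = Y.shape
    design, n_batch = _design(batches, covariates)
    batch_ids = list(pd.get_dummies(batches).columns)
    batch_masks = [(batches == b).to_numpy() for b in batch_ids]
    n_batches_arr = np.array([mask.sum() for mask in batch_masks], float)

    # genes with zero variance inside any batch are passed through unadjusted
    flat = np.zeros(n_genes, bool)
    for mask in batch_masks:
        flat |= Y[:, mask].var(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} gene(s) with zero within-batch variance "
            "passed through unadjusted",
            RuntimeWarning,
            stacklevel=2,
        )

    ok = ~flat
    full = Y
    Y = Y[ok]
    n_genes = Y.shape[0]
    if n_genes == 0:
        return pd.DataFrame(full, index=m.index, columns=m.columns)

    B_hat = np.linalg.solve(design.T @ design, design.T @ Y.T)  # (p, genes)
    grand_mean = (n_batches_arr / n) @ B_hat[:n_batch]
    resid = Y - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)  # divides by n, reference convention
    var_pooled = np.where(var_pooled <= 0, np.nan, var_pooled)

    stand_mean = np.tile(grand_mean[:, None], (1, n))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + (design[:, n_batch:] @ B_hat[n_batch:]).T
    scale = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / scale

    gamma_hat = np.stack([Z[:, mask].mean(axis=1) for mask in batch_masks])
    delta_hat = np.stack([Z[:, mask].var(axis=1, ddof=1) for mask in batch_masks])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)

    def a_prior(d: np.ndarray) -> float:
        mu, s2 = d.mean(), d.var(ddof=1)
        return (2 * s2 + mu**2) / s2

    def b_prior(d: np.ndarray) -> float:
        mu, s2 = d.mean(), d.var(ddof=1)
        return (mu * s2 + mu**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, mask in enumerate(batch_masks):
        a, b = a_prior(delta_hat[i]), b_prior(delta_hat[i])
        nb = n_batches_arr[i]
        g_old = gamma_hat[i].copy()
        d_old = delta_hat[i].copy()
        zi = Z[:, mask]
        for _ in range(max_iter):
            g_new = (t2[i] * nb * gamma_hat[i] + d_old * gamma_bar[i]) / (
                t2[i] * nb + d_old
            )
            sum2 = ((zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b) / (nb / 2.0 + a - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                np.max(np.abs(d_new - d_old) / np.abs(d_old)),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        gamma_star[i], delta_star[i] = g_old, d_old

    adjusted = Z.copy()
    for i, mask in enumerate(batch_masks):
        adjusted[:, mask] = (Z[:, mask] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    adjusted = adjusted * scale + stand_mean
    bad = ~np.isfinite(adjusted).all(axis=1)
    adjusted[bad] = Y[bad]
    out = full.copy()
    out[ok] = adjusted
    return pd.DataFrame(out, index=m.index, columns=m.columns)
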