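"""Parametric empirical-Bayes batch correction (location/scale model).

For peak g, sample j in batch i the model is

    Y_gij = alpha_g + gamma_ig + delta_ig * eps_gij,   eps ~ N(0, sigma_g^2)

Per-peak data are standardized, batch location effects are shrunk toward a
normal prior and batch scale effects toward an inverse-gamma prior, with
hyperparameters estimated by method of moments across peaks; the shrunken
effects are then removed and the data returned on the input scale.

Operates on a peaks x samples array of (log) intensities. NaNs are allowed
and excluded pairwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["combat"]


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = np.nanmean(delta_hat), np.nanvar(delta_hat, ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = np.nanmean(delta_hat), np.nanvar(delta_hat, ddof=1)
    return (m * s2 + m ** 3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterate the conditional posterior means for one batch until the
    relative change drops below ``conv``."""
    n = np.sum(~np.isnan(s_data), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    while True:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.nanmax(np.abs(g_new - g_old) / np.abs(g_old)),
            np.nanmax(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(data: np.ndarray, batch: np.ndarray, conv: float = 1e-4) -> np.ndarray:
    """Remove batch location/scale effects from a peaks x samples array.

    Parameters
    ----------
    data : (n_peaks, n_samples) float array of log intensities, NaN allowed.
    batch : (n_samples,) batch labels.
    """
    data = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    levels, inv = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    if n_batch < 2:
        raise ValueError("batch correction needs >= 2 batches")
    batch_masks = [inv == i for i in range(n_batch)]
    for lev, mask in zip(levels, batch_masks):
        if mask.sum() < 2:
            raise ValueError(f"batch {lev!r} has fewer than 2 samples")

    n_per = np.array([
        np.sum(~np.isnan(data[:, m]), axis=1) for m in batch_masks
    ]).T.astype(float)  # peaks x batches
    if np.any(n_per.sum(axis=1) < 2):
        raise ValueError("some peak has fewer than 2 non-missing samples")

    # --- standardize ------------------------------------------------------
    batch_mean = np.column_stack(
        [np.nanmean(data[:, m], axis=1) for m in batch_masks])  # peaks x batches
    weights = n_per / n_per.sum(axis=1, keepdims=True)
    grand_mean = np.sum(weights * batch_mean, axis=1)

    fitted = batch_mean[:, inv]
    resid = data - fitted
    var_pooled = np.nansum(resid ** 2, axis=1) / np.sum(~np.isnan(data), axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)

    z = (data - grand_mean[:, None]) / sd[:, None]

    # --- EB batch effect estimates ---------------------------------------
    gamma_hat = np.column_stack([np.nanmean(z[:, m], axis=1) for m in batch_masks])
    delta_hat = np.column_stack([np.nanvar(z[:, m], axis=1, ddof=1)
                                 for m in batch_masks])
    gamma_bar = np.mean(gamma_hat, axis=0)
    t2 = np.var(gamma_hat, axis=0, ddof=1)

    adjusted = z.copy()
    for i, m in enumerate(batch_masks):
        a, b = _aprior(delta_hat[:, i]), _bprior(delta_hat[:, i])
        g_star, d_star = _it_sol(
            z[:, m], gamma_hat[:, i], delta_hat[:, i], gamma_bar[i], t2[i],
            a, b, conv=conv)
        adjusted[:, m] = (z[:, m] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    return adjusted * sd[:, None] + grand_mean[:, None]
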