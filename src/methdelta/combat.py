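"""Parametric empirical-Bayes batch correction (ComBat-style).

Per-probe batch location and scale effects are estimated after
standardization, shrunk toward across-probe empirical priors (normal on
location, inverse-gamma on scale), removed, and the data restored to the
original scale with any preserved covariate effects intact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MethMatrix, validate_sample_sheet


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch, g_hat, d_hat, gamma_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterate the EB posterior-mean equations for one batch."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * gamma_bar) / (t2 * n + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    matrix: MethMatrix,
    sheet: pd.DataFrame,
    covariates_to_preserve: np.ndarray | None = None,
) -> MethMatrix:
    """Remove batch location/scale effects from an M-value matrix.

    Parameters
    ----------
    matrix : MethMatrix on the "m" scale.
    sheet : sample sheet with a ``batch`` column, one row per sample.
    covariates_to_preserve : optional samples x q design (no intercept)
        whose effects are estimated jointly and restored unchanged.
    """
    if matrix.scale != "m":
        raise ValueError("batch correction expects M-values")
    validate_sample_sheet(sheet)
    sheet = sheet.set_index("sample_id").loc[matrix.sample_ids]
    batches = sheet["batch"].to_numpy()
    levels, inverse = np.unique(batches, return_inverse=True)
    counts = np.bincount(inverse)
    if len(levels) == 1:
        return matrix.with_values(matrix.values.copy())
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(
            f"singleton batch(es) {list(bad)}: each batch needs >= 2 samples"
        )

    x = matrix.values
    n_probes, n_samples = x.shape
    n_batch = len(levels)
    batch_design = np.zeros((n_samples, n_batch))
    batch_design[np.arange(n_samples), inverse] = 1.0
    if covariates_to_preserve is not None:
        mod = np.atleast_2d(np.asarray(covariates_to_preserve, dtype=float))
        if mod.shape[0] != n_samples:
            raise ValueError("covariate design must have one row per sample")
        design = np.hstack([batch_design, mod])
    else:
        mod = None
        design = batch_design

    # per-probe OLS on [batch indicators, covariates]
    b_hat = np.linalg.solve(design.T @ design, design.T @ x.T).T
    grand_mean = b_hat[:, :n_batch] @ (counts / n_samples)
    fitted = b_hat @ design.T
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    mod_part = b_hat[:, n_batch:] @ mod.T if mod is not None else 0.0

    stand = grand_mean[:, None] + mod_part
    z = (x - stand) / np.sqrt(var_pooled)[:, None]

    z_adj = np.empty_like(z)
    gamma_hats = np.stack([z[:, inverse == i].mean(axis=1) for i in range(n_batch)])
    gamma_bar = gamma_hats.mean(axis=1)
    t2 = gamma_hats.var(axis=1, ddof=1)
    for i in range(n_batch):
        idx = inverse == i
        zb = z[:, idx]
        g_hat = gamma_hats[i]
        d_hat = zb.var(axis=1, ddof=1)
        g_star, d_star = _it_sol(
            zb, g_hat, d_hat, gamma_bar[i], t2[i], _aprior(d_hat), _bprior(d_hat)
        )
        z_adj[:, idx] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = z_adj * np.sqrt(var_pooled)[:, None] + stand
    return matrix.with_values(out)
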