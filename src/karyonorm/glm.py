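"""Vectorized IRLS for the per-gene negative-binomial GLM with offsets.

Model, per gene g with known dispersion alpha_g:

    K_gj ~ NB(mu_gj, alpha_g),  log mu_gj = o_gj + beta0_g + beta1_g * x_j

where o_gj = log f_gj are the combined normalization offsets and x_j is the
subline indicator.  All genes are fit simultaneously with closed-form 2x2
weighted-least-squares updates; the Wald statistic is beta1 / SE(beta1)
with the SE taken from the expected information at the fit.
"""

from __future__ import annotations

import numpy as np

_MAX_ETA = 50.0


def nb_irls(
    counts: np.ndarray,
    offsets: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Fit log mu = offset + beta0 + beta1*x for every row of ``counts``.

    Returns arrays ``beta0``, ``beta1``, ``se0``, ``se1`` and a boolean
    ``converged``.  Rows where either design group has zero total count are
    left as NaN with ``converged`` False (the MLE is at infinity).
    """
    K = np.asarray(counts, dtype=float)
    o = np.asarray(offsets, dtype=float)
    x = np.asarray(x, dtype=float)
    a = np.asarray(alpha, dtype=float)[:, None]
    n_genes = K.shape[0]

    in_alt = x > 0.5
    sum_ref = K[:, ~in_alt].sum(axis=1)
    sum_alt = K[:, in_alt].sum(axis=1)
    fittable = (sum_ref > 0) & (sum_alt > 0)

    eo = np.exp(o)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ref = sum_ref / eo[:, ~in_alt].sum(axis=1)
        r_alt = sum_alt / eo[:, in_alt].sum(axis=1)
    beta0 = np.where(fittable, np.log(np.maximum(r_ref, 1e-300)), np.nan)
    beta1 = np.where(fittable, np.log(np.maximum(r_alt, 1e-300)) - np.log(np.maximum(r_ref, 1e-300)), np.nan)

    active = fittable.copy()
    converged = np.zeros(n_genes, dtype=bool)
    A = np.full(n_genes, np.nan)
    det = np.full(n_genes, np.nan)
    C = np.full(n_genes, np.nan)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = np.clip(o[idx] + beta0[idx, None] + beta1[idx, None] * x[None, :], -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        W = mu / (1.0 + a[idx] * mu)
        z = (eta - o[idx]) + (K[idx] - mu) / mu

        Ai = W.sum(axis=1)
        Bi = (W * x).sum(axis=1)
        Ci = (W * x * x).sum(axis=1)
        b1 = (W * z).sum(axis=1)
        b2 = (W * z * x).sum(axis=1)
        deti = Ai * Ci - Bi * Bi
        ok = deti > 1e-300
        new0 = np.where(ok, (Ci * b1 - Bi * b2) / np.where(ok, deti, 1.0), beta0[idx])
        new1 = np.where(ok, (Ai * b2 - Bi * b1) / np.where(ok, deti, 1.0), beta1[idx])
        # damp extreme steps to keep eta in range
        new1 = np.clip(new1, -30.0, 30.0)
        new0 = np.clip(new0, -300.0, 300.0)

        delta = np.maximum(np.abs(new0 - beta0[idx]), np.abs(new1 - beta1[idx]))
        beta0[idx] = new0
        beta1[idx] = new1
        A[idx], det[idx], C[idx] = Ai, deti, Ci
        done = (delta < tol) & ok
        converged[idx[done]] = True
        active[idx[done]] = False
        active[idx[~ok]] = False

    # expected information evaluated at the final coefficients
    idx = np.where(fittable)[0]
    if len(idx):
        eta = np.clip(o[idx] + beta0[idx, None] + beta1[idx, None] * x[None, :], -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        W = mu / (1.0 + a[idx] * mu)
        A[idx] = W.sum(axis=1)
        Bi = (W * x).sum(axis=1)
        C[idx] = (W * x * x).sum(axis=1)
        det[idx] = A[idx] * C[idx] - Bi * Bi
    with np.errstate(divide="ignore", invalid="ignore"):
        se0 = np.sqrt(C / det)
        se1 = np.sqrt(A / det)
    bad = ~fittable | ~np.isfinite(se1)
    for arr in (beta0, beta1, se0, se1):
        arr[bad] = np.nan
    converged[bad] = False
    return {
        "beta0": beta0,
        "beta1": beta1,
        "se0": se0,
        "se1": se1,
        "converged": converged,
        "fittable": fittable,
    }
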