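"""Variance-stabilizing normalization and exploratory structure.

Raw label-free intensities show a strong mean-variance relationship:
multiplicative noise dominates bright proteins, an additive floor dominates
dim ones.  Under the additive-multiplicative error model the transform

    h_s(x) = arsinh((x - a_s) / b_s)

with per-sample offset ``a_s`` and scale ``b_s > 0`` renders the variance
approximately constant in intensity, and for large arguments differences of
``h`` converge to differences of natural logs, so fold changes keep their
usual log-ratio reading.

The calibration parameters are estimated by maximizing the profile
likelihood of the model (residual term plus the Jacobian of the transform),
made robust against the differentially expressed minority by least-trimmed
squares: after each fit the rows with the largest residual sums are set
aside and the fit repeated on the quietest fraction until the retained set
stabilizes.

Also here: per-protein z-scoring, complete-linkage hierarchical clustering
and PCA used for the heatmap / sample-map views of the normalized matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .containers import AbundanceMatrix, NormalizedMatrix, ValidationError


class FitError(RuntimeError):
    """Raised when the calibration fit fails or degenerates."""


def _neg_profile_loglik(params: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative profile log-likelihood and gradient.

    params = [a_1..a_S, log b_1..log b_S]; x is the retained rows x samples
    block.  Row means of h are profiled out analytically.
    """
    n_rows, n_samp = x.shape
    a = params[:n_samp]
    b = np.exp(params[n_samp:])
    u = (x - a) / b
    h = np.arcsinh(u)
    mu = h.mean(axis=1, keepdims=True)
    r = h - mu
    rss = float(np.sum(r * r))
    n_tot = x.size
    # Jacobian of the transform: h'(x) = 1 / sqrt(b^2 + (x-a)^2)
    d2 = b**2 + (x - a) ** 2
    f = 0.5 * n_tot * np.log(rss + 1e-300) + 0.5 * np.sum(np.log(d2))
    w = 1.0 / np.sqrt(d2)  # = h'
    # dh/da = -w ; dh/db = -(x-a) * w / b ; d(log-jac term)/d. analytic
    coef = n_tot / (rss + 1e-300)
    grad_a = np.sum(-coef * r * w - (x - a) * w * w, axis=0)
    grad_b = np.sum(-coef * r * (x - a) * w / b + b * w * w, axis=0)
    grad_logb = grad_b * b
    return f, np.concatenate([grad_a, grad_logb])


def vsn_normalize(
    m: AbundanceMatrix,
    trim: float = 0.10,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> NormalizedMatrix:
    """Fit the per-sample glog calibration and transform the matrix.

    Parameters
    ----------
    m
        Raw abundance matrix (>= 10 proteins, >= 2 samples, positive values).
    trim
        Fraction of rows excluded per robustness iteration — the rows with
        the largest residual sums, which is where differential proteins end
        up.  10% by default.
    max_iter
        Cap on least-trimmed-squares reselection rounds.
    tol
        Convergence tolerance on the relative calibration parameter change
        (offsets live on the raw intensity scale, so an absolute tolerance
        would be meaningless across instruments).
    """
    x = m.intensities.to_numpy(dtype=float)
    n_rows, n_samp = x.shape
    if n_samp < 2:
        raise ValidationError("need >= 2 samples")
    if n_rows < 10:
        raise ValidationError("need >= 10 proteins")
    col_sd = x.std(axis=0)
    if np.any(col_sd == 0):
        bad = list(m.intensities.columns[col_sd == 0])
        raise FitError(f"degenerate constant sample(s): {bad}")

    # init: zero offsets, scales at the per-sample median so that typical
    # arguments of arsinh are O(1)
    a0 = np.zeros(n_samp)
    b0 = np.median(x, axis=0)
    params = np.concatenate([a0, np.log(b0)])

    n_keep = max(10, int(np.ceil((1.0 - trim) * n_rows)))
    keep = np.arange(n_rows)
    iters = 0
    for iters in range(1, max_iter + 1):
        bounds = [(None, None)] * n_samp + [
            (lb - 40.0, lb + 40.0) for lb in np.log(b0)
        ]
        res = minimize(
            _neg_profile_loglik,
            params,
            args=(x[keep],),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        new_params = res.x
        a = new_params[:n_samp]
        b = np.exp(new_params[n_samp:])
        h_all = np.arcsinh((x - a) / b)
        row_rss = np.sum((h_all - h_all.mean(axis=1, keepdims=True)) ** 2, axis=1)
        new_keep = np.sort(np.argsort(row_rss)[:n_keep])
        rel_change = np.max(np.abs(new_params - params) / (1.0 + np.abs(params)))
        converged = np.array_equal(new_keep, keep) and rel_change < tol
        params, keep = new_params, new_keep
        if converged:
            break

    a = params[:n_samp]
    b = np.exp(params[n_samp:])
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise FitError(f"non-positive or non-finite scale estimate: {b}")
    h = np.arcsinh((x - a) / b)
    values = pd.DataFrame(h, index=m.intensities.index, columns=m.intensities.columns)
    return NormalizedMatrix(
        values=values,
        offsets=pd.Series(a, index=m.intensities.columns),
        scales=pd.Series(b, index=m.intensities.columns),
        groups=m.groups.copy(),
        protease=m.protease.copy(),
        diagnostics={"iterations": iters, "trimmed_fraction": 1.0 - n_keep / n_rows},
    )


def zscore_by_protein(
    nm: NormalizedMatrix | pd.DataFrame, protein_subset=None
) -> pd.DataFrame:
    """Row-wise z-transform (sample sd, ddof=1) of selected proteins.

    Raises on zero-variance rows, naming the offending protein.
    """
    values = nm.values if isinstance(nm, NormalizedMatrix) else nm
    if protein_subset is not None:
        protein_subset = list(protein_subset)
        if not protein_subset:
            raise ValidationError("empty protein subset")
        missing = set(protein_subset) - set(values.index)
        if missing:
            raise ValidationError(f"unknown proteins: {sorted(missing)}")
        values = values.loc[protein_subset]
    if values.shape[1] < 2:
        raise ValidationError("need >= 2 samples to z-score")
    sd = values.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValidationError(f"zero-variance protein(s): {list(zero.index)}")
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


def hierarchical_cluster(z: pd.DataFrame, axis: int = 0) -> dict:
    """Complete-linkage, Euclidean-metric agglomerative clustering.

    axis=0 clusters rows (proteins), axis=1 clusters columns (samples).
    Returns the SciPy linkage matrix, the leaf order and the item labels.
    Merge heights are non-decreasing (complete linkage is monotone).
    """
    data = z.to_numpy(dtype=float)
    labels = list(z.index if axis == 0 else z.columns)
    if axis == 1:
        data = data.T
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    if not np.all(np.isfinite(data)):
        raise ValidationError("non-finite values in clustering input")
    link = complete(pdist(data, metric="euclidean"))
    order = [labels[i] for i in leaves_list(link)]
    return {"linkage": link, "leaf_order": order, "labels": labels}


def pca(data: pd.DataFrame, n_components: int | None = None) -> dict:
    """PCA of samples (columns) in protein space via SVD of centered data.

    Returns sample scores, orthonormal loadings, and explained-variance
    fractions (non-increasing, summing to <= 1 when truncated).
    """
    x = data.to_numpy(dtype=float).T  # samples x proteins
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValidationError("need >= 2 samples and >= 2 features")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        (u * s)[:, :k], index=data.columns,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=data.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return {"scores": scores, "loadings": loadings, "explained_var": frac[:k]}
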