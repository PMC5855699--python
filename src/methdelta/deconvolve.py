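"""Two-stage deconvolution of whole-blood methylation.

Stage one removes latent structure: surrogate variables are the top
right singular vectors of the row-centered M-value matrix, and each
probe is residualized on them (per timepoint dataset). Stage two
estimates the mixing proportions of seven leukocyte subtypes per sample
by constrained least squares against a cell-type signature reference;
the proportions enter the paired models as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import MethMatrix

#: weight of the sum-to-one pseudo-observation in the augmented NNLS
_SUM_WEIGHT = 1000.0


def estimate_cell_proportions(
    matrix: MethMatrix, reference: pd.DataFrame
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions from beta values.

    Solves ``min ||S w - b||^2  s.t.  w >= 0, sum(w) = 1`` per sample
    over the signature probes shared between matrix and reference, via
    nonnegative least squares with a heavily weighted sum-to-one
    pseudo-row followed by exact renormalization.
    """
    if matrix.scale != "beta":
        raise ValueError("cell deconvolution runs on beta values")
    shared = [p for p in reference.index if p in set(matrix.probe_ids)]
    if len(shared) < reference.shape[1]:
        raise ValueError(
            f"only {len(shared)} signature probes shared; need >= "
            f"{reference.shape[1]}"
        )
    s = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(s) < s.shape[1]:
        raise ValueError("reference is rank-deficient on the shared probes")
    b = matrix.subset_probes(shared).values
    s_aug = np.vstack([s, _SUM_WEIGHT * np.ones((1, s.shape[1]))])
    out = np.empty((matrix.n_samples, s.shape[1]))
    for j in range(matrix.n_samples):
        w, _ = nnls(s_aug, np.append(b[:, j], _SUM_WEIGHT))
        total = w.sum()
        out[j] = w / total if total > 0 else np.full_like(w, 1.0 / len(w))
    return pd.DataFrame(out, index=matrix.sample_ids, columns=reference.columns)


@dataclass
class SurrogateVariableSet:
    """Top-k right singular vectors of a row-centered M matrix."""

    sv: np.ndarray  # samples x k, orthonormal columns
    singular_values: np.ndarray
    var_explained: np.ndarray
    sample_ids: np.ndarray

    @property
    def k(self) -> int:
        return self.sv.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.sv, index=self.sample_ids,
            columns=[f"SV{i+1}" for i in range(self.k)],
        )


def compute_surrogate_variables(matrix: MethMatrix, k: int = 15) -> SurrogateVariableSet:
    """SVD-based surrogate variables, ordered by singular value.

    ``k`` is truncated (with a warning) if it exceeds the rank bound
    min(samples - 1, probes).
    """
    if matrix.scale != "m":
        raise ValueError("surrogate variables are computed on M-values")
    if k > matrix.n_samples - 1:
        raise ValueError(f"k={k} exceeds samples-1={matrix.n_samples - 1}")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    if k == 0:
        return SurrogateVariableSet(
            np.empty((matrix.n_samples, 0)), np.empty(0), np.empty(0),
            matrix.sample_ids,
        )
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((svals > svals[0] * 1e-12).sum()) if svals.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating")
        k = rank
    total = (svals**2).sum()
    return SurrogateVariableSet(
        sv=vt[:k].T,
        singular_values=svals[:k],
        var_explained=svals[:k] ** 2 / total if total > 0 else svals[:k] * 0,
        sample_ids=matrix.sample_ids,
    )


def residualize(matrix: MethMatrix, svs: SurrogateVariableSet) -> MethMatrix:
    """Remove surrogate-variable structure probe-wise, keeping location.

    Each probe is regressed (OLS) on an intercept plus the SVs; the
    returned values are the residuals plus the fitted intercept, so the
    probe's location is preserved. With k=0 this is the identity.
    """
    if not np.array_equal(svs.sample_ids, matrix.sample_ids):
        raise ValueError("surrogate variables were computed on a different sample set")
    if svs.k == 0:
        return matrix.with_values(matrix.values.copy())
    d = np.hstack([np.ones((matrix.n_samples, 1)), svs.sv])
    coefs = np.linalg.solve(d.T @ d, d.T @ matrix.values.T).T  # probes x (k+1)
    fitted = coefs @ d.T
    resid = matrix.values - fitted
    return matrix.with_values(resid + coefs[:, [0]])
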