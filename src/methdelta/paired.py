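"""Per-CpG paired repeated-measures tests with unstructured covariance.

For each probe, the model is

    M_ij = b0 + b1 * time_ij + gamma' cells_ij + e_ij

for subject i at times j in {baseline, pregnancy}, with the two
within-subject errors following an unstructured 2x2 covariance
(free variances at each time, free cross-time covariance), estimated by
iterated generalized least squares. b1 is the adjusted mean change in
M-value from baseline into the pregnancy window; its Wald t-test uses
the between-within degrees of freedom for within-subject effects,
df = n_subjects - rank(X) + 1, which reduces to the classical paired
t-test (df = n - 1) in the spherical no-covariate limit.

The implementation is vectorized across probes: the sample-level design
is shared, so per-iteration work per probe is a 2x2 weight update and a
small linear solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05

RESULT_COLUMNS = (
    "probe_id", "window", "estimate", "se", "p_value", "q_value",
    "significant_raw", "significant_fdr", "direction", "converged",
)


@dataclass
class PairedDesign:
    """Matched two-timepoint data for a set of probes.

    y0, y1 : subjects x probes residual M-values at baseline / pregnancy.
    covariates0, covariates1 : subjects x q covariates at each time
        (time-varying cell proportions); may be None.
    """

    y0: np.ndarray
    y1: np.ndarray
    probe_ids: np.ndarray
    subject_ids: np.ndarray
    covariates0: np.ndarray | None = None
    covariates1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y0 = np.atleast_2d(np.asarray(self.y0, dtype=float))
        self.y1 = np.atleast_2d(np.asarray(self.y1, dtype=float))
        if self.y0.shape != self.y1.shape:
            raise ValueError("baseline and pregnancy matrices must match")
        if (self.covariates0 is None) != (self.covariates1 is None):
            raise ValueError("covariates must be supplied at both times or neither")

    @property
    def n_subjects(self) -> int:
        return self.y0.shape[0]

    def design_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_subjects
        ones = np.ones((n, 1))
        if self.covariates0 is None:
            x0 = np.hstack([ones, np.zeros((n, 1))])
            x1 = np.hstack([ones, np.ones((n, 1))])
        else:
            c0 = np.atleast_2d(np.asarray(self.covariates0, dtype=float))
            c1 = np.atleast_2d(np.asarray(self.covariates1, dtype=float))
            x0 = np.hstack([ones, np.zeros((n, 1)), c0])
            x1 = np.hstack([ones, np.ones((n, 1)), c1])
        return x0, x1


def _drop_aliased(x0: np.ndarray, x1: np.ndarray):
    """Drop covariate columns until the stacked design is full rank."""
    stacked = np.vstack([x0, x1])
    keep = list(range(stacked.shape[1]))
    while len(keep) > 2 and np.linalg.matrix_rank(stacked[:, keep]) < len(keep):
        dropped = keep.pop()  # covariates sit at the end; drop from the right
        log.warning("dropping aliased design column %d", dropped)
    return x0[:, keep], x1[:, keep]


def fit_paired_design(
    design: PairedDesign,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Iterated-GLS fit of the paired model for every probe at once.

    Returns a frame with estimate (b1 = pregnancy - baseline), se,
    p_value, direction, and a convergence flag per probe. Probes with
    degenerate (singular) residual covariance are reported with
    estimate as fitted but p_value = 1.
    """
    x0, x1 = design.design_matrices()
    x0, x1 = _drop_aliased(x0, x1)
    n, p = x0.shape
    if n < 8:
        raise ValueError(f"need >= 8 complete pairs, got {n}")
    df = n - p + 1
    if df < 1:
        raise ValueError(f"within-subject df {df} < 1 (n={n}, rank={p})")

    y0, y1 = design.y0, design.y1  # subjects x probes
    n_probes = y0.shape[1]
    xs = (x0, x1)
    ys = (y0, y1)
    # C[j,k] = X_j' X_k (p x p); D[j,k] = X_j' Y_k (p x probes)
    c = np.array([[xs[j].T @ xs[k] for k in range(2)] for j in range(2)])
    d = np.array([[xs[j].T @ ys[k] for k in range(2)] for j in range(2)])

    w = np.broadcast_to(np.eye(2), (n_probes, 2, 2)).copy()
    sigma_old = np.broadcast_to(np.eye(2), (n_probes, 2, 2)).copy()
    beta = np.zeros((n_probes, p))
    converged = np.zeros(n_probes, dtype=bool)
    degenerate = np.zeros(n_probes, dtype=bool)
    a = np.empty((n_probes, p, p))

    for it in range(max_iter):
        a = np.einsum("qjk,jkab->qab", w, c)
        b = np.einsum("qjk,jkaq->qa", w, d)
        try:
            beta = np.linalg.solve(a, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = (np.linalg.pinv(a) @ b[..., None])[..., 0]
        e0 = y0 - x0 @ beta.T
        e1 = y1 - x1 @ beta.T
        s = np.empty((n_probes, 2, 2))
        s[:, 0, 0] = (e0 * e0).sum(axis=0)
        s[:, 1, 1] = (e1 * e1).sum(axis=0)
        s[:, 0, 1] = s[:, 1, 0] = (e0 * e1).sum(axis=0)
        sigma = s / df
        det = sigma[:, 0, 0] * sigma[:, 1, 1] - sigma[:, 0, 1] ** 2
        diag_scale = sigma[:, 0, 0] * sigma[:, 1, 1]
        # degenerate: vanishing residual variance or (near-)perfect
        # cross-time correlation; both make the 2x2 weight explode
        degenerate = (
            (sigma[:, 0, 0] <= 1e-12) | (sigma[:, 1, 1] <= 1e-12)
            | (det <= 1e-10 * np.maximum(diag_scale, 1e-300))
        )
        safe = np.where(degenerate[:, None, None], np.eye(2), sigma)
        w = np.linalg.inv(safe)
        delta = np.abs(sigma - sigma_old).max(axis=(1, 2))
        scale = np.abs(sigma_old).max(axis=(1, 2)) + 1e-30
        newly = delta / scale < tol
        converged |= newly | degenerate
        sigma_old = sigma
        if converged.all():
            break

    if not converged.all():
        log.warning(
            "%d probes not converged after %d iterations; "
            "using method-of-moments covariance", int((~converged).sum()), max_iter,
        )

    # final GLS pass with the converged weights
    a = np.einsum("qjk,jkab->qab", w, c)
    b = np.einsum("qjk,jkaq->qa", w, d)
    try:
        beta = np.linalg.solve(a, b[..., None])[..., 0]
        cov = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(a)
        beta = (cov @ b[..., None])[..., 0]
    estimate = beta[:, 1]
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, estimate / se, 0.0)
    p_value = 2.0 * stats.t.sf(np.abs(tstat), df)
    p_value = np.where(degenerate | (se == 0), 1.0, p_value)
    estimate = np.where(degenerate, 0.0, estimate)

    return pd.DataFrame({
        "probe_id": design.probe_ids,
        "estimate": estimate,
        "se": se,
        "p_value": p_value,
        "direction": np.sign(estimate).astype(int),
        "converged": converged,
    })


def fit_paired_gls(design: PairedDesign) -> pd.Series:
    """Single-probe convenience wrapper around :func:`fit_paired_design`."""
    if design.y0.shape[1] != 1:
        raise ValueError("fit_paired_gls expects a single probe")
    return fit_paired_design(design).iloc[0]


def build_paired_design(
    residuals_baseline,
    residuals_pregnancy,
    proportions: pd.DataFrame | None,
    sheet: pd.DataFrame,
    window: str,
) -> PairedDesign:
    """Assemble matched-subject data for one pregnancy window.

    ``residuals_*`` are MethMatrix objects (m scale, same probes);
    ``proportions`` holds per-sample cell proportions indexed by
    sample_id. Subjects present at both timepoints are matched through
    the sample sheet.
    """
    timepoint = {"first": "preg_first", "second": "preg_second"}[window]
    base = sheet[sheet["timepoint"] == "age18"].set_index("subject_id")
    preg = sheet[sheet["timepoint"] == timepoint].set_index("subject_id")
    subjects = sorted(set(base.index) & set(preg.index))
    if not subjects:
        raise ValueError(f"no subjects overlap between age18 and {timepoint}")
    s0 = base.loc[subjects, "sample_id"].to_numpy()
    s1 = preg.loc[subjects, "sample_id"].to_numpy()
    if not np.array_equal(residuals_baseline.probe_ids, residuals_pregnancy.probe_ids):
        raise ValueError("probe universes differ between timepoint datasets")
    y0 = residuals_baseline.subset_samples(s0).values.T
    y1 = residuals_pregnancy.subset_samples(s1).values.T
    cov0 = cov1 = None
    if proportions is not None:
        # drop one cell type: proportions sum to 1 and the model has an
        # intercept, so the full set would be aliased
        cols = list(proportions.columns[:-1])
        cov0 = proportions.loc[s0, cols].to_numpy(float)
        cov1 = proportions.loc[s1, cols].to_numpy(float)
    return PairedDesign(
        y0=y0, y1=y1,
        probe_ids=residuals_baseline.probe_ids,
        subject_ids=np.asarray(subjects, dtype=object),
        covariates0=cov0, covariates1=cov1,
    )


def run_all_probes(
    residuals_baseline,
    residuals_pregnancy,
    proportions: pd.DataFrame | None,
    sheet: pd.DataFrame,
    window: str,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Fit every probe for one window; deterministic given inputs."""
    design = build_paired_design(
        residuals_baseline, residuals_pregnancy, proportions, sheet, window
    )
    n_probes = len(design.probe_ids)
    log.info("paired GLS: window=%s, %d probes, %d pairs",
             window, n_probes, design.n_subjects)
    results = fit_paired_design(design)
    results.insert(1, "window", window)
    results["significant_raw"] = results["p_value"] <= alpha
    log.info("window=%s: %d/%d probes significant at p<=%.2g",
             window, int(results["significant_raw"].sum()), n_probes, alpha)
    return results


def adjust_fdr(
    results: pd.DataFrame,
    scope: list | np.ndarray | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values within a probe family.

    ``scope`` restricts the family to a probe subset (e.g., one pathway
    or one random draw); the returned frame covers only that family.
    """
    out = results if scope is None else results[
        results["probe_id"].isin(set(scope))
    ].copy()
    if len(out) == 0:
        out = out.copy()
        out["q_value"] = pd.Series(dtype=float)
        out["significant_fdr"] = pd.Series(dtype=bool)
        return out
    out = out.copy()
    _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["q_value"] = q
    out["significant_fdr"] = out["q_value"] <= alpha
    return out
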