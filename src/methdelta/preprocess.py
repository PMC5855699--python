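"""Probe filtering, beta/M transforms, and quantile normalization.

The analysis scale is the M-value, ``log2(beta / (1 - beta))``: beta
values are proportions and strongly heteroscedastic near 0 and 1, while
M-values are approximately Gaussian and suitable for linear modelling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import MethMatrix, validate_manifest

log = logging.getLogger(__name__)

#: clipping bound applied to beta before the logit, so M stays finite
BETA_CLIP = 1e-6

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def intensity_to_beta(meth, unmeth, c: float = 100.0):
    """Beta from methylated/unmethylated intensities: M / (c + M + U).

    The offset ``c`` (array convention: 100) guards against division by
    zero for probes with near-zero total intensity.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any() or c < 0:
        raise ValueError("intensities and offset must be nonnegative")
    denom = c + meth + unmeth
    if np.any(denom == 0):
        raise ZeroDivisionError("meth, unmeth and c are all zero")
    out = meth / denom
    return float(out) if out.ndim == 0 else out


def clip_beta(beta, bound: float = BETA_CLIP):
    return np.clip(beta, bound, 1.0 - bound)


def beta_to_m(beta):
    """log2 logit of beta; raises if beta is outside (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if (beta <= 0).any() or (beta >= 1).any():
        raise ValueError("beta must lie strictly in (0, 1); clip first")
    out = np.log2(beta / (1.0 - beta))
    return float(out) if out.ndim == 0 else out


def m_to_beta(m):
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out


def matrix_to_m(matrix: MethMatrix) -> MethMatrix:
    if matrix.scale != "beta":
        raise ValueError("matrix already on m scale")
    return matrix.with_values(beta_to_m(clip_beta(matrix.values)), scale="m")


def matrix_to_beta(matrix: MethMatrix) -> MethMatrix:
    if matrix.scale != "m":
        raise ValueError("matrix already on beta scale")
    return matrix.with_values(m_to_beta(matrix.values), scale="beta")


@dataclass
class FilterReport:
    n_input: int
    n_removed_snp: int
    n_removed_sexchrom: int
    n_output: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def filter_probes(matrix: MethMatrix, manifest: pd.DataFrame):
    """Drop probes with a common probe SNP (MAF > 1%) or on chrX/chrY.

    A probe flagged both ways is removed once and counted under the SNP
    rule (first applied). Idempotent.
    """
    validate_manifest(manifest)
    man = manifest.set_index("probe_id")
    missing = set(matrix.probe_ids) - set(man.index)
    if missing:
        raise KeyError(f"{len(missing)} matrix probes missing from manifest")
    man = man.loc[matrix.probe_ids]
    snp = man["snp_maf_gt_1pct"].to_numpy(bool)
    sexchrom = man["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()
    keep = ~(snp | sexchrom)
    report = FilterReport(
        n_input=matrix.n_probes,
        n_removed_snp=int(snp.sum()),
        n_removed_sexchrom=int((sexchrom & ~snp).sum()),
        n_output=int(keep.sum()),
    )
    out = MethMatrix(matrix.values[keep], matrix.probe_ids[keep],
                     matrix.sample_ids, matrix.scale)
    return out, report


def peak_correction(matrix: MethMatrix) -> MethMatrix:
    """Intensity-level peak/background correction placeholder.

    Peak correction and background-noise removal operate on raw channel
    intensities; starting from a beta matrix there is nothing to redo,
    so this stage is an explicit no-op kept for pipeline parity.
    """
    log.info("peak correction: no-op (pipeline input is a beta matrix)")
    return matrix


def quantile_normalize(matrix: MethMatrix) -> MethMatrix:
    """Force every sample (column) onto the same empirical distribution.

    The reference distribution is the row-wise mean of the sorted
    columns; tied values within a column receive the mean of the tied
    reference values (average ranks).
    """
    x = matrix.values
    n_probes, n_samples = x.shape
    if n_samples < 2:
        warnings.warn("quantile normalization skipped: single sample")
        return matrix
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n_probes + 1, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return matrix.with_values(out)
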