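"""Core containers shared across pipeline stages.

Tabular data (manifest, sample sheet, results) travels as pandas
DataFrames with documented schemas; the methylation matrix gets a thin
dataclass so the value scale (beta vs M) is carried explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TIMEPOINTS = ("age18", "preg_first", "preg_second")
PREGNANCY_WINDOWS = ("first", "second")
#: leukocyte subtypes of the whole-blood deconvolution reference
CELL_TYPES = ("B", "CD4T", "CD8T", "Eos", "Gran", "Mono", "NK")
REGION_TOKENS = ("TSS200", "TSS1500", "1stExon", "Body", "5UTR", "3UTR")

#: manifest column schema: probe_id, chrom, pos, genes (';'-joined),
#: region_groups (';'-joined tokens), snp_maf_gt_1pct (bool), pathway
#: ('' if none), cd4_gene (bool), signature_cell ('' if not a
#: deconvolution signature probe)
MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "genes",
    "region_groups",
    "snp_maf_gt_1pct",
    "pathway",
    "cd4_gene",
    "signature_cell",
)

SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "timepoint", "batch")


@dataclass
class MethMatrix:
    """Probes x samples methylation values on an explicit scale."""

    values: np.ndarray
    probe_ids: np.ndarray
    sample_ids: np.ndarray
    scale: str  # "beta" | "m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (probes x samples)")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("beta", "m"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if np.isnan(self.values).any():
            raise ValueError("methylation matrix contains missing values")
        if self.scale == "beta" and (
            (self.values <= 0).any() or (self.values >= 1).any()
        ):
            raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "MethMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    def subset_probes(self, probe_ids) -> "MethMatrix":
        idx = pd.Index(self.probe_ids).get_indexer(list(probe_ids))
        if (idx < 0).any():
            missing = np.asarray(list(probe_ids))[idx < 0][:5]
            raise KeyError(f"probes not in matrix: {list(missing)} ...")
        return MethMatrix(
            self.values[idx], np.asarray(list(probe_ids), dtype=object),
            self.sample_ids, self.scale,
        )

    def subset_samples(self, sample_ids) -> "MethMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = np.asarray(list(sample_ids))[idx < 0][:5]
            raise KeyError(f"samples not in matrix: {list(missing)} ...")
        return MethMatrix(
            self.values[:, idx], self.probe_ids,
            np.asarray(list(sample_ids), dtype=object), self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str) -> "MethMatrix":
        return cls(frame.to_numpy(dtype=float), frame.index.to_numpy(object),
                   frame.columns.to_numpy(object), scale)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad_tp = set(sheet["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    if sheet.duplicated(["subject_id", "timepoint"]).any():
        raise ValueError("(subject_id, timepoint) pairs must be unique")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample_id must be unique")
    return sheet


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS[:6]) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["probe_id"].duplicated().any():
        raise ValueError("probe_id must be unique")
    if (manifest["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return manifest


def split_tokens(joined: str) -> list[str]:
    """Split a ';'-joined manifest annotation field; '' means none."""
    if joined is None or (isinstance(joined, float) and np.isnan(joined)):
        return []
    joined = str(joined).strip()
    return [t for t in joined.split(";") if t] if joined else []
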