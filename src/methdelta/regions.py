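"""Gene-region classification and spatial clustering of CpGs.

450K manifest region tokens are collapsed to four groups (Body includes
the 1st exon; the two TSS windows form the Promoter), every probe gets
exactly one canonical combination label, and significant CpGs are
checked for significant same-direction neighbors within +/-1500 bp.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .core import split_tokens
from .enrichment import SubsetDraw

_TOKEN_MAP = {
    "TSS200": "Promoter",
    "TSS1500": "Promoter",
    "1stExon": "Body",
    "Body": "Body",
    "5UTR": "5'UTR",
    "5'UTR": "5'UTR",
    "3UTR": "3'UTR",
    "3'UTR": "3'UTR",
}

#: canonical ordering of groups inside a combination label
_GROUP_ORDER = ("Body", "3'UTR", "5'UTR", "Promoter")

#: the 13 standard composition rows (always reported, even when empty)
REGION_LABELS = (
    "Body, 3'UTR, and Promoter",
    "Body, 5'UTR, and Promoter",
    "Body and 3'UTR",
    "Body and 5'UTR",
    "Body and Promoter",
    "Body",
    "3'UTR and Promoter",
    "5'UTR and Promoter",
    "Promoter",
    "3'UTR and 5'UTR",
    "3'UTR",
    "5'UTR",
    "Intergenic",
)

#: rarer combinations, reported only when observed
_EXTRA_LABELS = (
    "Body, 3'UTR, and 5'UTR",
    "Body, 3'UTR, 5'UTR, and Promoter",
)


def classify_region(region_groups) -> str:
    """Canonical gene-region label from raw manifest tokens.

    Order-insensitive; unknown tokens raise. Empty input means the
    probe is intergenic.
    """
    if isinstance(region_groups, str):
        region_groups = split_tokens(region_groups)
    groups = set()
    for tok in region_groups:
        if tok not in _TOKEN_MAP:
            raise ValueError(f"unknown region token {tok!r}")
        groups.add(_TOKEN_MAP[tok])
    if not groups:
        return "Intergenic"
    ordered = [g for g in _GROUP_ORDER if g in groups]
    if len(ordered) == 1:
        return ordered[0]
    if len(ordered) == 2:
        return f"{ordered[0]} and {ordered[1]}"
    return ", ".join(ordered[:-1]) + f", and {ordered[-1]}"


def region_composition(probes, manifest: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of probes per region label."""
    man = manifest.set_index("probe_id")
    labels = [classify_region(man.at[p, "region_groups"]) for p in probes]
    counts = Counter(labels)
    total = len(labels)
    report_labels = list(REGION_LABELS) + [
        lab for lab in _EXTRA_LABELS if counts.get(lab, 0) > 0
    ]
    rows = [
        {"region": lab, "n": counts.get(lab, 0),
         "percent": round(100.0 * counts.get(lab, 0) / total, 1)}
        for lab in report_labels
    ]
    return pd.DataFrame(rows)


def exclude_intergenic(
    draw: SubsetDraw, universe, excluded, manifest: pd.DataFrame
) -> SubsetDraw:
    """Redraw a subset from the universe restricted to genic probes.

    The redraw reuses the draw's recorded child seed, so the result is
    deterministic and shares the original seed lineage.
    """
    man = manifest.set_index("probe_id")
    genic = [
        p for p in universe
        if classify_region(man.at[p, "region_groups"]) != "Intergenic"
    ]
    eligible = np.asarray(sorted(set(genic) - set(excluded)), dtype=object)
    size = len(draw.probe_ids)
    if len(eligible) < size:
        raise ValueError(
            f"only {len(eligible)} genic probes available; need {size}"
        )
    rng = np.random.default_rng(draw.seed)
    picked = rng.choice(eligible, size=size, replace=False)
    return SubsetDraw(draw.universe + "_genic", draw.draw_index, picked, draw.seed)


def cluster_significant(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    window_bp: int = 1500,
) -> pd.DataFrame:
    """Neighbor report for every significant CpG.

    For each CpG significant in ``results`` (significant_raw), all other
    probes on the same chromosome within ``window_bp`` (inclusive) are
    listed with their distance, significance, and direction concordance.
    Uses a sorted-position sweep per chromosome.
    """
    man = manifest.set_index("probe_id")
    res = results.set_index("probe_id")
    probes = [p for p in res.index if p in man.index]
    if len(probes) < len(res):
        raise KeyError("positions unavailable for some result probes")
    info = pd.DataFrame({
        "chrom": man.loc[probes, "chrom"].astype(str).to_numpy(),
        "pos": man.loc[probes, "pos"].to_numpy(int),
        "significant": res.loc[probes, "significant_raw"].to_numpy(bool),
        "direction": res.loc[probes, "direction"].to_numpy(int),
    }, index=probes)

    rows = []
    for _, grp in info.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        ids = grp.index.to_numpy()
        sig = grp["significant"].to_numpy()
        direc = grp["direction"].to_numpy()
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        for i in np.flatnonzero(sig):
            for j in range(lo[i], hi[i]):
                if j == i:
                    continue
                rows.append({
                    "probe_id": ids[i],
                    "neighbor_id": ids[j],
                    "distance_bp": int(abs(pos[j] - pos[i])),
                    "neighbor_significant": bool(sig[j]),
                    "same_direction": bool(sig[j] and direc[j] == direc[i]),
                })
    return pd.DataFrame(
        rows, columns=["probe_id", "neighbor_id", "distance_bp",
                       "neighbor_significant", "same_direction"],
    )


def cluster_summary(report: pd.DataFrame, results: pd.DataFrame) -> dict:
    """Counts of clustered vs isolated significant CpGs."""
    sig = results[results["significant_raw"]]["probe_id"]
    clustered = set(
        report[report["neighbor_significant"] & report["same_direction"]]["probe_id"]
    )
    return {
        "n_significant": int(len(sig)),
        "n_with_same_direction_neighbor": len(clustered & set(sig)),
        "n_isolated": int(len(sig)) - len(clustered & set(sig)),
    }
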