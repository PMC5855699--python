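"""Published summary counts used for arithmetic cross-checks.

The subject-level methylation of the original cohort is not public;
what is public are the per-gene counts of significantly changed CpGs,
the pathway CpG totals, and the median significant proportions of the
random reference subsets. Those printed numbers are inputs here: the
functions below recompute pathway percentages and combined risk ratios
from them, which pins down the exact arithmetic conventions the rest of
the package implements.
"""

from __future__ import annotations

#: pathway CpG totals (denominators of the printed percentages)
PATHWAY_TOTALS = {"Th1": 155, "Th2": 77, "Th17": 106, "Treg": 10}

#: per-gene counts of significant CpGs (first half, second half)
SIGNIFICANT_BY_GENE = {
    "Th1": {
        "IFNG": (1, 1), "IFNGR1": (1, 1), "IFNGR2": (3, 4), "IL12A": (3, 2),
        "IL12B": (1, 1), "IL12RB1": (1, 2), "IL12RB2": (7, 8), "IL2": (0, 0),
        "IL2RA": (0, 0), "IL2RB": (1, 3), "TNF": (4, 6), "TNFAIP1": (1, 4),
        "TNFAIP2": (2, 4), "TNFAIP3": (4, 2), "TNFAIP6": (1, 1),
        "TNFAIP8": (9, 7), "TNFAIP8L": (4, 10),
    },
    "Th2": {
        "GATA3": (6, 4), "IL13": (1, 1), "IL13RA1": (5, 5), "IL13RA2": (1, 1),
        "IL1RL1": (2, 1), "IL4": (0, 0), "IL4R": (4, 4), "IL5": (0, 1),
        "IL5RA": (3, 3), "IL9": (0, 0), "JAK1": (3, 3), "JAK3": (1, 2),
        "STAT6": (1, 1),
    },
    "Th17": {
        "IL17A": (1, 0), "IL17B": (1, 2), "IL17C": (3, 2), "IL17D": (1, 2),
        "IL17F": (0, 0), "IL17RA": (5, 4), "IL17RC": (0, 0), "IL17RD": (4, 5),
        "IL17RE": (4, 2), "IL17REL": (5, 4), "IL21": (1, 1), "IL21R": (7, 7),
        "IL22": (0, 1), "IL22RA1": (1, 3), "IL22RA2": (1, 0),
    },
    "Treg": {"FOXP3": (3, 4), "CTLA4": (0, 0)},
}

#: median significant proportions (%) of the 10 random subsets, by
#: (universe, window, p basis)
MEDIAN_SUBSET_PROPORTION = {
    ("whole_genome", "first", "raw"): 24.1,
    ("whole_genome", "first", "fdr"): 12.9,
    ("whole_genome", "second", "raw"): 24.6,
    ("whole_genome", "second", "fdr"): 14.9,
    ("cd4", "first", "raw"): 24.0,
    ("cd4", "first", "fdr"): 10.4,
    ("cd4", "second", "raw"): 26.7,
    ("cd4", "second", "fdr"): 9.80,
}

#: published pathway significant proportions (%), by (window, p basis)
PATHWAY_PROPORTION = {
    ("Th1", "first", "raw"): 27.7, ("Th1", "first", "fdr"): 18.7,
    ("Th1", "second", "raw"): 36.1, ("Th1", "second", "fdr"): 25.2,
    ("Th2", "first", "raw"): 35.1, ("Th2", "first", "fdr"): 20.9,
    ("Th2", "second", "raw"): 33.8, ("Th2", "second", "fdr"): 26.0,
    ("Th17", "first", "raw"): 32.1, ("Th17", "first", "fdr"): 18.9,
    ("Th17", "second", "raw"): 31.1, ("Th17", "second", "fdr"): 22.6,
    ("Treg", "first", "raw"): 30.0, ("Treg", "first", "fdr"): 20.0,
    ("Treg", "second", "raw"): 40.0, ("Treg", "second", "fdr"): 30.0,
}


def pathway_count(pathway: str, window: str) -> int:
    """Total significant CpGs in a pathway, summed over its genes."""
    idx = {"first": 0, "second": 1}[window]
    return sum(v[idx] for v in SIGNIFICANT_BY_GENE[pathway].values())


def pathway_percentage(pathway: str, window: str) -> float:
    """Significant percentage computed from the per-gene counts."""
    return round(100.0 * pathway_count(pathway, window) / PATHWAY_TOTALS[pathway], 1)


def combined_rr(pathway: str, window: str, universe: str,
                p_basis: str = "raw") -> float:
    """Pathway proportion over the median subset proportion, 2 dp."""
    prop = PATHWAY_PROPORTION[(pathway, window, p_basis)]
    med = MEDIAN_SUBSET_PROPORTION[(universe, window, p_basis)]
    return round(prop / med, 2)
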