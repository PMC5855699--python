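"""Resampling-based pathway enrichment via risk ratios.

The proportion of significant CpGs in each T-cell pathway (Th1, Th2,
Th17, Treg) is compared against 10 size-matched random CpG subsets
drawn from a reference universe (all eligible probes, or probes of
genes expressed in CD4+ cells). Each comparison is a log-linear
(log-binomial) model whose exponentiated group coefficient is the risk
ratio; the 10 draws are combined through the median subset proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

log = logging.getLogger(__name__)

PATHWAYS = ("Th1", "Th2", "Th17", "Treg")
#: post-filter pathway CpG counts at the default configuration
PATHWAY_SIZES_DEFAULT = {"Th1": 155, "Th2": 77, "Th17": 106, "Treg": 10}
N_DRAWS_DEFAULT = 10
#: fixed offset deriving per-draw child seeds from the master seed
_SEED_STRIDE = 1_000_003


def significant_proportion(results: pd.DataFrame, probes, p_basis: str = "raw",
                           alpha: float = 0.05) -> float:
    """Percentage of probes significant on the chosen basis, 1 decimal."""
    probes = list(probes)
    if not probes:
        raise ValueError("empty probe list")
    col = {"raw": "p_value", "fdr": "q_value"}[p_basis]
    sub = results.set_index("probe_id").reindex(probes)
    if sub[col].isna().any():
        missing = sub.index[sub[col].isna()][:5]
        raise KeyError(f"probes without a result: {list(missing)} ...")
    k = int((sub[col] <= alpha).sum())
    return round(100.0 * k / len(probes), 1)


@dataclass
class SubsetDraw:
    universe: str  # "whole_genome" | "cd4"
    draw_index: int  # 1-based
    probe_ids: np.ndarray
    seed: int


def draw_subsets(
    universe,
    excluded,
    size: int,
    n_draws: int = N_DRAWS_DEFAULT,
    seed: int = 0,
    universe_name: str = "whole_genome",
) -> list[SubsetDraw]:
    """Draw ``n_draws`` random CpG subsets of ``size`` without replacement.

    Pathway probes (``excluded``) never appear in a draw. Each draw uses
    a child seed derived from the master seed by a fixed stride, so the
    full set of draws is reproducible and individually re-derivable.
    """
    eligible = np.asarray(sorted(set(universe) - set(excluded)), dtype=object)
    if len(eligible) < size:
        raise ValueError(
            f"universe has only {len(eligible)} eligible probes; need {size}"
        )
    log.info("drawing %d subsets of %d from %s universe of %d eligible probes",
             n_draws, size, universe_name, len(eligible))
    draws = []
    for i in range(n_draws):
        child_seed = int((seed + _SEED_STRIDE * (i + 1)) % (2**31))
        rng = np.random.default_rng(child_seed)
        picked = rng.choice(eligible, size=size, replace=False)
        draws.append(SubsetDraw(universe_name, i + 1, picked, child_seed))
    return draws


def _katz_ci(a, n1, b, n2):
    rr = (a / n1) / (b / n2)
    se = np.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    return rr, rr * np.exp(-1.96 * se), rr * np.exp(1.96 * se)


def loglinear_rr(pathway_flags, subset_flags):
    """Risk ratio of significance, pathway vs subset, with Wald 95% CI.

    Fits a binomial GLM with log link on the group indicator; for this
    saturated two-group layout the exponentiated coefficient equals the
    ratio of proportions and the Wald interval equals the classical
    Katz interval. Zero cells fall back to adding 0.5 to every cell of
    the implied 2x2 table.
    """
    pf = np.asarray(pathway_flags, dtype=float)
    sf = np.asarray(subset_flags, dtype=float)
    if len(pf) == 0 or len(sf) == 0:
        raise ValueError("both groups must be nonempty")
    a, n1 = pf.sum(), len(pf)
    b, n2 = sf.sum(), len(sf)
    if a + b == 0:
        raise ValueError("no significant CpGs in either group: RR undefined")
    if a == n1 and b == n2:
        raise ValueError("all CpGs significant in both groups: RR undefined")
    if a == 0 or b == 0 or a == n1 or b == n2:
        log.info("zero cell in 2x2 (a=%d/%d, b=%d/%d): adding 0.5 to all cells",
                 a, n1, b, n2)
        return _katz_ci(a + 0.5, n1 + 1.0, b + 0.5, n2 + 1.0)
    y = np.concatenate([pf, sf])
    x = sm.add_constant(np.concatenate([np.ones(int(n1)), np.zeros(int(n2))]))
    p_pooled = y.mean()
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            # statsmodels warns that the log link can leave the binomial
            # domain; fitted probabilities here stay in (0, 1)
            _warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, x, family=sm.families.Binomial(sm.families.links.Log())
            ).fit(start_params=[np.log(p_pooled), 0.0], maxiter=200)
        rr = float(np.exp(fit.params[1]))
        lo, hi = np.exp(fit.conf_int()[1])
        return rr, float(lo), float(hi)
    except Exception:  # log-link binomial can fail off the boundary
        log.warning("log-binomial GLM failed; using closed-form 2x2 estimate")
        return _katz_ci(a, n1, b, n2)


@dataclass
class EnrichmentResult:
    pathway: str
    window: str
    universe: str
    p_basis: str
    n_cpgs: int
    pathway_proportion: float
    subset_proportions: list[float]
    median_subset_proportion: float
    per_draw_rr: list[tuple[float, float, float]]
    median_rr: float
    combined_rr: float
    ci_low: float
    ci_high: float

    def to_row(self) -> dict:
        return {
            "pathway": self.pathway,
            "n_cpgs": self.n_cpgs,
            "window": self.window,
            "universe": self.universe,
            "p_basis": self.p_basis,
            "proportion": self.pathway_proportion,
            "combined_RR": round(self.combined_rr, 2),
            "median_RR": round(self.median_rr, 2),
            "CI_low": round(self.ci_low, 2),
            "CI_high": round(self.ci_high, 2),
            "median_subset_proportion": self.median_subset_proportion,
        }


def combine_over_draws(
    pathway: str,
    window: str,
    universe: str,
    p_basis: str,
    pathway_proportion: float,
    n_cpgs: int,
    subset_proportions,
    per_draw_rr,
) -> EnrichmentResult:
    """Median combination over the random draws.

    Three summaries are retained: the combined RR (pathway proportion
    over median subset proportion), the median of the per-draw RRs, and
    the medians of the per-draw CI bounds.
    """
    subset_proportions = [float(p) for p in subset_proportions]
    med_prop = float(np.median(subset_proportions))
    rrs = [r[0] for r in per_draw_rr]
    los = [r[1] for r in per_draw_rr]
    his = [r[2] for r in per_draw_rr]
    combined = pathway_proportion / med_prop if med_prop > 0 else np.nan

    def _med(vals):
        vals = np.asarray(vals, dtype=float)
        return float(np.median(vals[~np.isnan(vals)])) if (~np.isnan(vals)).any() \
            else float("nan")

    return EnrichmentResult(
        pathway=pathway, window=window, universe=universe, p_basis=p_basis,
        n_cpgs=n_cpgs,
        pathway_proportion=pathway_proportion,
        subset_proportions=subset_proportions,
        median_subset_proportion=med_prop,
        per_draw_rr=[tuple(map(float, r)) for r in per_draw_rr],
        median_rr=_med(rrs),
        combined_rr=float(combined),
        ci_low=_med(los),
        ci_high=_med(his),
    )


def enrich_pathway(
    results: pd.DataFrame,
    pathway: str,
    pathway_probes,
    draws: list[SubsetDraw],
    window: str,
    p_basis: str = "raw",
    alpha: float = 0.05,
    fdr_per_family: bool = True,
) -> EnrichmentResult:
    """Full enrichment of one pathway against a set of subset draws.

    With ``p_basis='fdr'`` and ``fdr_per_family`` (default), the BH
    adjustment is recomputed within the pathway family and within each
    draw family, mirroring the per-table structure of the raw analysis.
    """
    from .paired import adjust_fdr

    col = {"raw": "p_value", "fdr": "q_value"}[p_basis]

    def flags(probes):
        if p_basis == "fdr" and fdr_per_family:
            fam = adjust_fdr(results, scope=probes, alpha=alpha)
            sub = fam.set_index("probe_id").reindex(list(probes))
        else:
            sub = results.set_index("probe_id").reindex(list(probes))
        if sub[col].isna().any():
            raise KeyError(f"probes without results in {pathway}/{window}")
        return (sub[col] <= alpha).to_numpy()

    pflags = flags(list(pathway_probes))
    p_prop = round(100.0 * pflags.mean(), 1)
    subset_props, per_draw = [], []
    for d in draws:
        sflags = flags(list(d.probe_ids))
        subset_props.append(round(100.0 * sflags.mean(), 1))
        try:
            per_draw.append(loglinear_rr(pflags, sflags))
        except ValueError:
            # degenerate draw (no significance anywhere, or everywhere)
            log.warning("RR undefined for %s/%s draw %d", pathway, window,
                        d.draw_index)
            per_draw.append((np.nan, np.nan, np.nan))
    return combine_over_draws(
        pathway, window, d.universe, p_basis, p_prop, len(pflags),
        subset_props, per_draw,
    )


def chi_square_proportions(k1: int, n1: int, k2: int, n2: int):
    """Pearson chi-square on the 2x2, no continuity correction."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # degenerate margin: proportions are trivially equal or undefined
        return 0.0, 1.0
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 1).any():
        log.warning("chi-square with expected cell < 1")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
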