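"""End-to-end orchestration of the two-step analysis.

Stages: simulate (or load) -> probe filtering -> quantile normalization
-> M transform -> batch correction -> per-timepoint surrogate-variable
residualization -> cell-proportion estimation -> paired tests per
pregnancy window -> FDR -> resampling enrichment (two universes, raw
and FDR bases) -> gene-region composition -> neighbor clustering.
All randomness flows from a single seed; outputs are plain text and
byte-identical across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .combat import combat_adjust
from .core import MethMatrix, TIMEPOINTS
from .deconvolve import (
    compute_surrogate_variables,
    estimate_cell_proportions,
    residualize,
)
from .enrichment import (
    N_DRAWS_DEFAULT,
    chi_square_proportions,
    draw_subsets,
    enrich_pathway,
)
from .paired import adjust_fdr, run_all_probes
from .preprocess import filter_probes, matrix_to_m, peak_correction, quantile_normalize
from .regions import cluster_significant, region_composition
from .simulate import SyntheticConfig, generate_cohort, generate_manifest, write_cohort

log = logging.getLogger(__name__)

WINDOWS = ("first", "second")
UNIVERSES = ("whole_genome", "cd4")
P_BASES = ("raw", "fdr")


@dataclass
class RunConfig:
    """Pipeline settings; either simulate or point at input files."""

    simulate: SyntheticConfig | None = None
    manifest_path: str | None = None
    beta_path: str | None = None
    sample_sheet_path: str | None = None
    reference_path: str | None = None
    n_svs: int = 15
    alpha: float = 0.05
    n_draws: int = N_DRAWS_DEFAULT
    seed: int = 0
    out_dir: str = "results"
    write_inputs: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 and self.alpha != 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.simulate is None and not all(
            [self.manifest_path, self.beta_path, self.sample_sheet_path,
             self.reference_path]
        ):
            raise ValueError("either a simulate block or all input paths required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        raw.update(overrides)
        if sim is not None:
            raw["simulate"] = SyntheticConfig(**sim)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # where outputs land is not science
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    from .simulate import read_manifest, read_matrix

    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim = SyntheticConfig(**{**asdict_config(sim), "seed": config.seed})
        manifest = generate_manifest(sim)
        matrix, sheet, reference, truth = generate_cohort(sim, manifest)
        return manifest, matrix, sheet, reference, truth
    manifest = read_manifest(config.manifest_path)
    matrix = read_matrix(config.beta_path, scale="beta")
    sheet = pd.read_csv(config.sample_sheet_path)
    reference = pd.read_csv(config.reference_path, index_col=0)
    return manifest, matrix, sheet, reference, None


def asdict_config(cfg) -> dict:
    d = asdict(cfg)
    return d


def deconvolve_by_timepoint(m_matrix: MethMatrix, sheet: pd.DataFrame, n_svs: int):
    """SVA + residualization separately per timepoint dataset."""
    residuals, svsets = {}, {}
    for tp in TIMEPOINTS:
        samples = sheet.loc[sheet["timepoint"] == tp, "sample_id"].to_numpy()
        if len(samples) == 0:
            continue
        sub = m_matrix.subset_samples(samples)
        k = min(n_svs, sub.n_samples - 1)
        if k < n_svs:
            log.warning("timepoint %s: truncating SVs to %d (n=%d)",
                        tp, k, sub.n_samples)
        svs = compute_surrogate_variables(sub, k=k)
        residuals[tp] = residualize(sub, svs)
        svsets[tp] = svs
    return residuals, svsets


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the artifact bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, matrix, sheet, reference, truth = _load_inputs(config)
    if config.simulate is not None and config.write_inputs:
        write_cohort(out / "sim", manifest, matrix, sheet, reference, truth)

    filtered, report = filter_probes(matrix, manifest)
    report.to_json(out / "filter_report.json")
    log.info("filtering: %d -> %d probes", report.n_input, report.n_output)

    filtered = peak_correction(filtered)
    normalized = quantile_normalize(filtered)

    proportions = estimate_cell_proportions(normalized, reference)
    proportions.rename_axis("sample_id").to_csv(out / "cell_proportions.tsv", sep="\t")

    m_all = matrix_to_m(normalized)
    tp_design = pd.get_dummies(
        sheet.set_index("sample_id").loc[m_all.sample_ids, "timepoint"]
    ).to_numpy(float)[:, 1:]
    m_adj = combat_adjust(m_all, sheet, covariates_to_preserve=tp_design)

    residuals, svsets = deconvolve_by_timepoint(m_adj, sheet, config.n_svs)
    svs_out = []
    for tp, svset in svsets.items():
        frame = svset.to_frame()
        frame.insert(0, "timepoint", tp)
        svs_out.append(frame.rename_axis("sample_id").reset_index())
    pd.concat(svs_out).to_csv(out / "svs.tsv", sep="\t", index=False)

    man_idx = manifest.set_index("probe_id")
    surviving = pd.Index(m_adj.probe_ids)
    pathway_probes = {
        pw: [p for p in surviving if man_idx.at[p, "pathway"] == pw]
        for pw in ("Th1", "Th2", "Th17", "Treg")
    }
    all_pathway = [p for probes in pathway_probes.values() for p in probes]
    gene_of = man_idx["genes"]

    results = {}
    for window, tp in (("first", "preg_first"), ("second", "preg_second")):
        if tp not in residuals:
            continue
        res = run_all_probes(
            residuals["age18"], residuals[tp], proportions, sheet, window,
            alpha=config.alpha,
        )
        res = adjust_fdr(res, alpha=config.alpha)  # genome-wide q, per-family below
        res["gene"] = res["probe_id"].map(gene_of).fillna("")
        res["pathway"] = res["probe_id"].map(man_idx["pathway"]).fillna("")
        results[window] = res
        res.to_csv(out / f"change_results_{window}.tsv", sep="\t", index=False)

    # enrichment: both universes, both p bases
    universe_probes = {
        "whole_genome": list(surviving),
        "cd4": [p for p in surviving if man_idx.at[p, "cd4_gene"]],
    }
    size = len(all_pathway)
    rows = []
    run_info_draws = {}
    for uni in UNIVERSES:
        draws = draw_subsets(
            universe_probes[uni], excluded=all_pathway, size=size,
            n_draws=config.n_draws, seed=config.seed, universe_name=uni,
        )
        run_info_draws[uni] = {
            "universe_size": len(universe_probes[uni]),
            "eligible": len(set(universe_probes[uni]) - set(all_pathway)),
            "seeds": [d.seed for d in draws],
        }
        for window, res in results.items():
            for basis in P_BASES:
                for pw, probes in pathway_probes.items():
                    if not probes:
                        continue
                    enr = enrich_pathway(
                        res, pw, probes, draws, window, p_basis=basis,
                        alpha=config.alpha,
                    )
                    rows.append(enr.to_row())
    enrichment = pd.DataFrame(rows)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # region composition: pathway CpGs vs the two reference universes
    comps = []
    for name, probes in [
        ("pathway", all_pathway),
        ("whole_genome_universe", universe_probes["whole_genome"][:5000]),
        ("cd4_universe", universe_probes["cd4"][:5000]),
    ]:
        if not probes:
            continue
        comp = region_composition(probes, manifest)
        comp.insert(0, "probe_set", name)
        comps.append(comp)
    pd.concat(comps).to_csv(out / "region_table.tsv", sep="\t", index=False)

    # neighbor clustering of significant pathway CpGs
    cluster_frames = []
    for window, res in results.items():
        rep = cluster_significant(
            res[res["pathway"] != ""].reset_index(drop=True), manifest
        )
        rep.insert(0, "window", window)
        cluster_frames.append(rep)
    clusters = pd.concat(cluster_frames) if cluster_frames else pd.DataFrame()
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)

    run_manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "alpha": config.alpha,
        "n_svs": config.n_svs,
        "n_draws": config.n_draws,
        "filter": json.loads((out / "filter_report.json").read_text()),
        "n_pathway_probes": {pw: len(p) for pw, p in pathway_probes.items()},
        "draws": run_info_draws,
        "windows": {
            w: {
                "n_probes": int(len(r)),
                "n_significant_raw": int(r["significant_raw"].sum()),
            } for w, r in results.items()
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2) + "\n")

    return {
        "manifest": manifest,
        "sheet": sheet,
        "proportions": proportions,
        "residuals": residuals,
        "results": results,
        "enrichment": enrichment,
        "pathway_probes": pathway_probes,
        "universe_probes": universe_probes,
        "truth": truth,
        "run_manifest": run_manifest,
    }


def subgroup_sensitivity(
    bundle: dict, sheet: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Compare significance rates in the all-three-timepoints subgroup.

    Reruns the paired tests restricted to subjects sampled at baseline
    and in both pregnancy windows, then contrasts the proportion of
    significant pathway CpGs against the full per-window groups with a
    chi-square test.
    """
    by_subject = sheet.groupby("subject_id")["timepoint"].apply(set)
    complete = sorted(by_subject[by_subject.apply(lambda s: len(s) == 3)].index)
    if len(complete) < 8:
        raise ValueError(f"only {len(complete)} subjects with all three timepoints")
    sub_sheet = sheet[sheet["subject_id"].isin(complete)]
    residuals = bundle["residuals"]
    proportions = bundle["proportions"]
    pathway_ids = [p for ps in bundle["pathway_probes"].values() for p in ps]
    rows = []
    for window, tp in (("first", "preg_first"), ("second", "preg_second")):
        if tp not in residuals:
            continue
        sub_res = run_all_probes(
            residuals["age18"], residuals[tp], proportions, sub_sheet, window,
            alpha=alpha,
        )
        full = bundle["results"][window]
        k_sub = int(sub_res[sub_res["probe_id"].isin(pathway_ids)]
                    ["significant_raw"].sum())
        k_full = int(full[full["probe_id"].isin(pathway_ids)]
                     ["significant_raw"].sum())
        n = len(pathway_ids)
        stat, p = chi_square_proportions(k_sub, n, k_full, n)
        rows.append({
            "window": window,
            "n_subgroup_subjects": len(complete),
            "significant_subgroup": k_sub,
            "significant_full": k_full,
            "n_cpgs": n,
            "proportion_subgroup": round(100.0 * k_sub / n, 1),
            "proportion_full": round(100.0 * k_full / n, 1),
            "chi_square": round(stat, 4),
            "p_value": p,
        })
    return pd.DataFrame(rows)
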