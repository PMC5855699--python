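"""Synthetic cohort generator.

Emulates the study layout the pipeline was designed for: 245 women with
a baseline (age 18) blood draw, of whom 39 have a first-half and 35 a
second-half pregnancy sample (20 have all three); methylation measured
on an array-like probe set across 7 processing batches; whole blood a
mixture of 7 leukocyte subtypes with cell-type-specific methylation
signatures; latent technical/biological factors; and true pregnancy
effects injected additively on the M scale at pathway-specific rates.

Every quantity drawn is recorded in a ground-truth table so recovery
can be tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CELL_TYPES, MethMatrix
from .preprocess import BETA_CLIP, beta_to_m, m_to_beta

#: pathway gene panels (T-helper / regulatory T-cell cytokines,
#: receptors and transcription factors)
PATHWAY_GENES = {
    "Th1": [
        "IFNG", "IFNGR1", "IFNGR2", "IL12A", "IL12B", "IL12RB1", "IL12RB2",
        "IL2", "IL2RA", "IL2RB", "TNF", "TNFAIP1", "TNFAIP2", "TNFAIP3",
        "TNFAIP6", "TNFAIP8", "TNFAIP8L",
    ],
    "Th2": [
        "GATA3", "IL13", "IL13RA1", "IL13RA2", "IL1RL1", "IL4", "IL4R",
        "IL5", "IL5RA", "IL9", "JAK1", "JAK3", "STAT6",
    ],
    "Th17": [
        "IL17A", "IL17B", "IL17C", "IL17D", "IL17F", "IL17RA", "IL17RC",
        "IL17RD", "IL17RE", "IL17REL", "IL21", "IL21R", "IL22", "IL22RA1",
        "IL22RA2",
    ],
    "Treg": ["FOXP3", "CTLA4"],
}

_REGION_CHOICES = (
    ("Body", 0.42), ("TSS200", 0.16), ("TSS1500", 0.16),
    ("5UTR", 0.08), ("3UTR", 0.05), ("1stExon", 0.05),
    ("Body;TSS1500", 0.04), ("Body;5UTR", 0.04),
)

#: mean whole-blood composition (B, CD4T, CD8T, Eos, Gran, Mono, NK)
_BLOOD_MEAN = np.array([0.05, 0.15, 0.08, 0.04, 0.55, 0.08, 0.05])
#: shift applied during pregnancy (mild neutrophilia, relative
#: lymphopenia), renormalized
_PREG_SHIFT = np.array([-0.01, -0.03, -0.01, 0.0, 0.06, -0.005, -0.005])
_DIRICHLET_CONC = 60.0


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_baseline: int = 245
    n_first: int = 39
    n_second: int = 35
    n_all_three: int = 20
    n_background_cpgs: int = 20_000
    pathway_sizes: dict = field(
        default_factory=lambda: {"Th1": 155, "Th2": 77, "Th17": 106, "Treg": 10}
    )
    n_celltypes: int = 7
    n_batches: int = 7
    #: per-pathway probability a CpG carries a true pregnancy effect;
    #: calibrated so observed significance rates land near the 28-36%
    #: band the pipeline is meant to reproduce
    p_effect_pathway: dict = field(
        default_factory=lambda: {"Th1": 0.30, "Th2": 0.38, "Th17": 0.34, "Treg": 0.34}
    )
    p_effect_background: float = 0.21
    effect_size_m: float = 0.5
    noise_sd_m: float = 0.5
    subject_sd_m: float = 0.8
    n_latent: int = 5
    latent_loading_sd: float = 0.4
    latent_probe_frac: float = 0.3
    batch_loc_sd: float = 0.3
    batch_scale_sd: float = 0.1
    snp_probe_frac: float = 0.37
    sexchrom_probe_frac: float = 0.04
    intergenic_frac: float = 0.22
    cd4_gene_frac: float = 0.25
    n_signature_probes: int = 420
    signature_offset_m: float = 3.0
    cell_offset_sd_m: float = 0.3
    probes_per_gene: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_baseline, self.n_first, self.n_second, self.n_all_three) <= 0:
            raise ValueError("all cohort counts must be positive")
        if self.n_all_three > min(self.n_first, self.n_second):
            raise ValueError("n_all_three cannot exceed min(n_first, n_second)")
        if self.n_first + self.n_second - self.n_all_three > self.n_baseline:
            raise ValueError("pregnant subjects exceed the baseline cohort")
        for name, p in [("p_effect_background", self.p_effect_background),
                        *self.p_effect_pathway.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if not 0 <= self.snp_probe_frac <= 1 or not 0 <= self.sexchrom_probe_frac <= 1:
            raise ValueError("probe filter fractions must be in [0, 1]")
        for pw, size in self.pathway_sizes.items():
            if size > self.probes_per_gene * len(PATHWAY_GENES[pw]) * 10:
                raise ValueError(f"pathway {pw} size {size} exceeds gene capacity")

    @property
    def total_pathway_cpgs(self) -> int:
        return sum(self.pathway_sizes.values())


def generate_manifest(config: SyntheticConfig) -> pd.DataFrame:
    """Probe manifest: pathway probes, signature probes, background.

    Pathway probes are autosomal, unflagged, and gene-annotated, so all
    of them survive filtering. Background probes carry the SNP and
    sex-chromosome flags, an intergenic fraction, and a CD4-expressed
    gene flag defining the second reference universe. Positions are
    strictly increasing within each chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows: list[dict] = []

    region_labels = [r for r, _ in _REGION_CHOICES]
    region_probs = np.array([p for _, p in _REGION_CHOICES])
    region_probs = region_probs / region_probs.sum()

    # pathway probes: spread over the pathway's gene panel
    for pw, size in config.pathway_sizes.items():
        genes = PATHWAY_GENES[pw]
        for i in range(size):
            gene = genes[i % len(genes)]
            rows.append({
                "probe_id": f"cgP{pw}{i:05d}",
                "chrom": str(1 + (hash_stable(gene) % 22)),
                "pos": 0,  # assigned after chromosome grouping
                "genes": gene,
                "region_groups": region_labels[
                    rng.choice(len(region_labels), p=region_probs)
                ],
                "snp_maf_gt_1pct": False,
                "pathway": pw,
                "cd4_gene": True,
                "signature_cell": "",
            })

    # deconvolution signature probes: autosomal, unflagged, genic
    per_cell = config.n_signature_probes // config.n_celltypes
    for c, cell in enumerate(CELL_TYPES[: config.n_celltypes]):
        for i in range(per_cell):
            rows.append({
                "probe_id": f"cgS{cell}{i:04d}",
                "chrom": str(1 + ((c * per_cell + i) % 22)),
                "pos": 0,
                "genes": f"SIG{cell}{i // 8:03d}",
                "region_groups": "Body",
                "snp_maf_gt_1pct": False,
                "pathway": "",
                "cd4_gene": False,
                "signature_cell": cell,
            })

    # background probes
    n_bg = config.n_background_cpgs
    on_sex = rng.random(n_bg) < config.sexchrom_probe_frac
    snp_flag = rng.random(n_bg) < config.snp_probe_frac
    intergenic = rng.random(n_bg) < config.intergenic_frac
    n_genes = max(1, n_bg // config.probes_per_gene)
    gene_idx = rng.integers(0, n_genes, size=n_bg)
    cd4_genes = set(
        rng.choice(n_genes, size=int(round(config.cd4_gene_frac * n_genes)),
                   replace=False)
    )
    sex_choice = rng.random(n_bg) < 0.5
    auto_chrom = rng.integers(1, 23, size=n_bg)
    region_idx = rng.choice(len(region_labels), size=n_bg, p=region_probs)
    for i in range(n_bg):
        chrom = ("X" if sex_choice[i] else "Y") if on_sex[i] else str(auto_chrom[i])
        rows.append({
            "probe_id": f"cg1{i:07d}",
            "chrom": chrom,
            "pos": 0,
            "genes": "" if intergenic[i] else f"GENE{gene_idx[i]:06d}",
            "region_groups": "" if intergenic[i] else region_labels[region_idx[i]],
            "snp_maf_gt_1pct": bool(snp_flag[i]),
            "pathway": "",
            "cd4_gene": bool((not intergenic[i]) and gene_idx[i] in cd4_genes),
            "signature_cell": "",
        })

    manifest = pd.DataFrame(rows)
    # strictly increasing positions within each chromosome
    pos = np.zeros(len(manifest), dtype=int)
    for _, idx in manifest.groupby("chrom").groups.items():
        idx = np.asarray(idx)
        gaps = rng.integers(50, 2000, size=len(idx))
        pos[idx] = 1 + np.cumsum(gaps)
    manifest["pos"] = pos
    return manifest.reset_index(drop=True)


def hash_stable(text: str) -> int:
    """Deterministic small hash (process-independent, unlike hash())."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def _build_sample_sheet(config: SyntheticConfig, rng) -> pd.DataFrame:
    subjects = [f"S{i:03d}" for i in range(config.n_baseline)]
    # subjects 0..n_all_three-1 appear at all three timepoints
    first = subjects[: config.n_first]
    second = (
        subjects[: config.n_all_three]
        + subjects[config.n_first: config.n_first + config.n_second - config.n_all_three]
    )
    # samples are randomized across processing batches (plate
    # randomization); confounding batch with timepoint would make the
    # downstream batch correction itself distort the time contrast
    rows = []
    b = config.n_batches
    for s in subjects:
        rows.append({"sample_id": f"{s}_age18", "subject_id": s,
                     "timepoint": "age18", "batch": int(rng.integers(b))})
    for s in first:
        rows.append({"sample_id": f"{s}_preg1", "subject_id": s,
                     "timepoint": "preg_first", "batch": int(rng.integers(b))})
    for s in second:
        rows.append({"sample_id": f"{s}_preg2", "subject_id": s,
                     "timepoint": "preg_second", "batch": int(rng.integers(b))})
    return pd.DataFrame(rows)


def generate_cohort(config: SyntheticConfig, manifest: pd.DataFrame):
    """Generate (MethMatrix, sample sheet, cell reference, ground truth).

    Each sample's beta vector is a cell-proportion-weighted mixture of
    cell-type beta profiles; batch location/scale shifts, latent-factor
    contributions, true pregnancy effects, and noise are added on the M
    scale and mapped back through the inverse logit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sheet = _build_sample_sheet(config, rng)
    probe_ids = manifest["probe_id"].to_numpy(object)
    n_probes = len(probe_ids)
    n_samples = len(sheet)
    n_cells = config.n_celltypes

    # per-probe per-cell-type M profiles (bimodal baseline)
    low = rng.random(n_probes) < 0.5
    m0 = np.where(low, rng.normal(-3.0, 1.0, n_probes), rng.normal(3.0, 1.0, n_probes))
    cell_off = rng.normal(0.0, config.cell_offset_sd_m, size=(n_probes, n_cells))
    sig_cell = manifest["signature_cell"].to_numpy(object)
    for c, cell in enumerate(CELL_TYPES[:n_cells]):
        mask = sig_cell == cell
        signs = rng.choice([-1.0, 1.0], size=int(mask.sum()))
        cell_off[mask] = 0.0
        cell_off[mask, c] = signs * config.signature_offset_m
    m_cell = m0[:, None] + cell_off
    beta_cell = m_to_beta(m_cell)

    # true cell proportions per sample
    is_preg = sheet["timepoint"].ne("age18").to_numpy()
    props = np.empty((n_samples, n_cells))
    base_mean = _BLOOD_MEAN[:n_cells] / _BLOOD_MEAN[:n_cells].sum()
    preg_mean = base_mean + _PREG_SHIFT[:n_cells]
    preg_mean = np.clip(preg_mean, 0.01, None)
    preg_mean = preg_mean / preg_mean.sum()
    for i in range(n_samples):
        mean = preg_mean if is_preg[i] else base_mean
        props[i] = rng.dirichlet(mean * _DIRICHLET_CONC)

    beta_mix = beta_cell @ props.T  # probes x samples
    m = beta_to_m(np.clip(beta_mix, BETA_CLIP, 1 - BETA_CLIP))

    # subject-level random intercepts (stable methylation set point)
    subjects = sheet["subject_id"].unique()
    subj_index = {s: i for i, s in enumerate(subjects)}
    u = rng.normal(0.0, config.subject_sd_m, size=(n_probes, len(subjects)))
    cols = sheet["subject_id"].map(subj_index).to_numpy()
    m = m + u[:, cols]

    # latent factors on a random subset of probes
    factors = rng.normal(size=(config.n_latent, n_samples))
    affected = rng.random(n_probes) < config.latent_probe_frac
    loadings = np.zeros((n_probes, config.n_latent))
    loadings[affected] = rng.normal(
        0.0, config.latent_loading_sd, size=(int(affected.sum()), config.n_latent)
    )
    m = m + loadings @ factors

    # batch location and scale
    batch = sheet["batch"].to_numpy()
    batch_mu = rng.normal(0.0, config.batch_loc_sd, size=config.n_batches)
    batch_gamma = rng.normal(
        batch_mu[None, :], 0.1, size=(n_probes, config.n_batches)
    )
    batch_delta = np.exp(rng.normal(0.0, config.batch_scale_sd, size=config.n_batches))
    m = m + batch_gamma[:, batch]

    # true pregnancy effects
    pathway = manifest["pathway"].to_numpy(object)
    p_eff = np.full(n_probes, config.p_effect_background)
    for pw, p in config.p_effect_pathway.items():
        p_eff[pathway == pw] = p
    has_effect = rng.random(n_probes) < p_eff
    signs = rng.choice([-1.0, 1.0], size=n_probes)
    mag1 = config.effect_size_m * rng.uniform(0.75, 1.25, size=n_probes)
    mag2 = mag1 * rng.uniform(0.8, 1.2, size=n_probes)
    eff_first = np.where(has_effect, signs * mag1, 0.0)
    eff_second = np.where(has_effect, signs * mag2, 0.0)
    tp = sheet["timepoint"].to_numpy(object)
    m = m + np.outer(eff_first, tp == "preg_first")
    m = m + np.outer(eff_second, tp == "preg_second")

    # residual noise, scaled by batch
    noise = rng.normal(0.0, config.noise_sd_m, size=(n_probes, n_samples))
    m = m + noise * batch_delta[batch][None, :]

    beta = np.clip(m_to_beta(m), BETA_CLIP, 1 - BETA_CLIP)
    matrix = MethMatrix(beta, probe_ids, sheet["sample_id"].to_numpy(object), "beta")

    # measured cell reference: true signatures plus small assay noise
    sig_mask = sig_cell != ""
    ref_beta = np.clip(
        beta_cell[sig_mask] + rng.normal(0.0, 0.01, size=(int(sig_mask.sum()), n_cells)),
        BETA_CLIP, 1 - BETA_CLIP,
    )
    reference = pd.DataFrame(
        ref_beta, index=probe_ids[sig_mask], columns=list(CELL_TYPES[:n_cells])
    )

    truth_probes = pd.DataFrame({
        "probe_id": probe_ids,
        "true_effect_first": eff_first,
        "true_effect_second": eff_second,
        "is_true_positive_first": eff_first != 0.0,
        "is_true_positive_second": eff_second != 0.0,
    })
    truth_samples = pd.DataFrame(
        props, index=sheet["sample_id"], columns=list(CELL_TYPES[:n_cells])
    )
    truth_samples["batch"] = batch
    for f in range(config.n_latent):
        truth_samples[f"latent{f+1}"] = factors[f]
    truth = {"probes": truth_probes, "samples": truth_samples.reset_index()}
    return matrix, sheet, reference, truth


def paired_power(delta: float, noise_sd: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided paired-t power for a within-pair shift ``delta``.

    Each measurement carries independent noise of SD ``noise_sd``, so the
    paired difference has SD sqrt(2)*noise_sd; df = n - 1.
    """
    from scipy import stats

    sd_d = np.sqrt(2.0) * noise_sd
    ncp = delta / (sd_d / np.sqrt(n))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return float(stats.nct.sf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit, n - 1, ncp))


def effect_prob_for_rate(
    target_rate: float, delta: float, noise_sd: float, n: int, alpha: float = 0.05
) -> float:
    """Effect probability that yields a target rejection rate.

    Solves target = p * power + (1 - p) * alpha for p, so a mixture of
    true effects (detected with the paired-t power) and nulls (rejected
    at alpha) produces the requested overall significance rate.
    """
    power = paired_power(delta, noise_sd, n, alpha)
    p = (target_rate - alpha) / (power - alpha)
    if not 0.0 <= p <= 1.0:
        raise ValueError(
            f"target rate {target_rate} unreachable with power {power:.3f}"
        )
    return p


# ---------------------------------------------------------------------------
# plain-text readers/writers for every artifact

_ILLUMINA_COLS = {
    "probe_id": "IlmnID", "chrom": "CHR", "pos": "MAPINFO",
    "genes": "UCSC_RefGene_Name", "region_groups": "UCSC_RefGene_Group",
    "snp_maf_gt_1pct": "SNP_MAF_GT_1PCT",
}


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.rename(columns=_ILLUMINA_COLS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"CHR": str})
    df = df.rename(columns={v: k for k, v in _ILLUMINA_COLS.items()})
    df["snp_maf_gt_1pct"] = df["snp_maf_gt_1pct"].astype(bool)
    if "cd4_gene" in df:
        df["cd4_gene"] = df["cd4_gene"].astype(bool)
    for col in ("pathway", "cd4_gene", "signature_cell"):
        if col not in df:
            df[col] = "" if col != "cd4_gene" else False
    return df


def write_matrix(matrix: MethMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path, scale: str) -> MethMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return MethMatrix.from_frame(frame, scale)


def write_pathways(manifest: pd.DataFrame, path) -> None:
    """Gene -> pathway map derived from the manifest annotation."""
    sub = manifest[manifest["pathway"] != ""][["genes", "pathway"]].drop_duplicates()
    sub = sub.rename(columns={"genes": "gene"}).sort_values(["pathway", "gene"])
    sub.to_csv(path, sep="\t", index=False)


def write_cd4_universe(manifest: pd.DataFrame, path) -> None:
    genes = sorted(
        set(manifest.loc[manifest["cd4_gene"] & (manifest["genes"] != ""), "genes"])
    )
    Path(path).write_text("\n".join(genes) + "\n")


def write_cohort(outdir, manifest, matrix, sheet, reference, truth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_manifest(manifest, outdir / "manifest.csv")
    write_matrix(matrix, outdir / "beta.tsv")
    sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    reference.to_csv(outdir / "cell_reference.csv")
    write_pathways(manifest, outdir / "pathways.tsv")
    write_cd4_universe(manifest, outdir / "cd4_universe.txt")
    truth["probes"].to_csv(outdir / "ground_truth_probes.tsv", sep="\t", index=False)
    truth["samples"].to_csv(outdir / "ground_truth_samples.tsv", sep="\t", index=False)
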