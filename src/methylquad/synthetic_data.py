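"""Synthetic inputs with planted, known structure for every pipeline stage.

The generator emulates the shape of a two-platform blood-leukocyte study:
a small two-group expression matrix (13 cases vs 11 controls by default),
an 8-vs-8 CpG beta-value matrix on a 450K-style manifest annotated to the
six intragenic region classes, a toy cytoband table with pericentromeric
p11.1/q11.1 bands, a STRING-style scored edge list with a planted dense
module, GMT gene sets, and restriction-enzyme qPCR Cq tables.

Differential signal is planted in all four direction combinations
(up-hyper, up-hypo, down-hyper, down-hypo): case expression is shifted by
a signed log2 fold change on planted genes, and case betas by a signed
additive delta-beta on the CpGs of the planted genes' affected regions.
Control betas are drawn logit-normally around per-probe baselines so the
planted shift is additive on the beta scale. Everything is deterministic
under a fixed seed (numpy PCG64 generators keyed off ``seed``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import (
    REGION_CLASSES,
    CytobandTable,
    GeneSetCollection,
    Manifest,
    OmicsMatrix,
    write_gmt,
    write_manifest,
    write_omics_matrix,
)

QUADRANT_DIRECTIONS = (
    ("up", "hyper"),
    ("up", "hypo"),
    ("down", "hyper"),
    ("down", "hypo"),
)


@dataclass(frozen=True)
class PlantedGene:
    """A gene with planted differential signal in both data layers."""

    gene: str
    deg_direction: str  # "up" | "down"
    dmg_direction: str  # "hyper" | "hypo"
    regions: tuple[str, ...]
    delta_beta: float
    log2fc: float

    @property
    def quadrant(self) -> str:
        return f"{self.deg_direction}-{self.dmg_direction}"


@dataclass
class SimulationConfig:
    """All knobs of the generator. Defaults mirror the emulated study
    scale: 13 vs 11 expression samples, 8 vs 8 methylation samples,
    ~1000 genes on 22 autosomes."""

    seed: int = 0
    n_genes: int = 1000
    cpgs_per_region: dict = field(
        default_factory=lambda: {r: (1, 3) for r in REGION_CLASSES}
    )
    n_case_expr: int = 13
    n_control_expr: int = 11
    n_case_meth: int = 8
    n_control_meth: int = 8
    expr_log2_mean: float = 8.0
    expr_log2_sd: float = 1.0
    expr_noise_sd: float = 0.5
    beta_logit_sd: float = 0.3
    # planted signal
    n_per_quadrant: int = 10
    delta_beta: float = 0.2
    log2fc: float = 1.0
    planted_regions: tuple = ("TSS200", "5UTR")
    planted: list[PlantedGene] | None = None
    # genome layout
    n_chromosomes: int = 22
    n_intergenic_probes: int = 50
    centromere_fraction: float = 0.02
    # PPI
    ppi_module_size: int = 6
    ppi_background_p: float = 0.05
    # qPCR
    cq_noise_sd: float = 0.05
    cq_baseline: float = 24.0
    max_cycle: float = 40.0

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def planted_genes(self) -> list[PlantedGene]:
        """The configured planted set, or the default: the first
        4 * n_per_quadrant genes, one block per quadrant."""
        if self.planted is not None:
            planted = list(self.planted)
        else:
            names = self.gene_names()
            needed = 4 * self.n_per_quadrant
            if needed > self.n_genes:
                raise ValueError("more planted genes than genes")
            planted = []
            for qi, (deg, dmg) in enumerate(QUADRANT_DIRECTIONS):
                block = names[qi * self.n_per_quadrant : (qi + 1) * self.n_per_quadrant]
                planted.extend(
                    PlantedGene(g, deg, dmg, tuple(self.planted_regions),
                                self.delta_beta, self.log2fc)
                    for g in block
                )
        seen = [p.gene for p in planted]
        if len(set(seen)) != len(seen):
            raise ValueError("planted gene sets must be disjoint across quadrants")
        for p in planted:
            if not 0 < p.delta_beta < 1:
                raise ValueError(f"delta_beta for {p.gene} must lie in (0,1)")
        return planted


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    quadrant: dict[str, str]  # gene -> quadrant label
    dmc_probes: frozenset[str]  # probes with a planted beta shift
    module_nodes: frozenset[str] = frozenset()

    def quadrant_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for q in self.quadrant.values():
            out[q] = out.get(q, 0) + 1
        return out


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def simulate_cytobands(config: SimulationConfig) -> CytobandTable:
    """Toy per-chromosome band table with p11.1/q11.1 centromere bands.

    Chromosome i has length (260 - 9i) Mb with a ~5 Mb pericentromeric
    block straddling 40% of the length; coordinates are 0-based
    half-open, deterministic (no randomness needed)."""
    rows = []
    for i in range(1, config.n_chromosomes + 1):
        length = int((260 - 9 * i) * 1e6)
        centro_mid = int(0.4 * length)
        half = int(2.5e6)
        rows += [
            (str(i), 0, centro_mid - half, "p21"),
            (str(i), centro_mid - half, centro_mid, "p11.1"),
            (str(i), centro_mid, centro_mid + half, "q11.1"),
            (str(i), centro_mid + half, length, "q21"),
        ]
    return CytobandTable(pd.DataFrame(rows, columns=["chromosome", "start", "end", "band"]))


def simulate_manifest(
    config: SimulationConfig, cytobands: CytobandTable | None = None
) -> Manifest:
    """Probe annotation: each gene gets CpGs in each region class.

    Probe counts per (gene, region) are drawn from the configured range.
    A ``centromere_fraction`` of probes is positioned inside the
    chromosome's p11.1/q11.1 bands, the rest outside them."""
    cytobands = cytobands if cytobands is not None else simulate_cytobands(config)
    rng = _rng(config, 1)
    bands = cytobands.bands
    layout = {}
    for chrom, grp in bands.groupby("chromosome"):
        cent = grp[grp["band"].isin(("p11.1", "q11.1"))]
        layout[chrom] = {
            "length": int(grp["end"].max()),
            "cent_lo": int(cent["start"].min()),
            "cent_hi": int(cent["end"].max()),
        }
    chroms = sorted(layout, key=int)

    def draw_position(chrom: str) -> int:
        info = layout[chrom]
        if rng.random() < config.centromere_fraction:
            pos0 = int(rng.integers(info["cent_lo"], info["cent_hi"]))
        else:  # outside the centromere block, either arm
            left = info["cent_lo"]
            right = info["length"] - info["cent_hi"]
            u = int(rng.integers(0, left + right))
            pos0 = u if u < left else info["cent_hi"] + (u - left)
        return pos0 + 1  # manifest positions are 1-based

    rows = []
    probe_no = 0
    for gi, gene in enumerate(config.gene_names()):
        chrom = chroms[gi % len(chroms)]
        for region in REGION_CLASSES:
            lo, hi = config.cpgs_per_region[region]
            for _ in range(int(rng.integers(lo, hi + 1))):
                probe_no += 1
                rows.append(
                    (f"cg{probe_no:08d}", chrom, draw_position(chrom), gene, region)
                )
    for _ in range(config.n_intergenic_probes):
        probe_no += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        rows.append((f"cg{probe_no:08d}", chrom, draw_position(chrom), "", "intergenic"))
    return Manifest(
        pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "gene", "region"])
    )


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------

def _sample_ids(prefix: str, n_case: int, n_control: int) -> tuple[list[str], pd.Series]:
    cases = [f"{prefix}_case_{i+1:02d}" for i in range(n_case)]
    controls = [f"{prefix}_ctrl_{i+1:02d}" for i in range(n_control)]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=cases + controls
    )
    return cases + controls, labels


def simulate_omics(
    config: SimulationConfig, manifest: Manifest
) -> tuple[OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Expression (gene level) and methylation (CpG level) matrices.

    Expression is log-normal: per-gene baseline ``N(mean, sd)`` on the
    log2 scale plus the signed planted log2FC in cases plus i.i.d. noise.
    Methylation baselines are uniform on (0.1, 0.9) (narrowed for planted
    probes so that baseline + delta stays inside (0, 1), else a config
    error); betas are logit-normal around the group mean."""
    planted = {p.gene: p for p in config.planted_genes()}
    genes = config.gene_names()
    missing = set(planted) - set(manifest.genes())
    if missing:
        raise ValueError(f"planted genes absent from manifest: {sorted(missing)}")

    # expression
    rng = _rng(config, 2)
    samples, labels = _sample_ids("expr", config.n_case_expr, config.n_control_expr)
    n_case = config.n_case_expr
    mu = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=len(genes))
    effect = np.array(
        [
            (planted[g].log2fc if planted[g].deg_direction == "up" else -planted[g].log2fc)
            if g in planted
            else 0.0
            for g in genes
        ]
    )
    log2_means = mu[:, None] + effect[:, None] * np.array(
        [1.0] * n_case + [0.0] * config.n_control_expr
    )
    noise = rng.normal(0.0, config.expr_noise_sd, size=log2_means.shape)
    expr = OmicsMatrix(
        pd.DataFrame(2.0 ** (log2_means + noise), index=pd.Index(genes, name="feature_id"),
                     columns=samples),
        labels,
        "expression",
    )

    # methylation
    rng = _rng(config, 3)
    msamples, mlabels = _sample_ids("meth", config.n_case_meth, config.n_control_meth)
    pairs = manifest.gene_region_pairs()
    probe_info = manifest.probe_positions()
    probes = probe_info["probe_id"].tolist()
    shift = pd.Series(0.0, index=pd.Index(probes))
    for _, row in pairs.iterrows():
        p = planted.get(row["gene"])
        if p is not None and row["region"] in p.regions:
            signed = p.delta_beta if p.dmg_direction == "hyper" else -p.delta_beta
            shift[row["probe_id"]] = signed
    baseline = pd.Series(rng.uniform(0.1, 0.9, size=len(probes)), index=shift.index)
    planted_mask = shift != 0
    # keep planted baselines clear of the boundaries
    pos = planted_mask & (shift > 0)
    neg = planted_mask & (shift < 0)
    baseline[pos] = rng.uniform(0.15, 0.95 - config.delta_beta, size=int(pos.sum()))
    baseline[neg] = rng.uniform(0.05 + config.delta_beta, 0.85, size=int(neg.sum()))
    case_mean = baseline + shift
    if ((case_mean <= 0) | (case_mean >= 1)).any():
        raise ValueError("planted delta_beta pushes a baseline outside (0, 1)")
    means = np.column_stack(
        [case_mean.to_numpy()] * config.n_case_meth
        + [baseline.to_numpy()] * config.n_control_meth
    )
    betas = expit(logit(means) + rng.normal(0.0, config.beta_logit_sd, size=means.shape))
    betas = np.clip(betas, 0.0, 1.0)
    meth = OmicsMatrix(
        pd.DataFrame(betas, index=pd.Index(probes, name="feature_id"), columns=msamples),
        mlabels,
        "methylation_beta",
    )

    truth = GroundTruth(
        quadrant={p.gene: p.quadrant for p in planted.values()},
        dmc_probes=frozenset(shift.index[planted_mask]),
    )
    return expr, meth, truth


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------

def simulate_ppi(
    config: SimulationConfig, genes: list[str]
) -> tuple[pd.DataFrame, frozenset[str]]:
    """STRING-style scored edge list over ``genes`` with a planted module.

    The first ``ppi_module_size`` genes form a clique with high scores;
    background pairs appear with probability ``ppi_background_p`` and
    scores spanning both sides of the usual 0.4 confidence cutoff."""
    if len(genes) < config.ppi_module_size + 2:
        raise ValueError("need more genes than the planted module size")
    rng = _rng(config, 4)
    module = list(genes[: config.ppi_module_size])
    rows = []
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            rows.append((a, b, float(rng.uniform(0.7, 0.99))))
    module_pairs = {frozenset((a, b)) for a, b, _ in rows}
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if frozenset((a, b)) in module_pairs:
                continue
            if rng.random() < config.ppi_background_p:
                rows.append((a, b, float(rng.uniform(0.15, 0.95))))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return edges, frozenset(module)


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

def simulate_cq(
    m_values,
    assay: str,
    config: SimulationConfig | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 2,
    sample_ids: list[str] | None = None,
    groups: list[str] | None = None,
    gene: str = "GENE",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cq quadruples consistent with the enzyme-digestion models.

    For each sample with true methylation fraction m the digested Cq is
    derived from the undigested one: ``Cq_dig = Cq_und - log2(1 - m)``
    under MDRE (methylation-dependent enzyme) and
    ``Cq_dig = Cq_und - log2(m)`` under MSRE, plus Gaussian Cq noise per
    replicate. Saturating cases (m = 1 under MDRE, m = 0 under MSRE) cap
    the digested Cq at the max cycle number. Replicates are duplicates
    by default, mirroring assays run twice."""
    config = config or SimulationConfig()
    if assay not in ("mdre", "msre"):
        raise ValueError("assay must be 'mdre' or 'msre'")
    noise_sd = config.cq_noise_sd if noise_sd is None else noise_sd
    rng = rng if rng is not None else _rng(config, 5)
    m_values = np.asarray(m_values, float)
    if ((m_values < 0) | (m_values > 1)).any():
        raise ValueError("true methylation fractions must lie in [0, 1]")
    n = len(m_values)
    sample_ids = sample_ids or [f"S{i+1:03d}" for i in range(n)]
    groups = groups or ["case"] * n
    rows = []
    for sid, grp, m in zip(sample_ids, groups, m_values):
        cq_und = config.cq_baseline
        if assay == "mdre":
            offset = math.inf if m >= 1.0 else -math.log2(1.0 - m)
        else:
            offset = math.inf if m <= 0.0 else -math.log2(m)
        cq_dig = min(cq_und + offset, config.max_cycle)
        for rep in range(1, n_replicates + 1):
            e_und = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            e_dig = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((sid, grp, gene, assay, "undigested", rep,
                         min(cq_und + e_und, config.max_cycle)))
            rows.append((sid, grp, gene, assay, "digested", rep,
                         min(cq_dig + e_dig, config.max_cycle)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "gene", "assay", "condition", "replicate", "cq"],
    )


def simulate_expression_cq(
    ratios,
    config: SimulationConfig | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 2,
    sample_ids: list[str] | None = None,
    groups: list[str] | None = None,
    gene: str = "GENE",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Target/reference Cq pairs consistent with 2^-dCq = ratio."""
    config = config or SimulationConfig()
    noise_sd = config.cq_noise_sd if noise_sd is None else noise_sd
    rng = rng if rng is not None else _rng(config, 6)
    ratios = np.asarray(ratios, float)
    if (ratios <= 0).any():
        raise ValueError("expression ratios must be positive")
    n = len(ratios)
    sample_ids = sample_ids or [f"S{i+1:03d}" for i in range(n)]
    groups = groups or ["case"] * n
    rows = []
    for sid, grp, ratio in zip(sample_ids, groups, ratios):
        cq_ref = config.cq_baseline - 4.0
        cq_tgt = cq_ref - math.log2(ratio)
        for rep in range(1, n_replicates + 1):
            e_t = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            e_r = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((sid, grp, gene, "expression", "target", rep, cq_tgt + e_t))
            rows.append((sid, grp, gene, "expression", "reference", rep, cq_ref + e_r))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "gene", "assay", "condition", "replicate", "cq"],
    )


# ---------------------------------------------------------------------------
# gene sets and full-input writer
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    config: SimulationConfig, truth: GroundTruth, n_random_sets: int = 10
) -> GeneSetCollection:
    """GMT collection: one set per planted quadrant plus random sets."""
    rng = _rng(config, 7)
    genes = config.gene_names()
    sets: dict[str, tuple[str, list[str]]] = {}
    by_quadrant: dict[str, list[str]] = {}
    for gene, quad in truth.quadrant.items():
        by_quadrant.setdefault(quad, []).append(gene)
    for quad, members in sorted(by_quadrant.items()):
        sets[f"PLANTED_{quad.upper().replace('-', '_')}"] = (
            f"planted {quad} genes", sorted(members)
        )
    for i in range(n_random_sets):
        size = int(rng.integers(10, 40))
        members = sorted(rng.choice(genes, size=size, replace=False))
        sets[f"RANDOM_{i+1:02d}"] = ("random background set", list(members))
    return GeneSetCollection(sets)


def write_inputs(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input and write it under ``outdir``.

    Writes expression and beta matrices, group maps, manifest, cytobands,
    the PPI edge list (0-1000 STRING dialect), gene sets, a Cq table and
    the ground truth; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cytobands = simulate_cytobands(config)
    manifest = simulate_manifest(config, cytobands)
    expr, meth, truth = simulate_omics(config, manifest)
    planted_genes = [p.gene for p in config.planted_genes()]
    edges, module = simulate_ppi(config, planted_genes + config.gene_names()[-20:])
    truth = replace_truth_module(truth, module)
    gene_sets = simulate_gene_sets(config, truth)

    rng = _rng(config, 8)
    n_val = 12
    m_case = np.clip(rng.normal(0.7, 0.05, n_val // 2), 0, 1)
    m_ctrl = np.clip(rng.normal(0.5, 0.05, n_val // 2), 0, 1)
    cq = simulate_cq(
        np.concatenate([m_case, m_ctrl]),
        "msre",
        config,
        sample_ids=[f"V{i+1:03d}" for i in range(n_val)],
        groups=["case"] * (n_val // 2) + ["control"] * (n_val // 2),
        gene="VALGENE",
        rng=rng,
    )

    paths = {}
    paths["expression"] = outdir / "expression.tsv"
    write_omics_matrix(expr, paths["expression"])
    paths["methylation"] = outdir / "methylation.tsv"
    write_omics_matrix(meth, paths["methylation"])
    for name, mat in (("expression", expr), ("methylation", meth)):
        p = outdir / f"groups_{name}.tsv"
        pd.DataFrame(
            {"sample_id": mat.sample_ids, "group": mat.group_labels.values}
        ).to_csv(p, sep="\t", index=False)
        paths[f"groups_{name}"] = p
    paths["manifest"] = outdir / "manifest.tsv"
    write_manifest(manifest, paths["manifest"])
    paths["cytobands"] = outdir / "cytoband.txt"
    cytobands.bands.to_csv(paths["cytobands"], sep="\t", index=False, header=False)
    paths["ppi"] = outdir / "ppi.tsv"
    scaled = edges.copy()
    scaled["score"] = (scaled["score"] * 1000).round().astype(int)
    scaled.to_csv(paths["ppi"], sep="\t", index=False, header=False)
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    write_gmt(gene_sets, paths["gene_sets"])
    paths["cq"] = outdir / "cq_table.tsv"
    cq.to_csv(paths["cq"], sep="\t", index=False)
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    pd.DataFrame(
        [{"gene": g, "quadrant": q} for g, q in sorted(truth.quadrant.items())]
    ).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


def replace_truth_module(truth: GroundTruth, module: frozenset[str]) -> GroundTruth:
    return GroundTruth(truth.quadrant, truth.dmc_probes, module)
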