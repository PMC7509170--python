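"""Region-level methylation: aggregation, DMC/DMR/DMG calling, summaries.

A CpG's beta values are averaged with those of all other CpGs annotated to
the same (gene, intragenic region) pair; the mean is the region's
comprehensive methylation level. Single CpGs passing the differential
thresholds are DMCs; regions passing them are DMRs; a gene whose DMRs all
share one direction is a DMG (hyper or hypo). Genes with DMRs in both
directions are flagged conflicted and excluded from DMG lists.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .differential_testing import TestConfig, differential_records, significant
from .io_formats import REGION_CLASSES, Manifest, OmicsMatrix

REGION_SEP = "|"  # region-level feature ids are "GENE|REGION"


@dataclass(frozen=True)
class DmgCall:
    """Per-gene differential-methylation call."""

    gene: str
    direction: str | None  # "hyper", "hypo", or None when conflicted
    dmr_regions: frozenset[str]
    conflicted: bool

    def __post_init__(self) -> None:
        if self.conflicted and self.direction is not None:
            raise ValueError("conflicted genes carry no direction")
        if not self.conflicted and self.direction not in ("hyper", "hypo"):
            raise ValueError("unconflicted DMG needs direction hyper/hypo")


def region_key(gene: str, region: str) -> str:
    return f"{gene}{REGION_SEP}{region}"


def split_region_key(key: str) -> tuple[str, str]:
    gene, region = key.rsplit(REGION_SEP, 1)
    return gene, region


def aggregate_regions(beta_matrix: OmicsMatrix, manifest: Manifest) -> OmicsMatrix:
    """Average CpG betas within each (gene, region) pair, per sample.

    Intergenic probes are excluded. A probe annotated to several
    gene/region pairs contributes to each of them. Regions with no
    probes in the matrix are simply absent.
    """
    pairs = manifest.gene_region_pairs()
    pairs = pairs[pairs["probe_id"].isin(beta_matrix.values.index)]
    if pairs.empty:
        raise ValueError("no annotated intragenic probes present in the beta matrix")
    expanded = beta_matrix.values.loc[pairs["probe_id"]].reset_index(drop=True)
    keys = [region_key(g, r) for g, r in zip(pairs["gene"], pairs["region"])]
    region_means = expanded.groupby(pd.Series(keys, name="feature_id")).mean()
    return OmicsMatrix(region_means, beta_matrix.group_labels, "methylation_region")


def call_dmc(beta_matrix: OmicsMatrix, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Per-CpG differential records; rows with direction != none are DMCs."""
    return differential_records(beta_matrix, config)


def call_dmr_dmg(
    region_matrix: OmicsMatrix,
    config: TestConfig = TestConfig(),
    min_cpgs: int = 1,
    cpg_counts: pd.Series | None = None,
) -> list[DmgCall]:
    """Call DMRs on region means, then DMGs by same-direction consensus.

    ``min_cpgs`` (with ``cpg_counts`` mapping region keys to CpG counts)
    optionally excludes sparsely covered regions; by default a single-CpG
    region is an eligible DMR.
    """
    records = differential_records(region_matrix, config)
    dmrs = significant(records)
    if min_cpgs > 1 and cpg_counts is not None:
        keep = [f for f in dmrs.index if cpg_counts.get(f, 0) >= min_cpgs]
        dmrs = dmrs.loc[keep]
    per_gene: dict[str, dict[str, set[str]]] = {}
    for feature, row in dmrs.iterrows():
        gene, region = split_region_key(feature)
        direction = "hyper" if row["direction"] == "up" else "hypo"
        per_gene.setdefault(gene, {}).setdefault(direction, set()).add(region)
    calls = []
    for gene in sorted(per_gene):
        directions = per_gene[gene]
        regions = frozenset().union(*directions.values())
        if len(directions) > 1:
            calls.append(DmgCall(gene, None, regions, conflicted=True))
        else:
            (direction,) = directions
            calls.append(DmgCall(gene, direction, regions, conflicted=False))
    return calls


def dmg_genes(calls: Iterable[DmgCall], direction: str | None = None) -> list[str]:
    """Unconflicted DMG gene symbols, optionally one direction only."""
    return sorted(
        c.gene
        for c in calls
        if not c.conflicted and (direction is None or c.direction == direction)
    )


def dmg_direction_counts(calls: Iterable[DmgCall]) -> dict[str, int]:
    calls = list(calls)
    return {
        "hyper": sum(1 for c in calls if c.direction == "hyper"),
        "hypo": sum(1 for c in calls if c.direction == "hypo"),
        "conflicted": sum(1 for c in calls if c.conflicted),
        "total_dmg": sum(1 for c in calls if not c.conflicted),
    }


def dmc_region_distribution(
    dmc_records: pd.DataFrame,
    manifest: Manifest,
    gene_subset: Sequence[str] | None = None,
    region_lengths_mb: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Count DMCs per intragenic region class (bar-plot equivalent).

    A DMC annotated to several (gene, region) pairs is counted under each
    pair whose gene lies in ``gene_subset`` (all genes when None).
    Percentages are over the six region classes and sum to 100 whenever
    any DMC is counted. With ``region_lengths_mb`` a per-Mb density
    column is added.
    """
    dmcs = significant(dmc_records)
    pairs = manifest.gene_region_pairs()
    pairs = pairs[pairs["probe_id"].isin(dmcs.index)]
    if gene_subset is not None:
        pairs = pairs[pairs["gene"].isin(set(gene_subset))]
    counts = pairs.groupby("region").size()
    table = pd.DataFrame(
        {"count": [int(counts.get(r, 0)) for r in REGION_CLASSES]},
        index=pd.Index(REGION_CLASSES, name="region"),
    )
    total = table["count"].sum()
    table["percent"] = 100.0 * table["count"] / total if total else 0.0
    if region_lengths_mb is not None:
        table["per_mb"] = [
            table.loc[r, "count"] / region_lengths_mb[r] if region_lengths_mb.get(r) else float("nan")
            for r in REGION_CLASSES
        ]
    return table


def dmr_combination_table(calls: Iterable[DmgCall]) -> pd.DataFrame:
    """Exact region-class-combination counts of DMGs (UpSet equivalent).

    Each unconflicted DMG is counted once under the exact set of region
    classes its DMRs occupy, split by direction.
    """
    rows: dict[tuple[str, tuple[str, ...]], int] = {}
    for c in calls:
        if c.conflicted:
            continue
        combo = tuple(sorted(c.dmr_regions, key=REGION_CLASSES.index))
        rows[(c.direction, combo)] = rows.get((c.direction, combo), 0) + 1
    table = pd.DataFrame(
        [
            {"direction": d, "regions": "+".join(combo), "n_regions": len(combo), "count": n}
            for (d, combo), n in sorted(rows.items())
        ]
    )
    return table


def combination_fractions(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per direction: fraction of DMGs with exactly one / three-plus DMR regions."""
    out: dict[str, dict[str, float]] = {}
    if table.empty:
        return out
    for direction, grp in table.groupby("direction"):
        total = grp["count"].sum()
        out[direction] = {
            "single_region": float(grp.loc[grp["n_regions"] == 1, "count"].sum()) / total,
            "three_plus_regions": float(grp.loc[grp["n_regions"] >= 3, "count"].sum()) / total,
            "total": int(total),
        }
    return out
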