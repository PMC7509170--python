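"""Readers and writers for the tabular formats the pipeline consumes.

All downstream modules work on the validated containers defined here:
:class:`OmicsMatrix` (features x samples with two-group labels),
:class:`Manifest` (450K-style probe annotation), cytoband tables,
protein-interaction edge lists and GMT gene-set collections.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the six intragenic region classes of the 450K manifest
REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
INTERGENIC = "intergenic"
VALID_REGIONS = set(REGION_CLASSES) | {INTERGENIC}

LAYERS = ("expression", "methylation_beta", "methylation_region")
GROUPS = ("case", "control")

#: precision (decimal digits) guaranteed by the TSV round trip
TSV_PRECISION = 6


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class OmicsMatrix:
    """Feature x sample matrix with two-group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample.
    group_labels
        Series indexed by sample id with values ``"case"`` / ``"control"``.
    layer
        One of ``expression``, ``methylation_beta`` or ``methylation_region``.
        Methylation layers must hold beta values in [0, 1].
    """

    values: pd.DataFrame
    group_labels: pd.Series
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        self.group_labels = self.group_labels.reindex(self.values.columns)
        if self.group_labels.isna().any():
            missing = self.group_labels.index[self.group_labels.isna()].tolist()
            raise FormatError(f"samples without a group label: {missing}")
        bad = set(self.group_labels) - set(GROUPS)
        if bad:
            raise FormatError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
        for g in GROUPS:
            if (self.group_labels == g).sum() == 0:
                raise FormatError(f"group {g!r} has no samples")
        if self.values.isna().any().any():
            raise FormatError("matrix contains missing values after load policy")
        if self.layer.startswith("methylation"):
            vals = self.values.to_numpy()
            out = (vals < 0) | (vals > 1)
            if out.any():
                rows = self.values.index[out.any(axis=1)].tolist()
                raise FormatError(f"beta values outside [0,1] for features: {rows[:5]}")

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.group_labels.index[self.group_labels == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.group_labels.index[self.group_labels == "control"])

    def case_values(self) -> pd.DataFrame:
        return self.values[self.case_samples]

    def control_values(self) -> pd.DataFrame:
        return self.values[self.control_samples]

    def swapped_labels(self) -> "OmicsMatrix":
        """Return a copy with case and control labels exchanged."""
        swapped = self.group_labels.map({"case": "control", "control": "case"})
        return OmicsMatrix(self.values.copy(), swapped, self.layer)

    def equals_up_to_feature_order(self, other: "OmicsMatrix") -> bool:
        if set(self.feature_ids) != set(other.feature_ids):
            return False
        if self.sample_ids != other.sample_ids or self.layer != other.layer:
            return False
        return np.allclose(
            self.values.loc[other.feature_ids].to_numpy(), other.values.to_numpy()
        ) and (self.group_labels == other.group_labels).all()


@dataclass
class Manifest:
    """450K-style probe annotation.

    ``records`` holds one row per (probe, gene, region) pair; intergenic
    probes appear with an empty gene symbol and region ``intergenic``.
    Columns: probe_id, chromosome, position (1-based), gene, region.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chromosome", "position", "gene", "region"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if (self.records["position"] < 1).any():
            raise FormatError("manifest positions must be >= 1 (1-based)")
        bad = set(self.records["region"]) - VALID_REGIONS
        if bad:
            raise FormatError(f"unknown region tokens: {sorted(bad)}")
        inter = self.records["region"] == INTERGENIC
        empty = self.records["gene"] == ""
        if (inter != empty).any():
            raise FormatError("region is intergenic iff gene symbol is empty")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.records["probe_id"].unique())

    def gene_region_pairs(self) -> pd.DataFrame:
        """Intragenic (probe, gene, region) rows only."""
        return self.records[self.records["region"] != INTERGENIC].reset_index(drop=True)

    def probe_positions(self) -> pd.DataFrame:
        """One row per probe: probe_id, chromosome, position."""
        return (
            self.records[["probe_id", "chromosome", "position"]]
            .drop_duplicates("probe_id")
            .reset_index(drop=True)
        )

    def genes(self) -> list[str]:
        g = self.records.loc[self.records["gene"] != "", "gene"]
        return sorted(g.unique())


@dataclass
class CytobandTable:
    """UCSC-dialect cytogenetic bands (0-based half-open intervals)."""

    bands: pd.DataFrame  # chromosome, start, end, band

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "band"}
        missing = required - set(self.bands.columns)
        if missing:
            raise FormatError(f"cytoband table missing columns: {sorted(missing)}")
        if (self.bands["end"] <= self.bands["start"]).any():
            raise FormatError("cytoband end must exceed start")
        for chrom, grp in self.bands.groupby("chromosome"):
            srt = grp.sort_values("start")
            if (srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]).any():
                raise FormatError(f"overlapping bands on chromosome {chrom}")

    def chromosome_lengths(self) -> pd.Series:
        return self.bands.groupby("chromosome")["end"].max()


@dataclass
class GeneSetCollection:
    """GMT-style term -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {term!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[term] = (self.sets[term][0], sorted(set(genes)))

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def _normalize_chromosome(c: str) -> str:
    c = str(c).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_group_map(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series of case/control labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("group file needs columns sample_id and group")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "group"]
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"])


def read_omics_matrix(
    path: str | Path, layer: str, group_map: Mapping[str, str] | pd.Series
) -> OmicsMatrix:
    """Load a feature x sample TSV into a validated :class:`OmicsMatrix`.

    Rows containing any unparseable or missing value are dropped with a
    logged count (missing-value policy). A duplicated feature id, a sample
    absent from ``group_map`` or a methylation value outside [0, 1] is a
    hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids in {path}: {dups}")
    df = df.apply(pd.to_numeric, errors="coerce")
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d feature rows with missing values from %s", dropped, path)
    group_map = pd.Series(dict(group_map)) if not isinstance(group_map, pd.Series) else group_map
    missing = [s for s in df.columns if s not in group_map.index]
    if missing:
        raise FormatError(f"samples missing from group map: {missing}")
    if layer.startswith("methylation"):
        vals = df.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            probe = df.index[bad.any(axis=1)][0]
            raise FormatError(f"beta value outside [0,1] for probe {probe!r}")
    return OmicsMatrix(df, group_map.loc[df.columns], layer)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=f"%.{TSV_PRECISION}f", index_label="feature_id")


def read_manifest(path: str | Path) -> Manifest:
    """Parse a 450K-manifest-dialect TSV into a :class:`Manifest`.

    The gene and region fields hold semicolon-separated aligned lists
    (``"A;B"`` / ``"TSS200;Body"``) that are zipped positionally into one
    record per (gene, region) pair. An empty gene field yields a single
    intergenic record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "chromosome", "position", "gene", "region"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        chrom = _normalize_chromosome(rec.chromosome)
        try:
            pos = int(rec.position)
        except ValueError as exc:
            raise FormatError(f"non-integer position for probe {rec.probe_id}") from exc
        genes = [g for g in str(rec.gene).split(";") if g] if str(rec.gene) else []
        regions = [r for r in str(rec.region).split(";") if r] if str(rec.region) else []
        if not genes:
            rows.append((rec.probe_id, chrom, pos, "", INTERGENIC))
            continue
        if len(genes) != len(regions):
            raise FormatError(
                f"probe {rec.probe_id}: gene list length {len(genes)} != region list length {len(regions)}"
            )
        for g, r in zip(genes, regions):
            if r not in REGION_CLASSES:
                raise FormatError(f"probe {rec.probe_id}: unknown region token {r!r}")
            rows.append((rec.probe_id, chrom, pos, g, r))
    out = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "gene", "region"])
    # the same (gene, region) pair listed twice on one probe counts once
    out = out.drop_duplicates().reset_index(drop=True)
    return Manifest(out)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest back to the semicolon-list TSV dialect."""
    rows = []
    for probe_id, grp in manifest.records.groupby("probe_id", sort=False):
        first = grp.iloc[0]
        intragenic = grp[grp["region"] != INTERGENIC]
        genes = ";".join(intragenic["gene"])
        regions = ";".join(intragenic["region"])
        rows.append((probe_id, first["chromosome"], first["position"], genes, regions))
    pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "gene", "region"]).to_csv(
        path, sep="\t", index=False
    )


def read_cytobands(path: str | Path) -> CytobandTable:
    """Read a UCSC cytoBand.txt-style TSV (chrom, start, end, band[, stain])."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise FormatError("cytoband file needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["chromosome", "start", "end", "band"]
    df["chromosome"] = df["chromosome"].map(_normalize_chromosome)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return CytobandTable(df.reset_index(drop=True))


def read_edge_list(path: str | Path, score_cutoff: float = 0.4) -> nx.Graph:
    """Load a three-column interaction TSV into an undirected graph.

    Scores above 1 are auto-detected as the 0-1000 STRING dialect and
    divided by 1000 before the cutoff comparison, which is inclusive
    (``score >= cutoff``, STRING's medium-confidence convention).
    Self-loops are dropped with a warning; duplicate pairs keep the
    maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError("edge list needs columns geneA, geneB, score")
    # tolerate a header row
    first = df.iloc[0, 2]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "score"]
    try:
        df["score"] = df["score"].astype(float)
    except ValueError as exc:
        raise FormatError("non-numeric interaction score") from exc
    if (df["score"] > 1).any():
        df["score"] = df["score"] / 1000.0
    graph = nx.Graph()
    n_loops = 0
    for a, b, s in df.itertuples(index=False):
        if a == b:
            n_loops += 1
            continue
        if s < score_cutoff:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], s)
        else:
            graph.add_edge(a, b, weight=s)
    if n_loops:
        logger.warning("dropped %d self-loop rows from %s", n_loops, path)
    return graph


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {line!r}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"gene set {term!r} has no members")
            sets[term] = (desc, sorted(set(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


CQ_CONDITIONS = ("target", "reference", "undigested", "digested")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy qPCR Cq table.

    Columns: sample_id, group, gene, assay, condition, replicate, cq.
    Cq must lie in (0, 40].
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    required = {"sample_id", "group", "gene", "assay", "condition", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Cq table missing columns: {sorted(missing)}")
    bad = set(df["condition"]) - set(CQ_CONDITIONS)
    if bad:
        raise FormatError(f"unknown Cq conditions: {sorted(bad)}")
    df["cq"] = df["cq"].astype(float)
    if ((df["cq"] <= 0) | (df["cq"] > 40)).any():
        raise FormatError("Cq values must lie in (0, 40]")
    return df
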