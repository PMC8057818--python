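"""Readers and writers for the pipeline's tabular and geometric artifacts.

Formats: cell tables as CSV, count matrices and sample metadata as TSV,
density contours as GeoJSON FeatureCollections, gene sets as GMT or
two-column TSV, and run configuration as YAML. Every writer is inverse
to the corresponding reader on its own output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import MultiPolygon, shape

from .density import DensityContour
from .enrichment import GeneSetCollection
from .simulate import IEG_GENES, RECEPTOR_GENES

REQUIRED_CELL_COLUMNS = ("section_id", "mouse_id", "condition", "region", "x", "y")


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


@dataclass
class RunConfig:
    """Run-level configuration with the pipeline's fixed constants.

    Defaults hold the published analysis constants: 20% KDE coverage,
    fold-change cutoff 1.2 with FDR 0.05, and the receptor cutoff of 8
    puncta/cell.
    """

    seed: int = 0
    coverage: float = 0.20
    fdr: float = 0.05
    fc_min: float = 1.2
    receptor_cutoff: int = 8
    grid_n: int = 100
    bandwidth: tuple[float, float] | None = None
    min_reads: float = 1e6
    reads_cap: float = 8e6
    downsample_fraction: float = 0.5
    thresholds: dict[str, int] = field(default_factory=dict)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must lie in (0, 1)")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if self.fc_min <= 1.0:
            raise ValueError("fc_min must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "bandwidth" in data and data["bandwidth"] is not None:
            data["bandwidth"] = tuple(data["bandwidth"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_cell_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-cell puncta table from CSV.

    Requires the section/mouse/condition/region/x/y columns plus one
    integer puncta column per probed gene; unknown columns are preserved.
    ``column_map`` renames deposit-specific headers onto the schema.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cell table {path} lacks required columns: {missing}")
    for gene in (*IEG_GENES, *RECEPTOR_GENES):
        if gene not in table.columns:
            continue
        col = table[gene]
        if not pd.api.types.is_integer_dtype(col):
            frac = col.astype(float) % 1 != 0
            if frac.any():
                row = int(frac.idxmax())
                raise SchemaError(
                    f"non-integer puncta for {gene} at row {row}: {col[row]!r}"
                )
            table[gene] = col.astype("int64")
        if (table[gene] < 0).any():
            raise SchemaError(f"negative puncta count in column {gene}")
    return table


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_counts(path_counts, path_meta) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count matrix (TSV, genes as rows) and its
    sample metadata (TSV), verifying that the ids align."""
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    meta = pd.read_csv(path_meta, sep="\t")
    if "sample_id" not in meta.columns:
        raise SchemaError("metadata lacks 'sample_id'")
    count_ids, meta_ids = set(counts.columns), set(meta["sample_id"])
    if count_ids != meta_ids:
        only_counts = sorted(count_ids - meta_ids)
        only_meta = sorted(meta_ids - count_ids)
        raise SchemaError(
            f"sample ids disagree; only in counts: {only_counts}; "
            f"only in meta: {only_meta}"
        )
    counts = counts[meta["sample_id"].tolist()]
    if not all(pd.api.types.is_integer_dtype(counts[c]) for c in counts.columns):
        raise SchemaError("count matrix must be integer")
    return counts, meta


def write_counts(counts: pd.DataFrame, meta: pd.DataFrame, path_counts, path_meta) -> None:
    counts.to_csv(path_counts, sep="\t")
    meta.to_csv(path_meta, sep="\t", index=False)


def write_contours(contours: list[DensityContour], path) -> None:
    """Write density contours as a GeoJSON FeatureCollection.

    Feature properties carry gene, condition, section, density level,
    enclosed fraction and mean puncta/cell.
    """
    features = []
    for c in contours:
        for poly in c.polygons.geoms:
            if not poly.exterior.is_closed:
                raise ValueError("contour ring is not closed")
        features.append(
            {
                "type": "Feature",
                "geometry": c.polygons.__geo_interface__,
                "properties": {
                    "gene": c.gene,
                    "condition": c.condition,
                    "section_id": c.section_id,
                    "level": c.level,
                    "enclosed_fraction": c.enclosed_fraction,
                    "mean_puncta": None if pd.isna(c.mean_puncta) else c.mean_puncta,
                    "n_cells": c.n_cells,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_contours(path) -> list[DensityContour]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            geom = MultiPolygon([geom])
        props = feat["properties"]
        out.append(
            DensityContour(
                level=props["level"],
                polygons=geom,
                enclosed_fraction=props["enclosed_fraction"],
                mean_puncta=(
                    float("nan") if props["mean_puncta"] is None else props["mean_puncta"]
                ),
                gene=props["gene"],
                condition=props["condition"],
                section_id=props["section_id"],
                n_cells=props["n_cells"],
            )
        )
    return out


def read_gene_sets(path, universe: set[str]) -> GeneSetCollection:
    """Read a gene-set collection from GMT or two-column TSV.

    GMT: ``term<TAB>description<TAB>gene...`` per line. TSV: header-less
    ``term<TAB>gene`` pairs.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"malformed GMT line: {line[:60]!r}")
            term, desc, genes = parts[0], parts[1], parts[2:]
            sets[term] = set(g for g in genes if g)
            names[term] = desc or term
    else:
        pairs = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
        for term, sub in pairs.groupby("term"):
            sets[str(term)] = set(sub["gene"].astype(str))
    return GeneSetCollection(sets=sets, universe=universe, names=names)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([term, collection.names.get(term, term), *sorted(genes)])
        for term, genes in sorted(collection.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")
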