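"""Robust-expressor thresholds for smFISH puncta counts.

For each IEG, cells of the cocaine-naive control pool expressing 0-1
puncta are discarded as non-expressing; the remaining cells are ranked by
per-cell puncta count and the minimum count among the top third ("robust
expressors") becomes the inclusive suprathreshold cutoff. Receptor
positivity (Drd1+/Drd2+) uses a fixed cutoff of 8 puncta/cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .simulate import IEG_GENES, RECEPTOR_GENES

DEFAULT_RECEPTOR_CUTOFF = 8


class InsufficientDataError(ValueError):
    """Fewer than three expressing cells remain for threshold derivation."""


@dataclass
class ThresholdSet:
    """Per-gene suprathreshold cutoffs plus the fixed receptor cutoff.

    ``provenance[gene]`` records (n_control_cells, n_removed_nonexpressing).
    """

    cutoffs: dict[str, int]
    receptor_cutoff: int = DEFAULT_RECEPTOR_CUTOFF
    provenance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, c in self.cutoffs.items():
            if c < 2:
                raise ValueError(f"cutoff for {gene} must be >= 2 (got {c})")
        if self.receptor_cutoff <= 0:
            raise ValueError("receptor_cutoff must be positive")


def derive_threshold(
    control_counts, gene: str = "", rule: str = "floor"
) -> tuple[int, tuple[int, int]]:
    """Tertile cutoff from control-cell puncta counts.

    Removes non-expressing cells (0-1 puncta), takes k = floor(N'/3) (or
    ceil under ``rule='ceiling'``), and returns the k-th largest remaining
    count: the minimum puncta among the top-tertile cells, so that
    classification with ``count >= cutoff`` is inclusive. Also returns
    provenance (cells used, cells removed).
    """
    counts = np.asarray(control_counts)
    if counts.size == 0:
        raise InsufficientDataError(f"no control cells for {gene or 'gene'}")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("puncta counts must be integers")
        counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("puncta counts must be non-negative")
    expressing = counts[counts >= 2]
    n_removed = counts.size - expressing.size
    n_prime = expressing.size
    if n_prime < 3:
        raise InsufficientDataError(
            f"only {n_prime} expressing control cells for {gene or 'gene'}; need >= 3"
        )
    if rule == "floor":
        k = n_prime // 3
    elif rule == "ceiling":
        k = math.ceil(n_prime / 3)
    else:
        raise ValueError(f"unknown tertile rule {rule!r}")
    k = max(k, 1)
    cutoff = int(np.sort(expressing)[::-1][k - 1])
    return cutoff, (n_prime, n_removed)


def derive_thresholds(
    cells: pd.DataFrame,
    genes=IEG_GENES,
    receptor_cutoff: int = DEFAULT_RECEPTOR_CUTOFF,
    per_region: bool = False,
    rule: str = "floor",
) -> ThresholdSet:
    """ThresholdSet from the pooled control cells of a cell table.

    The control pool is all ``condition == 'control'`` cells across
    sections and regions; ``per_region=True`` instead derives one cutoff
    per (gene, region) and stores it under ``"gene/region"``.
    """
    control = cells[cells["condition"] == "control"]
    if control.empty:
        raise InsufficientDataError("cell table contains no control cells")
    cutoffs: dict[str, int] = {}
    provenance: dict[str, tuple[int, int]] = {}
    if per_region:
        for region, sub in control.groupby("region"):
            for gene in genes:
                c, prov = derive_threshold(sub[gene].to_numpy(), gene, rule)
                cutoffs[f"{gene}/{region}"] = c
                provenance[f"{gene}/{region}"] = prov
    else:
        for gene in genes:
            c, prov = derive_threshold(control[gene].to_numpy(), gene, rule)
            cutoffs[gene] = c
            provenance[gene] = prov
    return ThresholdSet(cutoffs, receptor_cutoff, provenance)


def classify_cells(cells: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Annotate a cell table with suprathreshold flags and receptor labels.

    Adds one boolean ``supra_<gene>`` column per thresholded IEG
    (``puncta >= cutoff``, inclusive) and a ``receptor_class`` column in
    {Drd1, Drd2, dual, unassigned} using the fixed receptor cutoff.
    """
    out = cells.copy()
    for gene, cutoff in thresholds.cutoffs.items():
        col, _, region = gene.partition("/")
        if col not in out.columns:
            raise KeyError(f"cell table lacks puncta column {col!r}")
        flag = f"supra_{col}"
        if region:  # per-region cutoff
            if flag not in out.columns:
                out[flag] = False
            mask = out["region"] == region
            out.loc[mask, flag] = out.loc[mask, col] >= cutoff
        else:
            out[flag] = out[col] >= cutoff
    for receptor in RECEPTOR_GENES:
        if receptor not in out.columns:
            raise KeyError(f"cell table lacks puncta column {receptor!r}")
    d1 = out["Drd1"] >= thresholds.receptor_cutoff
    d2 = out["Drd2"] >= thresholds.receptor_cutoff
    out["receptor_class"] = np.select(
        [d1 & d2, d1, d2], ["dual", "Drd1", "Drd2"], default="unassigned"
    )
    return out
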