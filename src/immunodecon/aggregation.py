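"""Collapse fine-grained immune cell types into cell families.

The LM22 taxonomy distinguishes 22 leukocyte types; downstream pattern
analysis works on families (all five CD4 subtypes summed into one CD4
T-cell fraction, both B-cell subtypes into one B fraction, and so on).
Types the taxonomy does not subdivide (CD8 T-cells, plasma cells,
gamma-delta T-cells, monocytes, eosinophils, neutrophils) pass through as
singleton families so per-sample totals are conserved.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Mapping, Union

import pandas as pd

from .datatypes import ProportionEstimate, ValidationError

__all__ = [
    "AggregationMap",
    "default_lm22_map",
    "aggregate",
    "LM22_CELL_TYPES",
    "LM22_FAMILY_OF",
    "LM22_FAMILIES",
]

# Canonical LM22 cell-type spellings, in LM22 column order.
LM22_CELL_TYPES = [
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
]

# Fixed family spellings; one constant table keeps downstream joins bit-exact.
LM22_FAMILY_OF = {
    "B cells naive": "B cells",
    "B cells memory": "B cells",
    "Plasma cells": "Plasma cells",
    "T cells CD8": "CD8 T cells",
    "T cells CD4 naive": "CD4 T cells",
    "T cells CD4 memory resting": "CD4 T cells",
    "T cells CD4 memory activated": "CD4 T cells",
    "T cells follicular helper": "CD4 T cells",
    "T cells regulatory (Tregs)": "CD4 T cells",
    "T cells gamma delta": "Gamma delta T cells",
    "NK cells resting": "NK cells",
    "NK cells activated": "NK cells",
    "Monocytes": "Monocytes",
    "Macrophages M0": "Macrophages",
    "Macrophages M1": "Macrophages",
    "Macrophages M2": "Macrophages",
    "Dendritic cells resting": "Dendritic cells",
    "Dendritic cells activated": "Dendritic cells",
    "Mast cells resting": "Mast cells",
    "Mast cells activated": "Mast cells",
    "Eosinophils": "Eosinophils",
    "Neutrophils": "Neutrophils",
}

# Family order: first appearance in LM22 column order.
LM22_FAMILIES = list(dict.fromkeys(LM22_FAMILY_OF[t] for t in LM22_CELL_TYPES))


@dataclass(frozen=True)
class AggregationMap:
    """Many-to-one map from fine cell types to family labels."""

    family_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.family_of:
            raise ValidationError("aggregation map is empty")

    @property
    def families(self) -> list[str]:
        """Family labels in order of first appearance."""
        return list(dict.fromkeys(self.family_of.values()))

    @classmethod
    def from_csv(cls, path: Union[str, os.PathLike]) -> "AggregationMap":
        """Read a 2-column CSV ``fine_type,family`` (header optional)."""
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or len(row) < 2:
                    continue
                if row[0] == "fine_type" and row[1] == "family":
                    continue
                if row[0] in mapping:
                    raise ValidationError(f"fine type mapped twice: {row[0]!r}")
                mapping[row[0]] = row[1]
        return cls(mapping)

    def to_csv(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fine_type", "family"])
            for fine, fam in self.family_of.items():
                writer.writerow([fine, fam])


def default_lm22_map() -> AggregationMap:
    """The canonical 22-type -> 12-family map used throughout the pipeline."""
    return AggregationMap(dict(LM22_FAMILY_OF))


def aggregate(est: ProportionEstimate, mapping: AggregationMap) -> ProportionEstimate:
    """Sum member fractions into family fractions, per sample.

    Every cell type present in ``est`` must appear in ``mapping``;
    diagnostics are carried through unchanged. Per-sample mass is conserved
    exactly (a pure reordering + summation).
    """
    unmapped = [t for t in est.cell_types if t not in mapping.family_of]
    if unmapped:
        raise ValidationError(f"cell types missing from aggregation map: {unmapped}")
    groups = est.fractions.T.groupby(
        [mapping.family_of[t] for t in est.cell_types], sort=False
    ).sum().T
    # keep family order deterministic: first appearance in est's column order
    order = list(dict.fromkeys(mapping.family_of[t] for t in est.cell_types))
    groups = groups[order]
    groups.columns.name = est.fractions.columns.name
    return ProportionEstimate(fractions=groups, diagnostics=est.diagnostics.copy())
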