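"""Marker-based cell gating and subset-restricted repertoire statistics.

A subset is defined by a raw UMI threshold on one marker gene: a cell is
CD8+ (or FOXP3+) when it carries at least ``min_umi`` copies of the marker
(default 1).  Gating deliberately uses raw counts, not normalized values.
Cells gated on FOXP3 are reported as "FOXP3+ T cells" rather than
regulatory T cells: one or more FOXP3 UMIs can also mark activated
conventional T cells.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

from .io import ChainRecord, ExpressionMatrix
from .stats import diversity

#: marker shorthand -> gene symbols tried in order (panel-dependent)
MARKER_ALIASES = {
    "CD8": ("CD8", "CD8A", "CD8B"),
    "CD8A": ("CD8A", "CD8"),
    "FOXP3": ("FOXP3",),
}


@dataclass(frozen=True)
class GateDefinition:
    """A marker gene plus the minimum UMI count defining positivity."""

    marker: str
    min_umi: int = 1

    def __post_init__(self) -> None:
        if self.min_umi < 1:
            raise ValueError("min_umi must be >= 1")


def resolve_marker(expr: ExpressionMatrix, marker: str) -> str:
    """Resolve a marker name against the panel, trying known aliases."""
    for candidate in MARKER_ALIASES.get(marker, (marker,)):
        if candidate in expr.gene_ids:
            return candidate
    near = difflib.get_close_matches(marker, expr.gene_ids, n=3)
    raise KeyError(
        f"marker {marker!r} not in expression panel"
        + (f"; close matches: {near}" if near else "")
    )


def gate_cells(expr: ExpressionMatrix, gate: GateDefinition) -> set[str]:
    """Cells with at least ``gate.min_umi`` copies of the marker gene."""
    gene = resolve_marker(expr, gate.marker)
    column = expr.counts[:, expr.gene_index(gene)]
    return {cell for cell, count in zip(expr.cell_ids, column)
            if count >= gate.min_umi}


def subset_records(records: list[ChainRecord], cells: set[str]) -> list[ChainRecord]:
    """Chain records of the gated cells, input order preserved."""
    return [r for r in records if r.cell_id in cells]


def subset_diversity(
    records: list[ChainRecord],
    cells: set[str],
    entity: str = "cdr3_aa",
    locus: str | None = None,
    weight_basis: str = "molecules",
) -> float:
    """Shannon index of a repertoire entity restricted to gated cells."""
    subset = subset_records(records, cells)
    if not subset:
        raise ValueError("gated subset contains no chain records")
    return diversity(subset, entity=entity, locus=locus,
                     weight_basis=weight_basis)
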