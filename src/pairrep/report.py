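"""End-to-end report bundle: usage, pairing, diversity, clonotypes, DE.

Wires the pipeline stages into one deterministic run over a sample: V/J
usage tables for both loci, V-J pairing matrices, a diversity table (bulk
and marker-gated subsets x TRA/TRB), top-clonotype tables (bulk and per
gate) and, when a reference sample is supplied, per-gate up/down
fold-change rankings.  A JSON manifest records versions, parameters and
the seed; outputs are byte-identical across reruns with fixed inputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import SegmentCatalog, default_catalog, load_catalog
from .diffexpr import rank_fold_changes
from .gating import GateDefinition, gate_cells, subset_diversity, subset_records
from .io import ExpressionMatrix, read_expression, read_rearrangements
from .stats import (assemble_clonotypes, clonotype_table, segment_usage,
                    vj_pairing)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, filters and options of one report run."""

    rearrangements: str
    out_dir: str
    matrix: str | None = None
    cells: str | None = None
    genes: str | None = None
    catalog: str | None = None
    keep: tuple[str, ...] = ("functional",)
    weight_basis: str = "molecules"
    entity: str = "cdr3_aa"
    gates: tuple[tuple[str, int], ...] = (("CD8A", 1), ("FOXP3", 1))
    ref_matrix: str | None = None
    ref_cells: str | None = None
    ref_genes: str | None = None
    pseudocount: float = 1.0
    top_n: int = 10
    seed: int = 0


def _stage(name):
    def wrap(fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - start)
        return result

    return wrap


def _gate_label(marker: str) -> str:
    # FOXP3-gated cells are reported as FOXP3+ T cells, never as Tregs
    return f"{marker}+"


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle; returns paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    header = (f"# pairrep {__version__}; seed={config.seed}; "
              f"keep={','.join(config.keep)}; weight={config.weight_basis}\n")

    catalog = _stage("catalog")(
        lambda: load_catalog(config.catalog) if config.catalog
        else default_catalog()
    )
    records = _stage("rearrangements")(read_rearrangements,
                                       config.rearrangements)

    expr: ExpressionMatrix | None = None
    if config.matrix:
        expr = _stage("expression")(read_expression, config.matrix,
                                    config.cells, config.genes)

    keep = set(config.keep)
    for locus in ("TRA", "TRB"):
        for stype in ("V", "J"):
            table = _stage(f"usage:{locus}{stype}")(
                segment_usage, records, locus, stype, catalog, keep,
                config.weight_basis,
            )
            path = out_dir / f"usage_{locus}{stype}.tsv"
            _write_tsv(table.to_frame(), path, header)
            outputs[f"usage_{locus}{stype}"] = path
        pairing = _stage(f"pairing:{locus}")(
            vj_pairing, records, locus, catalog, keep, config.weight_basis
        )
        path = out_dir / f"pairing_{locus}.tsv"
        _write_tsv(pairing.to_frame(), path, header, index=True)
        outputs[f"pairing_{locus}"] = path

    # gated subsets
    subsets: dict[str, set[str]] = {"bulk": {r.cell_id for r in records}}
    for marker, min_umi in config.gates:
        stage_name = f"gate:{marker}"
        if expr is None:
            raise RuntimeError(
                f"stage {stage_name!r} failed: gate on {marker} requested "
                "but no expression matrix was provided"
            )
        subsets[_gate_label(marker)] = _stage(stage_name)(
            gate_cells, expr, GateDefinition(marker, min_umi)
        )

    rows = []
    for label, cells in subsets.items():
        for locus in ("TRA", "TRB"):
            try:
                h = subset_diversity(records, cells, entity=config.entity,
                                     locus=locus,
                                     weight_basis=config.weight_basis)
            except ValueError:
                h = float("nan")
            rows.append({"subset": label, "locus": locus,
                         "entity": config.entity, "shannon_index": h})
    path = out_dir / "diversity.tsv"
    _write_tsv(pd.DataFrame(rows), path, header)
    outputs["diversity"] = path

    for label, cells in subsets.items():
        clonotypes, unpaired = _stage(f"clonotypes:{label}")(
            assemble_clonotypes, subset_records(records, cells)
        )
        table = clonotype_table(clonotypes, config.top_n)
        path = out_dir / f"clonotypes_{label.replace('+', 'pos')}.tsv"
        _write_tsv(table, path,
                   header + f"# unpaired_cells={len(unpaired)}\n")
        outputs[f"clonotypes_{label}"] = path

    if config.ref_matrix:
        ref_expr = _stage("reference")(read_expression, config.ref_matrix,
                                       config.ref_cells, config.ref_genes)
        for marker, min_umi in config.gates:
            gate = GateDefinition(marker, min_umi)
            ranking = _stage(f"de:{marker}")(
                rank_fold_changes, expr, ref_expr,
                gate_cells(expr, gate), gate_cells(ref_expr, gate),
                config.pseudocount,
            )
            frame = pd.concat([ranking.top(config.top_n),
                               ranking.bottom(config.top_n)])
            path = out_dir / f"de_{marker}.tsv"
            _write_tsv(frame, path, header)
            outputs[f"de_{marker}"] = path

    manifest = {
        "tool": "pairrep",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": {
            "keep": sorted(config.keep),
            "weight_basis": config.weight_basis,
            "entity": config.entity,
            "gates": [list(g) for g in config.gates],
            "pseudocount": config.pseudocount,
            "top_n": config.top_n,
        },
        "outputs": sorted(p.name for p in outputs.values()),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    outputs["manifest"] = path
    return outputs


def _write_tsv(frame: pd.DataFrame, path: Path, header: str,
               index: bool = False) -> None:
    with open(path, "w") as handle:
        handle.write(header)
        frame.to_csv(handle, sep="\t", index=index,
                     float_format="%.10g")
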