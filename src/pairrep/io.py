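"""Reading/writing standard formats and read-to-molecule folding.

Chain annotations travel as AIRR Rearrangement TSV (one row per recovered
chain per cell); expression counts as a MatrixMarket triplet plus cell/gene
name files, or an equivalent dense TSV.  A "molecule" is a distinct
(cell label, gene, UMI) triple; reads sharing all three collapse to one
molecule.  A simplified directional Hamming-1 UMI merge approximates
substitution-error correction upstream of folding.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

TCR_LOCI = ("TRA", "TRB")

#: AIRR Rearrangement columns this pipeline requires / writes
AIRR_COLUMNS = ("cell_id", "locus", "v_call", "j_call", "junction_aa",
                "duplicate_count")


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read: cell label, UMI tag, gene it aligned to."""

    cell_label: str
    umi: str
    gene: str
    read_id: str = ""


@dataclass(frozen=True)
class ChainRecord:
    """One recovered TCR chain in one cell (UMI-collapsed counts)."""

    cell_id: str
    locus: str
    v_call: str
    j_call: str
    junction_aa: str
    molecule_count: int = 1
    read_count: int | None = None

    def __post_init__(self) -> None:
        if self.read_count is None:
            object.__setattr__(self, "read_count", self.molecule_count)
        if self.molecule_count < 0:
            raise ValueError("molecule_count must be non-negative")
        if self.read_count < self.molecule_count:
            raise ValueError("molecule_count cannot exceed read_count")


@dataclass
class ExpressionMatrix:
    """Cells x genes UMI count matrix with ordered id lists."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells as obs)."""
        import anndata

        return anndata.AnnData(
            X=scipy.sparse.csr_matrix(self.counts),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )


def read_rearrangements(path) -> list[ChainRecord]:
    """Read chain records from an AIRR Rearrangement TSV.

    Requires cell_id, locus, v_call, j_call and junction_aa columns;
    duplicate_count is optional (default 1) and is taken as the molecule
    count.  Rows on loci other than TRA/TRB are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    required = ["cell_id", "locus", "v_call", "j_call", "junction_aa"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"AIRR file {path} missing mandatory column {col!r}")
    n_before = len(df)
    df = df[df["locus"].isin(TCR_LOCI)]
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d non-TRA/TRB rows from %s", dropped, path)
    if "duplicate_count" in df.columns:
        counts = pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1)
    else:
        counts = pd.Series(1, index=df.index)
    return [
        ChainRecord(
            cell_id=row.cell_id,
            locus=row.locus,
            v_call=row.v_call,
            j_call=row.j_call,
            junction_aa=row.junction_aa,
            molecule_count=int(count),
        )
        for row, count in zip(df.itertuples(index=False), counts)
    ]


def write_rearrangements(records: Iterable[ChainRecord], path) -> None:
    """Write chain records as AIRR Rearrangement TSV (retained columns)."""
    df = pd.DataFrame(
        [
            (r.cell_id, r.locus, r.v_call, r.j_call, r.junction_aa,
             r.molecule_count)
            for r in records
        ],
        columns=list(AIRR_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def _read_names(path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def read_expression(matrix_path, cells_path=None, genes_path=None) -> ExpressionMatrix:
    """Read a cells x genes count matrix.

    MatrixMarket triplet (``.mtx``, cells as rows) with one-name-per-line
    cell and gene files, or a dense TSV with cell rows and gene columns
    (first column = cell ids).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if cells_path is None or genes_path is None:
            raise ValueError("MatrixMarket input needs cells_path and genes_path")
        mat = scipy.io.mmread(matrix_path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        cell_ids = _read_names(cells_path)
        gene_ids = _read_names(genes_path)
        if counts.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts = df.to_numpy()
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
    if not np.issubdtype(counts.dtype, np.integer):
        rounded = np.rint(counts)
        if not np.allclose(counts, rounded):
            raise ValueError("expression counts must be integral")
        counts = rounded.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("expression counts must be non-negative")
    return ExpressionMatrix(cell_ids, gene_ids, counts)


def write_expression(expr: ExpressionMatrix, matrix_path, cells_path, genes_path) -> None:
    """Write an expression matrix as MatrixMarket plus name files."""
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(expr.counts))
    Path(cells_path).write_text("".join(f"{c}\n" for c in expr.cell_ids))
    Path(genes_path).write_text("".join(f"{g}\n" for g in expr.gene_ids))


def fold_molecules(reads: Iterable[ReadRecord]) -> dict[tuple[str, str], int]:
    """Fold reads into molecules: distinct UMIs per (cell label, gene)."""
    umis: dict[tuple[str, str], set[str]] = defaultdict(set)
    for read in reads:
        if not read.umi:
            raise ValueError("read with empty UMI")
        umis[(read.cell_label, read.gene)].add(read.umi)
    return {key: len(vals) for key, vals in umis.items()}


def _hamming1(a: str, b: str) -> bool:
    return sum(x != y for x, y in zip(a, b)) == 1


def collapse_umis_hamming1(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Directionally merge near-duplicate UMIs within each (cell, gene) group.

    Within a group, a UMI at Hamming distance 1 from a strictly
    more-abundant UMI is relabelled to that UMI, most-abundant absorber
    first (ties broken lexicographically); passes repeat until no merge
    applies, so the operation is idempotent on its own output.  Equal-count
    neighbours are never merged.
    """
    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, read in enumerate(reads):
        groups[(read.cell_label, read.gene)].append(i)

    relabel: dict[int, str] = {}
    for key, idxs in groups.items():
        lengths = {len(reads[i].umi) for i in idxs}
        if len(lengths) > 1:
            raise ValueError(f"unequal UMI lengths within group {key}")
        mapping = _merge_mapping(Counter(reads[i].umi for i in idxs))
        for i in idxs:
            if reads[i].umi in mapping:
                relabel[i] = mapping[reads[i].umi]

    return [
        ReadRecord(r.cell_label, relabel[i], r.gene, r.read_id)
        if i in relabel
        else r
        for i, r in enumerate(reads)
    ]


def _merge_mapping(counts: Counter) -> dict[str, str]:
    """Directional Hamming-1 merge; returns victim UMI -> final absorber."""
    mapping: dict[str, str] = {}
    changed = True
    while changed:
        changed = False
        # least-abundant victims first; deterministic via lexicographic ties
        for umi in sorted(counts, key=lambda u: (counts[u], u)):
            candidates = [
                other
                for other in counts
                if counts[other] > counts[umi] and _hamming1(other, umi)
            ]
            if not candidates:
                continue
            absorber = min(candidates, key=lambda u: (-counts[u], u))
            counts[absorber] += counts.pop(umi)
            for victim, target in list(mapping.items()):
                if target == umi:
                    mapping[victim] = absorber
            mapping[umi] = absorber
            changed = True
            break
    return mapping
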