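"""Repertoire statistics: segment usage, V-J pairing, clonotypes, diversity.

Usage vectors and pairing matrices are percentage frequency tables over the
functional segment universe of a locus: the weighted count of each kept
segment (or V-J pair) divided by the weighted total over kept segments,
times 100.  Segments excluded by functionality class contribute to neither
numerator nor denominator.  Weights are UMI-collapsed molecule counts by
default; read counts and per-chain-record ("cells") weighting are
alternatives because upstream conventions differ.

Paired clonotypes are assembled per cell as the 6-tuple
(TRAV, CDR3alpha, TRAJ, TRBV, CDR3beta, TRBJ) of the dominant chain of each
locus; clonal diversity is the Shannon index H' = -sum p_i ln p_i over a
configurable repertoire entity.
"""

from __future__ import annotations

import logging

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .catalog import SegmentCatalog, normalize_segment_name
from .io import ChainRecord

logger = logging.getLogger(__name__)

WEIGHT_BASES = ("molecules", "reads", "cells")
DIVERSITY_ENTITIES = ("cdr3_aa", "vj_pair", "clonotype", "per_chain_cdr3")


@dataclass
class FrequencyTable:
    """A named discrete distribution in percent."""

    labels: list
    percent: np.ndarray
    weight_basis: str = "molecules"
    name: str = ""

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if len(self.labels) != len(set(map(str, self.labels))):
            raise ValueError("frequency table labels must be unique")
        if len(self.labels) != self.percent.size:
            raise ValueError("labels and percent length mismatch")
        if (self.percent < 0).any():
            raise ValueError("percent values must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label) -> float:
        return float(self.percent[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "percent": self.percent})


@dataclass
class PairingMatrix:
    """Percentage frequencies over every V-J recombination of one locus."""

    v_labels: list[str]
    j_labels: list[str]
    percent: np.ndarray
    weight_basis: str = "molecules"
    locus: str = ""

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.shape != (len(self.v_labels), len(self.j_labels)):
            raise ValueError("pairing matrix shape mismatch")

    @property
    def n_recombinants(self) -> int:
        return len(self.v_labels) * len(self.j_labels)

    def row_sums(self) -> np.ndarray:
        return self.percent.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.percent.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=self.v_labels,
                            columns=self.j_labels)


@dataclass(frozen=True)
class Clonotype:
    """A paired alpha/beta receptor identity with its cell-level frequency."""

    tra_v: str
    cdr3_a: str
    tra_j: str
    trb_v: str
    cdr3_b: str
    trb_j: str
    n_cells: int = 1
    frequency_percent: float = 0.0

    @property
    def key(self) -> tuple[str, str, str, str, str, str]:
        return (self.tra_v, self.cdr3_a, self.tra_j,
                self.trb_v, self.cdr3_b, self.trb_j)


def _record_weight(record: ChainRecord, weight_basis: str) -> float:
    if weight_basis == "molecules":
        return record.molecule_count
    if weight_basis == "reads":
        return record.read_count
    if weight_basis == "cells":
        return 1.0
    raise ValueError(f"unknown weight basis {weight_basis!r}")


def _kept_labels(catalog: SegmentCatalog, locus: str, segment_type: str,
                 keep: set[str]) -> list[str]:
    labels = catalog.names(locus, segment_type, keep)
    return labels


def _resolve_segment(name: str, locus: str, segment_type: str,
                     catalog: SegmentCatalog, keep: set[str]) -> str | None:
    """Canonical name if kept, None if excluded; unknowns kept with warning."""
    canonical = normalize_segment_name(name, locus=locus,
                                       segment_type=segment_type)
    if canonical in catalog:
        if catalog.functionality(canonical) not in keep:
            return None
        return canonical
    logger.warning("segment %s absent from catalog; treated as functional",
                   canonical)
    return canonical


def segment_usage(
    records: list[ChainRecord],
    locus: str,
    segment_type: str,
    catalog: SegmentCatalog,
    keep: set[str] = frozenset({"functional"}),
    weight_basis: str = "molecules",
    min_count: float = 0.0,
) -> FrequencyTable:
    """Percentage usage of each kept V (or J) segment of one locus.

    ``min_count`` additionally drops kept segments whose weighted count is
    below the threshold from both labels and denominator (the data-dependent
    "low-expressed" exclusion); the default 0 drops nothing, so unobserved
    kept segments appear with 0%.
    """
    if locus not in ("TRA", "TRB"):
        raise ValueError(f"unknown locus {locus!r}")
    if segment_type not in ("V", "J"):
        raise ValueError(f"unknown segment type {segment_type!r}")
    if weight_basis not in WEIGHT_BASES:
        raise ValueError(f"unknown weight basis {weight_basis!r}")

    labels = _kept_labels(catalog, locus, segment_type, set(keep))
    weights: dict[str, float] = {name: 0.0 for name in labels}
    for record in records:
        if record.locus != locus:
            continue
        call = record.v_call if segment_type == "V" else record.j_call
        resolved = _resolve_segment(call, locus, segment_type, catalog,
                                    set(keep))
        if resolved is None:
            continue
        if resolved not in weights:
            labels.append(resolved)
            weights[resolved] = 0.0
        weights[resolved] += _record_weight(record, weight_basis)

    if min_count > 0:
        labels = [g for g in labels if weights[g] >= min_count]
    values = np.array([weights[g] for g in labels], dtype=float)
    total = values.sum()
    percent = 100.0 * values / total if total > 0 else values
    return FrequencyTable(labels, percent, weight_basis,
                          name=f"{locus}{segment_type} usage")


def vj_pairing(
    records: list[ChainRecord],
    locus: str,
    catalog: SegmentCatalog,
    keep: set[str] = frozenset({"functional"}),
    weight_basis: str = "molecules",
) -> PairingMatrix:
    """Percentage frequency of every V-J recombination of one locus.

    The matrix spans the full kept V x kept J space (plus any observed
    off-catalog segments); entries sum to 100 and the marginals reproduce
    :func:`segment_usage` when the data carries no excluded segments.
    """
    v_labels = _kept_labels(catalog, locus, "V", set(keep))
    j_labels = _kept_labels(catalog, locus, "J", set(keep))
    weights: dict[tuple[str, str], float] = defaultdict(float)
    for record in records:
        if record.locus != locus:
            continue
        v = _resolve_segment(record.v_call, locus, "V", catalog, set(keep))
        j = _resolve_segment(record.j_call, locus, "J", catalog, set(keep))
        if v is None or j is None:
            continue
        if v not in v_labels:
            v_labels.append(v)
        if j not in j_labels:
            j_labels.append(j)
        weights[(v, j)] += _record_weight(record, weight_basis)

    matrix = np.zeros((len(v_labels), len(j_labels)))
    v_index = {name: i for i, name in enumerate(v_labels)}
    j_index = {name: i for i, name in enumerate(j_labels)}
    for (v, j), w in weights.items():
        matrix[v_index[v], j_index[j]] = w
    total = matrix.sum()
    if total > 0:
        matrix = 100.0 * matrix / total
    return PairingMatrix(v_labels, j_labels, matrix, weight_basis, locus)


def shannon_index(values) -> float:
    """Shannon diversity H' = -sum p_i ln p_i of a count/frequency vector.

    The input is normalized to sum 1; zero entries are skipped.  Satisfies
    0 <= H' <= ln S for S positive entries.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0 or (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("shannon_index needs a non-negative vector with a "
                         "positive total")
    return float(_scipy_entropy(arr[arr > 0]))


def assemble_clonotypes(
    records: list[ChainRecord],
) -> tuple[list[Clonotype], list[str]]:
    """Assemble one paired clonotype per cell.

    Per cell, the TRA and TRB chains with the largest molecule count are
    selected (ties: lexicographically smallest junction_aa, then v_call).
    Cells lacking either locus are returned separately as unpaired and are
    excluded from the paired frequency denominator.
    """
    by_cell: dict[str, dict[str, ChainRecord]] = defaultdict(dict)
    for record in records:
        best = by_cell[record.cell_id].get(record.locus)
        if best is None or _chain_rank(record) < _chain_rank(best):
            by_cell[record.cell_id][record.locus] = record

    cell_keys: dict[str, tuple] = {}
    unpaired: list[str] = []
    for cell_id, chains in by_cell.items():
        if "TRA" in chains and "TRB" in chains:
            a, b = chains["TRA"], chains["TRB"]
            cell_keys[cell_id] = (a.v_call, a.junction_aa, a.j_call,
                                  b.v_call, b.junction_aa, b.j_call)
        else:
            unpaired.append(cell_id)

    counts = Counter(cell_keys.values())
    total = sum(counts.values())
    clonotypes = [
        Clonotype(*key, n_cells=n, frequency_percent=100.0 * n / total)
        for key, n in counts.items()
    ]
    return clonotypes, unpaired


def _chain_rank(record: ChainRecord) -> tuple:
    return (-record.molecule_count, record.junction_aa, record.v_call)


def top_clonotypes(clonotypes: list[Clonotype], n: int) -> list[Clonotype]:
    """The ``n`` most frequent clonotypes, ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be positive")
    ranked = sorted(clonotypes, key=lambda c: (-c.n_cells, c.key))
    return ranked[:n]


def clonotype_table(clonotypes: list[Clonotype], n: int = 10) -> pd.DataFrame:
    """Top-n clonotypes as a report table (frequency shown to 1 decimal)."""
    rows = [
        {
            "clone_rank": i,
            "frequency_percent": round(c.frequency_percent, 1),
            "n_cells": c.n_cells,
            "TRAV": c.tra_v,
            "CDR3_TRA": c.cdr3_a,
            "TRAJ": c.tra_j,
            "TRBV": c.trb_v,
            "CDR3_TRB": c.cdr3_b,
            "TRBJ": c.trb_j,
        }
        for i, c in enumerate(top_clonotypes(clonotypes, n), start=1)
    ]
    return pd.DataFrame(rows)


def diversity(
    records: list[ChainRecord],
    entity: str = "cdr3_aa",
    locus: str | None = None,
    weight_basis: str = "molecules",
) -> float:
    """Shannon index over a repertoire entity.

    Entities: ``cdr3_aa`` (distinct CDR3 amino-acid strings of one locus,
    weight-basis weighted), ``vj_pair`` (distinct V-J pairs of one locus),
    ``per_chain_cdr3`` (distinct (locus, CDR3) species over both loci) and
    ``clonotype`` (paired clonotypes, cell weighted).
    """
    if entity not in DIVERSITY_ENTITIES:
        raise ValueError(f"unknown diversity entity {entity!r}")
    if entity == "clonotype":
        clonotypes, _ = assemble_clonotypes(records)
        if not clonotypes:
            raise ValueError("no paired cells to compute clonotype diversity")
        return shannon_index([c.n_cells for c in clonotypes])

    weights: Counter = Counter()
    for record in records:
        if entity != "per_chain_cdr3" and locus is not None and record.locus != locus:
            continue
        if entity == "cdr3_aa":
            key = record.junction_aa
        elif entity == "vj_pair":
            key = (record.v_call, record.j_call)
        else:
            key = (record.locus, record.junction_aa)
        weights[key] += _record_weight(record, weight_basis)
    if not weights:
        raise ValueError("no records for requested entity/locus")
    return shannon_index(list(weights.values()))
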