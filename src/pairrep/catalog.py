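"""Germline TCR V/J segment catalog with IMGT functionality classes.

The human TRA and TRB loci carry a fixed universe of germline variable (V)
and joining (J) gene segments.  IMGT classifies each segment as functional,
pseudogene, or ORF (open reading frame: intact coding region but defective
splicing/recombination/regulatory signals).  Repertoire frequency statistics
are conventionally computed over the functional segments only, so the
catalog provides the exclusion filter applied before any counting.

Segment names come in a long IMGT form ("TRAV12-1") and a short form
("AV12-1") common in print; both are accepted and canonicalized to the long
form.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

FUNCTIONALITY_CLASSES = ("functional", "pseudogene", "ORF")

#: accepted spellings -> canonical functionality label
_FUNCTIONALITY_ALIASES = {
    "functional": "functional",
    "f": "functional",
    "pseudogene": "pseudogene",
    "p": "pseudogene",
    "orf": "ORF",
}

_NAME_RE = re.compile(r"^(TR)?([AB])([VJ])(\S+)$")
_BARE_RE = re.compile(r"^([VJ])(\S+)$")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent segment catalogs."""


def normalize_segment_name(
    name: str, locus: str | None = None, segment_type: str | None = None
) -> str:
    """Canonicalize a segment name to the long IMGT form.

    Accepts ``TRAV12-1`` (long), ``AV12-1`` (short) and, when ``locus`` is
    given, the bare table form ``V12-1``/``J43``.  Idempotent.  Raises
    :class:`CatalogError` for names that cannot be interpreted or that
    contradict an explicitly supplied locus/segment type.
    """
    name = name.strip()
    m = _NAME_RE.match(name)
    if m:
        _, chain, stype, rest = m.groups()
        parsed_locus = "TRA" if chain == "A" else "TRB"
        canonical = f"TR{chain}{stype}{rest}"
    else:
        m = _BARE_RE.match(name)
        if m and locus in ("TRA", "TRB"):
            stype, rest = m.groups()
            parsed_locus = locus
            canonical = f"{locus}{stype}{rest}"
        else:
            raise CatalogError(f"unparseable segment name: {name!r}")
    if locus is not None and locus != parsed_locus:
        raise CatalogError(f"segment {name!r} is not on locus {locus}")
    if segment_type is not None and segment_type != stype:
        raise CatalogError(f"segment {name!r} is not a {segment_type} segment")
    return canonical


def parse_segment_name(name: str) -> tuple[str, str, str]:
    """Return ``(canonical_name, locus, segment_type)`` for a segment name."""
    canonical = normalize_segment_name(name)
    locus = "TRA" if canonical[2] == "A" else "TRB"
    return canonical, locus, canonical[3]


@dataclass(frozen=True)
class GeneSegment:
    """One germline V or J gene segment with its IMGT functionality class."""

    name: str
    locus: str
    segment_type: str
    functionality: str

    def __post_init__(self) -> None:
        canonical, locus, stype = parse_segment_name(self.name)
        if canonical != self.name:
            object.__setattr__(self, "name", canonical)
        if locus != self.locus or stype != self.segment_type:
            raise CatalogError(
                f"segment {self.name!r} inconsistent with "
                f"locus={self.locus} segment_type={self.segment_type}"
            )
        if self.functionality not in FUNCTIONALITY_CLASSES:
            raise CatalogError(
                f"unknown functionality {self.functionality!r} for {self.name}"
            )


@dataclass
class SegmentCatalog:
    """An ordered collection of :class:`GeneSegment` with fast lookup."""

    segments: list[GeneSegment]
    source_label: str = ""
    _index: dict[tuple[str, str, str], GeneSegment] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for seg in self.segments:
            key = (seg.locus, seg.segment_type, seg.name)
            if key in self._index:
                raise CatalogError(
                    f"duplicate segment {seg.name!r} within "
                    f"({seg.locus}, {seg.segment_type})"
                )
            self._index[key] = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, name: str) -> bool:
        try:
            canonical, locus, stype = parse_segment_name(name)
        except CatalogError:
            return False
        return (locus, stype, canonical) in self._index

    def functionality(self, name: str) -> str:
        canonical, locus, stype = parse_segment_name(name)
        try:
            return self._index[(locus, stype, canonical)].functionality
        except KeyError:
            raise KeyError(f"segment {canonical!r} not in catalog") from None

    def segments_for(self, locus: str, segment_type: str) -> list[GeneSegment]:
        """Segments of one locus and type, in catalog order."""
        return [
            s
            for s in self.segments
            if s.locus == locus and s.segment_type == segment_type
        ]

    def names(
        self,
        locus: str,
        segment_type: str,
        keep: Iterable[str] | None = None,
    ) -> list[str]:
        """Segment names of one locus/type, optionally functionality-filtered."""
        keep_set = None if keep is None else set(keep)
        return [
            s.name
            for s in self.segments_for(locus, segment_type)
            if keep_set is None or s.functionality in keep_set
        ]

    def validate(self) -> None:
        """Check each present locus has a functional V and a functional J."""
        if not self.segments:
            raise CatalogError("catalog contains no segments")
        for locus in sorted({s.locus for s in self.segments}):
            for stype in ("V", "J"):
                if not any(
                    s.functionality == "functional"
                    for s in self.segments_for(locus, stype)
                ):
                    raise CatalogError(
                        f"catalog has no functional {stype} segment on {locus}"
                    )


def load_catalog(path, source_label: str | None = None) -> SegmentCatalog:
    """Load a segment catalog from a delimited text file.

    The file needs (at least) ``name`` and ``functionality`` columns; locus
    and segment type are inferred from each name.  Short-form names are
    canonicalized.  Comment lines starting with ``#`` are ignored.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        raise CatalogError(f"catalog file {path} is empty or undelimited") from None
    missing = {"name", "functionality"} - set(df.columns)
    if missing:
        raise CatalogError(f"catalog file missing column(s): {sorted(missing)}")

    segments: list[GeneSegment] = []
    for row_no, (name, func) in enumerate(
        zip(df["name"], df["functionality"]), start=2
    ):
        func_label = _FUNCTIONALITY_ALIASES.get(str(func).strip().lower())
        if func_label is None:
            raise CatalogError(
                f"line {row_no}: unknown functionality label {func!r}"
            )
        try:
            canonical, locus, stype = parse_segment_name(str(name))
        except CatalogError as exc:
            raise CatalogError(f"line {row_no}: {exc}") from None
        segments.append(GeneSegment(canonical, locus, stype, func_label))

    catalog = SegmentCatalog(segments, source_label or str(path))
    catalog.validate()
    return catalog


def default_catalog() -> SegmentCatalog:
    """The bundled human TRA/TRB segment catalog."""
    ref = resources.files("pairrep.data").joinpath("imgt_fixture.tsv")
    with ref.open("r") as handle:
        return load_catalog(io.StringIO(handle.read()), source_label="bundled")


def filter_segments(catalog: SegmentCatalog, keep: set[str]) -> SegmentCatalog:
    """Catalog restricted to segments whose functionality is in ``keep``."""
    if not keep:
        raise CatalogError("keep must name at least one functionality class")
    unknown = set(keep) - set(FUNCTIONALITY_CLASSES)
    if unknown:
        raise CatalogError(f"unknown functionality class(es): {sorted(unknown)}")
    kept = [s for s in catalog.segments if s.functionality in keep]
    return replace(catalog, segments=kept)


def possible_recombinants(n_v: int, n_j: int) -> int:
    """Size of the V-J pairing space: every kept V with every kept J.

    With 41 functional TRAV and 50 functional TRAJ this gives the 2050
    possible alpha-chain recombinants; 50 TRBV with 13 TRBJ gives 650.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("segment counts must be positive")
    return int(n_v) * int(n_j)
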