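"""Synthetic paired single-cell TCR + expression data with known ground truth.

The generator emulates the structure of a microwell-based targeted
single-cell capture: ~1e4 PBMC-derived cells per sample, each carrying one
paired alpha/beta clonotype drawn from a clone-frequency law, UMI-collapsed
molecule counts per chain, a ~100-gene targeted expression panel with
marker genes (CD8A, FOXP3) positive in configurable cell fractions, and
optional planted log2 fold-change effects for case samples.

Every draw flows from ``SimConfig.seed``, so outputs are pure functions of
the configuration.  Ground truth (clone frequencies and identities, the
exact Shannon index of the clone law, marker-positive cell sets, realized
segment-usage profiles, planted effects) is emitted alongside the data for
parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import SegmentCatalog, default_catalog
from .io import ChainRecord, ExpressionMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: targeted T-cell panel: cytotoxicity/activation signature, lineage and
#: marker genes commonly read out in this setting
SIGNATURE_GENES = (
    "PRF1", "GZMH", "ITGB2", "NKG7", "CTSW", "CST7", "SELL", "SELPLG",
    "GNLY", "CX3CR1", "CD4", "CD5", "CD7", "CD27", "CD69", "IL32",
    "HLA-A", "HLA-DMA", "IL4R", "TNFRSF4", "LIF", "TRIB2", "PRDM1",
    "FOXP3", "CD8A",
)

#: segments given extra mass in the default usage profiles, mirroring the
#: dominant sets seen in peripheral-blood alpha/beta repertoires
DOMINANT_SEGMENTS = {
    ("TRA", "V"): ("TRAV9-2", "TRAV12-1", "TRAV12-3", "TRAV13-1", "TRAV17"),
    ("TRA", "J"): ("TRAJ9", "TRAJ20", "TRAJ29", "TRAJ34", "TRAJ49"),
    ("TRB", "V"): ("TRBV5-1", "TRBV7-2", "TRBV20-1", "TRBV28", "TRBV29-1"),
    ("TRB", "J"): ("TRBJ1-1", "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-7"),
}


@dataclass
class SimConfig:
    """Study-condition parameters of one simulated sample."""

    n_cells: int = 10_000
    n_clones: int = 200
    clone_law: tuple = ("dirichlet", 1.0)  # or ("geometric", rate)
    v_usage: dict | None = None  # locus -> {segment: prob}; default profiles
    j_usage: dict | None = None
    cdr3_length_range: tuple[int, int] = (8, 20)
    marker_positive_fraction: dict = field(
        default_factory=lambda: {"CD8A": 0.25, "FOXP3": 0.05}
    )
    nested_marker_clone_fraction: dict = field(default_factory=dict)
    marker_count_mean: float = 3.0
    marker_count_dispersion: float = 2.0
    background_mean: float = 2.0
    background_dispersion: float = 2.0
    n_genes: int = 100
    de_log_fc: dict = field(default_factory=dict)
    chain_dropout: float = 0.0
    mean_extra_molecules: float = 2.0  # molecule count per chain = 1 + Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_clones < 1:
            raise ValueError("n_cells and n_clones must be positive")
        if not 0 <= self.chain_dropout < 1:
            raise ValueError("chain_dropout must be in [0, 1)")
        for marker, frac in self.marker_positive_fraction.items():
            if not 0 < frac < 1:
                raise ValueError(f"marker fraction for {marker} must be in (0,1)")
        lo, hi = self.cdr3_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid cdr3_length_range")


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated sample."""

    clone_frequencies: np.ndarray
    clone_identities: list[tuple]
    true_shannon: float
    cell_subset_labels: dict
    de_log_fc: dict
    cell_ids: list[str]
    cell_clone: np.ndarray
    v_usage_realized: dict
    j_usage_realized: dict


def panel_genes(n_genes: int = 100) -> list[str]:
    """Panel gene identifiers: the named signature plus filler genes."""
    if n_genes < len(SIGNATURE_GENES):
        raise ValueError(f"panel needs at least {len(SIGNATURE_GENES)} genes")
    filler = [f"PANEL{i:03d}" for i in range(n_genes - len(SIGNATURE_GENES))]
    return list(SIGNATURE_GENES) + filler


def default_usage_profile(
    catalog: SegmentCatalog,
    locus: str,
    segment_type: str,
    dominant_mass: float = 0.5,
) -> dict[str, float]:
    """Skewed usage profile over the functional segments of one locus.

    The locus's dominant set shares ``dominant_mass`` uniformly; remaining
    functional segments share the rest uniformly.
    """
    names = catalog.names(locus, segment_type, keep={"functional"})
    dominant = [g for g in DOMINANT_SEGMENTS.get((locus, segment_type), ())
                if g in names]
    rest = [g for g in names if g not in dominant]
    profile: dict[str, float] = {}
    for g in dominant:
        profile[g] = dominant_mass / len(dominant)
    mass_rest = 1.0 - (dominant_mass if dominant else 0.0)
    for g in rest:
        profile[g] = mass_rest / len(rest)
    return {g: profile[g] for g in names}


def _clone_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    law, param = config.clone_law
    if law == "dirichlet":
        freqs = rng.dirichlet(np.full(config.n_clones, float(param)))
    elif law == "geometric":
        freqs = (1.0 - param) ** np.arange(config.n_clones)
        freqs = freqs / freqs.sum()
    else:
        raise ValueError(f"unknown clone law {law!r}")
    return np.sort(freqs)[::-1]


def _draw_cdr3(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _draw_identity(rng, profiles, length_range) -> tuple:
    (va, pa), (ja, qa) = profiles["TRA_V"], profiles["TRA_J"]
    (vb, pb), (jb, qb) = profiles["TRB_V"], profiles["TRB_J"]
    return (
        va[rng.choice(len(va), p=pa)],
        _draw_cdr3(rng, length_range),
        ja[rng.choice(len(ja), p=qa)],
        vb[rng.choice(len(vb), p=pb)],
        _draw_cdr3(rng, length_range),
        jb[rng.choice(len(jb), p=qb)],
    )


def simulate_repertoire(
    config: SimConfig, catalog: SegmentCatalog | None = None
) -> tuple[list[ChainRecord], SimTruth]:
    """Simulate one sample's paired chain records plus ground truth.

    Each clone carries a fixed paired identity (V/J drawn once per clone
    from the usage profiles, CDR3 letters uniform at a sampled length;
    identities never collide).  Each cell draws a clone from the clone
    frequencies; per-chain molecule counts are 1 + Poisson; chains drop out
    independently with ``chain_dropout``.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )

    freqs = _clone_frequencies(config, rng)

    profiles = {}
    for locus in ("TRA", "TRB"):
        for stype, override in (("V", config.v_usage), ("J", config.j_usage)):
            prof = (override or {}).get(locus) if override else None
            if prof is None:
                prof = default_usage_profile(catalog, locus, stype)
            names = list(prof)
            probs = np.asarray([prof[g] for g in names], dtype=float)
            if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
                raise ValueError(f"{locus}{stype} usage profile must sum to 1")
            profiles[f"{locus}_{stype}"] = (names, probs)

    identities: list[tuple] = []
    seen: set[tuple] = set()
    for _ in range(config.n_clones):
        identity = _draw_identity(rng, profiles, config.cdr3_length_range)
        while identity in seen:
            identity = _draw_identity(rng, profiles, config.cdr3_length_range)
        seen.add(identity)
        identities.append(identity)

    n = config.n_cells
    cell_ids = [f"cell{i:06d}" for i in range(n)]
    cell_clone = rng.choice(config.n_clones, size=n, p=freqs)
    mol = {
        locus: 1 + rng.poisson(config.mean_extra_molecules, size=n)
        for locus in ("TRA", "TRB")
    }
    dropped = {
        locus: rng.random(n) < config.chain_dropout for locus in ("TRA", "TRB")
    }

    records: list[ChainRecord] = []
    for i, cid in enumerate(cell_ids):
        tra_v, cdr3_a, tra_j, trb_v, cdr3_b, trb_j = identities[cell_clone[i]]
        if not dropped["TRA"][i]:
            records.append(ChainRecord(cid, "TRA", tra_v, tra_j, cdr3_a,
                                       int(mol["TRA"][i])))
        if not dropped["TRB"][i]:
            records.append(ChainRecord(cid, "TRB", trb_v, trb_j, cdr3_b,
                                       int(mol["TRB"][i])))

    subset_labels: dict[str, set[str]] = {}
    for marker in sorted(config.marker_positive_fraction):
        frac = config.marker_positive_fraction[marker]
        nested = config.nested_marker_clone_fraction.get(marker)
        if nested is None:
            positive = rng.random(n) < frac
        else:
            k = max(1, math.ceil(nested * config.n_clones))
            eligible = cell_clone < k
            n_eligible = int(eligible.sum())
            p_eff = min(1.0, frac * n / max(n_eligible, 1))
            positive = eligible & (rng.random(n) < p_eff)
        subset_labels[marker] = {cid for cid, pos in zip(cell_ids, positive)
                                 if pos}

    v_real = {locus: _realized_usage(identities, freqs, locus, "V")
              for locus in ("TRA", "TRB")}
    j_real = {locus: _realized_usage(identities, freqs, locus, "J")
              for locus in ("TRA", "TRB")}

    truth = SimTruth(
        clone_frequencies=freqs,
        clone_identities=identities,
        true_shannon=float(-(freqs * np.log(freqs)).sum()),
        cell_subset_labels=subset_labels,
        de_log_fc=dict(config.de_log_fc),
        cell_ids=cell_ids,
        cell_clone=cell_clone,
        v_usage_realized=v_real,
        j_usage_realized=j_real,
    )
    return records, truth


def _realized_usage(identities, freqs, locus, segment_type) -> dict[str, float]:
    """Clone-frequency-weighted segment usage induced by the drawn identities."""
    slot = {("TRA", "V"): 0, ("TRA", "J"): 2, ("TRB", "V"): 3,
            ("TRB", "J"): 5}[(locus, segment_type)]
    usage: dict[str, float] = {}
    for identity, p in zip(identities, freqs):
        usage[identity[slot]] = usage.get(identity[slot], 0.0) + float(p)
    return usage


def _nb(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Negative binomial with the (mean, dispersion=size r) parameterization."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_expression(
    config: SimConfig,
    cells: list[str],
    truth: SimTruth,
    case: bool = False,
) -> ExpressionMatrix:
    """Simulate the targeted expression panel for the given cells.

    Marker genes are positive (count >= 1) in exactly the truth-labelled
    cells and zero elsewhere.  Background genes draw negative-binomial
    counts around a common mean; for a case sample each gene's mean is
    scaled by 2**de_log_fc[gene].
    """
    # stream does not depend on `case`: with no planted effects a case
    # sample is byte-identical to its control
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
    )
    genes = panel_genes(config.n_genes)
    n = len(cells)

    means = np.full(len(genes), config.background_mean)
    if case:
        for gene, lfc in config.de_log_fc.items():
            if gene in genes:
                means[genes.index(gene)] *= 2.0 ** lfc
    counts = _nb(rng, means[None, :], config.background_dispersion,
                 (n, len(genes)))

    for marker in sorted(config.marker_positive_fraction):
        if marker not in genes:
            continue
        col = genes.index(marker)
        counts[:, col] = 0
        labelled = truth.cell_subset_labels.get(marker, set())
        positive = np.array([c in labelled for c in cells])
        n_pos = int(positive.sum())
        if n_pos:
            extra_mean = max(config.marker_count_mean - 1.0, 1e-9)
            counts[positive, col] = 1 + _nb(
                rng, extra_mean, config.marker_count_dispersion, (n_pos,)
            )
    return ExpressionMatrix(list(cells), genes, counts.astype(np.int64))


def true_shannon(truth: SimTruth) -> float:
    """Exact Shannon index of the configured clone-frequency law."""
    p = np.asarray(truth.clone_frequencies)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def truth_to_dict(truth: SimTruth) -> dict:
    """JSON-serializable view of the ground truth."""
    return {
        "clone_frequencies": [float(x) for x in truth.clone_frequencies],
        "clone_identities": [list(t) for t in truth.clone_identities],
        "true_shannon": truth.true_shannon,
        "cell_subset_labels": {
            m: sorted(cells) for m, cells in truth.cell_subset_labels.items()
        },
        "de_log_fc": truth.de_log_fc,
        "cell_clone": [int(x) for x in truth.cell_clone],
        "v_usage_realized": truth.v_usage_realized,
        "j_usage_realized": truth.j_usage_realized,
    }


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable echo of a configuration."""
    out = dataclasses.asdict(config)
    out["clone_law"] = list(out["clone_law"])
    out["cdr3_length_range"] = list(out["cdr3_length_range"])
    return out


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as handle:
        json.dump(truth_to_dict(truth), handle, indent=1, sort_keys=True)
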