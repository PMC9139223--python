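# Methods

## Scope and model

`pairrep` computes repertoire statistics for paired single-cell alpha/beta
T-cell receptor (TCR) data of the kind produced by microwell-based targeted
single-cell assays: per cell, the V and J germline segment calls and the
CDR3 amino-acid junction of the TRA and TRB chains, with UMI-collapsed
molecule counts, plus a targeted cell x gene UMI count matrix.

The statistics are:

- **Segment usage.** For one locus and segment type, the percentage of the
  weighted chain total attributed to each germline segment. Only segments
  whose IMGT functionality class is in the `keep` set (default
  `{functional}`) enter numerator or denominator; kept segments never
  observed appear with 0%. An optional `min_count` threshold additionally
  drops weakly observed segments (the data-dependent "low-expressed"
  exclusion); its default of 0 drops nothing, because no principled
  threshold exists a priori.
- **V-J pairing.** The same percentages over the full kept V x kept J
  product space of one locus. The matrix has exactly
  `possible_recombinants(n_V, n_J) = n_V * n_J` cells, and its row/column
  sums equal the V/J usage vectors whenever the data contains no excluded
  segments (exact conservation by construction; with excluded segments
  present, usage counts a chain when its *own* segment is kept while the
  pairing matrix needs both ends kept, so the marginals can differ — this
  is documented rather than hidden).
- **Clonotypes.** Per cell, the TRA and the TRB chain with the largest
  molecule count are selected (ties: lexicographically smallest
  junction, then V call — deterministic, and biased toward no call
  preference). The paired clonotype is the 6-tuple
  (TRAV, CDR3a, TRAJ, TRBV, CDR3b, TRBJ). Cells lacking either locus are
  reported as unpaired and excluded from the frequency denominator;
  report tables round frequencies to one decimal but internal values are
  full precision.
- **Shannon diversity.** H' = -sum p_i ln p_i over a configurable
  repertoire entity: per-locus CDR3 amino-acid species (default), V-J
  pairs, paired clonotypes (cell-weighted), or per-chain CDR3 species
  pooled over loci. The entity is configurable because published
  whole-repertoire H' values often exceed ln(cell count), implying a
  finer species definition than the clonotype; `pairrep` therefore
  reports H' per entity instead of privileging one.
- **Subset gating.** A cell is marker-positive when it carries at least
  `min_umi` (default 1) raw UMIs of the marker gene. Gating uses raw
  counts deliberately: the rule is a copy-number threshold, not an
  expression-level one. Cells gated on FOXP3 are labelled "FOXP3+ T
  cells", not regulatory T cells, since a single FOXP3 UMI can also mark
  activated conventional T cells.
- **Fold-change ranking.** Each cell is normalized to counts-per-10k
  (the natural scale of a ~100-gene targeted panel); gene means over the
  gated cells of a sample and a reference are compared as
  `log2(mean_s + c) - log2(mean_r + c)` with pseudocount `c = 1`.
  Computing the difference of logs (not the log of the ratio) makes
  swapping sample and reference negate every value bit-exactly. No
  p-values are attached: the output is a ranking statistic for top-k /
  bottom-k reports.

## Upstream molecule handling

Reads with identical cell label, UMI and gene fold into one molecule
(`fold_molecules`). Before folding, `collapse_umis_hamming1` optionally
merges, within each (cell, gene) group, any UMI at Hamming distance 1 of a
strictly more-abundant UMI into that UMI (directional merge, most-abundant
absorber first, ties never merged, repeated to a fixpoint so the operation
is idempotent). This is a deliberately simple stand-in for vendor
substitution-error correction, whose exact algorithm is proprietary;
distribution-based correction of amplification noise is not implemented,
and molecule counts in input files are taken as given.

## Segment catalog

The germline segment universe ships as an editable two-column fixture
(name, functionality) because IMGT functionality assignments change across
releases. Short print forms ("AV12-1") and long forms ("TRAV12-1") both
parse; bare table forms ("V27") parse when the locus is supplied.
Segments observed in data but absent from the catalog are retained as
functional with a logged warning, so catalog drift degrades loudly rather
than silently dropping data.

## The simulator and what passing tests show

`simulate_repertoire` emulates the *structure* of a targeted single-cell
capture, with defaults chosen as one plausible study condition:

- `n_cells = 10_000` (a typical per-sample capture), `n_clones = 200`;
- clone frequencies from a symmetric Dirichlet (default alpha = 1) or a
  geometric law;
- one fixed paired identity per clone: V and J drawn once per clone from
  skewed usage profiles (a 5-segment dominant set holding 50% of the mass,
  matching the strongly non-uniform usage seen in peripheral blood), CDR3
  letters uniform over the 20 amino acids at a length uniform in 8-20.
  Identities are rejection-sampled to never collide, so the clone law's
  entropy is exactly the clonotype entropy;
- per-chain molecule counts 1 + Poisson(2); independent per-chain dropout;
- marker-positive cells drawn per cell (CD8A 25%, FOXP3 5% by default),
  optionally *nested* — positive cells restricted to the top fraction of
  clones — which reproduces the characteristic diversity ordering
  H'(FOXP3+) < H'(CD8+) < H'(bulk) of real subsets;
- a 100-gene panel with negative-binomial background counts (mean 2,
  dispersion 2), marker genes >= 1 UMI in exactly the labelled cells, and
  per-gene means scaled by 2^log2FC in case samples.

All draws derive from one seed; outputs are pure functions of the
configuration. Because clone identities draw V/J once per clone, the
empirical segment usage converges (in cells) to the *realized*
clone-frequency-weighted usage, which the ground truth records — not to
the drawing profile, whose recovery would require many clones rather than
many cells. Recovery tests therefore compare against the realized
profiles.

The simulator does not emulate: sequencing error beyond UMI substitution,
doublets, ambient RNA, cross-platform batch effects, biophysically
realistic CDR3 composition, or allele-level segment resolution. Passing
recovery tests therefore demonstrates correctness of the counting,
gating, diversity and ranking machinery under the stated generative
model, not robustness to those real-data artifacts.

## Numerical choices

- Shannon index via `scipy.stats.entropy` on the positive entries
  (input normalized internally); tests check agreement with independent
  `math.fsum` summation to 1e-12 and the exact ln S value on uniform
  inputs up to S = 1e5.
- Frequency tables are full precision; only report tables round.
- Percent tables sum to 100 within 1e-6 whenever any observation exists.
- Degenerate inputs error loudly: empty catalogs, all-zero count vectors,
  empty gated subsets, zero-total cells (dropped with a logged count in
  normalization; an error if all cells are zero).
- Ties everywhere (chain selection, clonotype ranking, fold-change
  ranking, UMI merging) break lexicographically, never by input order.

## Problem sizes in the shipped checks

The bundled end-to-end checks run at 50 000 cells / 200 clones for entropy
and usage recovery (plug-in entropy bias ~ (S-1)/2n ≈ 0.002, well inside
the 0.05 acceptance margin), 5 000 cells for gating recovery, 2 000 cells
per side for fold-change rank recovery with planted |log2FC| = 2, and
8 000 cells for the nested-subset diversity ordering. These sizes were
chosen so each statistical check has generous margin over its sampling
noise while the whole suite stays interactive.

## Known limitations

- No repertoire overlap/similarity metrics between samples; no clonal
  expansion statistics beyond frequency ranking.
- Published whole-repertoire diversity values from proprietary upstream
  pipelines are not numerically reproducible here: they depend on an
  unstated species definition and on vendor error-correction internals.
  The package reports H' per entity and reproduces the qualitative
  subset ordering instead.
- The fold-change ranking makes no cross-platform or batch correction
  claim; comparing samples from different chemistries remains the
  caller's responsibility.
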