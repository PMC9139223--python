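# pairrep

Paired single-cell T-cell receptor (TCR) repertoire statistics for
alpha/beta chain data from targeted single-cell assays, with a
ground-truth simulator for end-to-end validation.

Single-cell V(D)J capture recovers, for each cell, the germline V and J
segment calls and the CDR3 amino-acid junction of the TRA and TRB chains,
alongside a targeted cell x gene UMI count matrix. `pairrep` turns those
into the standard repertoire readouts:

- **Segment usage** — percentage frequency of each germline V or J segment
  over the IMGT-functional segment universe (pseudogenes and ORFs excluded
  from numerator and denominator by default);
- **V-J pairing matrices** — the same frequencies over the full
  `n_V x n_J` recombination space of a locus (41 functional TRAV x
  50 TRAJ = 2050 alpha recombinants; 50 TRBV x 13 TRBJ = 650 beta);
- **Paired clonotypes** — per cell, the dominant TRA and TRB chain form
  the 6-tuple (TRAV, CDR3a, TRAJ, TRBV, CDR3b, TRBJ); clonotypes are
  ranked by cell frequency as top-10 style tables;
- **Shannon diversity** — H' = -Σ p_i ln p_i over a configurable
  repertoire entity (per-locus CDR3 species, V-J pairs, or paired
  clonotypes), for the bulk sample and for marker-gated subsets;
- **Marker gating** — CD8+/FOXP3+ subsets defined as cells with ≥ 1 raw
  UMI of the marker gene;
- **Fold-change ranking** — genes of a gated subset ranked against the
  same subset of a reference sample by
  `log2((mean_cp10k + 1) / (mean_cp10k,ref + 1))`, reported as top/bottom
  blocks.

Upstream helpers fold reads into molecules (distinct cell/gene/UMI
triples) and apply a directional Hamming-1 UMI merge. A simulator
generates paired repertoires and expression panels from a known
clone-frequency law so every stage is testable without external data.

## Worked example

```python
import numpy as np
import pairrep as pr
from pairrep.gating import GateDefinition, gate_cells, subset_diversity

cfg = pr.SimConfig(n_cells=2000, n_clones=50, seed=7,
                   nested_marker_clone_fraction={"CD8A": 0.5, "FOXP3": 0.1})
records, truth = pr.simulate_repertoire(cfg)
catalog = pr.default_catalog()

usage = pr.segment_usage(records, "TRA", "V", catalog)
for i in np.argsort(usage.percent)[::-1][:5]:
    print(f"{usage.labels[i]}\t{usage.percent[i]:.2f}")

clonotypes, unpaired = pr.assemble_clonotypes(records)
print(pr.clonotype_table(clonotypes, 3).to_string(index=False))

expr = pr.simulate_expression(cfg, truth.cell_ids, truth)
bulk = subset_diversity(records, set(truth.cell_ids), locus="TRA")
cd8 = subset_diversity(records, gate_cells(expr, GateDefinition("CD8A")), locus="TRA")
fox = subset_diversity(records, gate_cells(expr, GateDefinition("FOXP3")), locus="TRA")
print(f"H' TRA bulk={bulk:.3f} CD8A+={cd8:.3f} FOXP3+={fox:.3f}")
```

prints

```
TRAV9-2	28.44
TRAV12-3	19.32
TRAV13-1	9.83
TRAV12-1	8.16
TRAV10	4.82
 clone_rank  frequency_percent  n_cells     TRAV       CDR3_TRA   TRAJ     TRBV      CDR3_TRB    TRBJ
          1               12.2      244  TRAV9-2  HHSSLEEKICDVT TRAJ38   TRBV27 DRFSRCIGVSEGI TRBJ2-2
          2                8.7      174 TRAV13-1 AFWYEVSHNLTNGF TRAJ49  TRBV5-1     HMDFSDLAH TRBJ2-3
          3                5.3      106  TRAV9-2   LYSFPYCFRECK TRAJ47 TRBV20-1 TNGDVAWHILKHR TRBJ2-6
H' TRA bulk=3.450 CD8A+=2.959 FOXP3+=1.522
```

The usage table shows the dominant TRAV segments of the simulated sample
(the generator skews usage toward a 5-segment dominant set, as real
peripheral-blood repertoires do). The clonotype table mirrors the usual
top-10 report: the largest clone holds 12.2% of the 2000 paired cells.
The diversity line shows the nested-subset ordering
H'(FOXP3+) < H'(CD8+) < H'(bulk): the marker-positive subsets were drawn
from progressively fewer clones, and the bulk plug-in estimate 3.450 sits
next to the exact clone-law entropy 3.458.

## Command line

```sh
pairrep simulate --seed 7 --out-dir sim/           # AIRR TSV + .mtx + truth.json
pairrep usage sim/rearrangements.tsv --locus TRA --segment V
pairrep pairing sim/rearrangements.tsv --locus TRB
pairrep clonotypes sim/rearrangements.tsv --top 10
pairrep diversity sim/rearrangements.tsv --entity clonotype
pairrep gate --matrix sim/expression.mtx --cells sim/cells.txt \
             --genes sim/genes.txt --marker FOXP3 --out foxp3_cells.txt
pairrep de --sample case.mtx ... --ref ctrl.mtx ... --gate FOXP3:1 --top 10
pairrep report --config run.yaml                   # full report bundle
```

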