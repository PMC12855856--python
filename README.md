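# rmsfnet

Dynamic residue-coupling networks from per-residue RMSF of paired molecular
dynamics trajectories, with application to the peptide–MHC (pMHC) interface.

## The problem

When a presented peptide is perturbed — e.g. a valine→proline substitution at
peptide position 3 of an MHC class-I epitope — the change in dynamics is not
confined to the mutated residue: fluctuations can propagate through the
binding-groove helices to distant positions that contact the T cell receptor.
`rmsfnet` detects such long-range coupled dynamics from an ensemble of paired
MD trajectories (each crystallographic copy simulated under both peptide
conditions) using only per-residue RMSF magnitudes, and encodes them as a
biophysically validated residue network.

## The method

1. **Coupling statistics.** For every residue pair, the Spearman rank
   correlation ρ_s of per-residue RMSF across all n trajectories is converted
   to t = ρ_s·√((n−2)/(1−ρ_s²)) and assessed two-tailed against a permutation
   null built from pseudo-randomly paired resamples of two sequential integer
   arrays 1..n. P-values are Benjamini–Hochberg adjusted (FDR 5%); couplings
   additionally require |ρ_s| ≥ 0.5. Per-residue condition effects are tested
   with an exact paired Wilcoxon signed-rank test, and a rank-biserial
   correlation screens residues whose RMSF tracks immunogenicity.
2. **Network construction.** Significant couplings whose Cα distance r_Cα
   (from a reference crystal structure) is below a threshold t become edges
   with weight E[u,v,n,t] = |ρ_s[u,v]| / r_Cα[u,v]^n. A 2D scan over (n, t)
   is validated with shortest-path metrics F1/F2/F3 (fractions of Dijkstra
   shortest paths that take geometrically implausible detours) and the
   largest-connected-component fraction; the chosen network minimizes F1 at
   LCC > 90% with the lowest weight complexity.
3. **Topology.** Degree, betweenness, closeness, eigenvector centrality and
   coreness; shortest-path maps from a focal residue; consensus Louvain
   communities over many independently seeded runs, with per-residue
   community co-occurrence relative to the focal residue.

A synthetic-study generator (`rmsfnet.synthetic`) emulates the paired design
— 13 crystal copies × 2 conditions, planted coupled residue blocks with
signed log-scale effects, idealized two-helix/peptide-strand Cα geometry —
so the whole pipeline is testable without trajectories.

## Worked example

```sh
rmsfnet simulate --out sim --seed 17                   # 26 synthetic RMSF .xvg + structure.pdb
rmsfnet run --manifest sim/manifest.tsv --structure sim/structure.pdb \
    --out analysis --seed 5 --louvain-iterations 1000
```

`analysis/` then contains the correlation matrices (`rho.csv`, `p_adj.csv`),
the volcano table, Wilcoxon and screen reports, the (n, t) scan
(`scan.csv`), the chosen network (`network.graphml`, `network.edges.csv`),
node centralities, shortest-path maps from p3V/P, and community consensus.
On this default synthetic study (seed 1 of the acceptance run) the pipeline
reports, for example:

- `wilcoxon_p_peptide3 = 0.000244` — the planted loss of p3 dynamics under
  proline is detected by the exact paired test at 13 pairs (the minimum
  attainable one-sided p is 1/2¹³ ≈ 0.00012);
- `significant_pair_count = 28` — the strong planted block (p3 + seven
  groove-helix residues, 28 pairs) is flagged; the weak block stays below
  threshold, as designed;
- `recovery_recall_median = 0.93`, `recovery_precision_median = 0.97` —
  pairwise recovery of an 8-residue planted block at log-effect 0.4 and
  noise 0.2 over 25 replicates;
- `null_flagged_fraction_mean = 0.0` — on pure-noise studies essentially no
  pair survives BH at 5%;
- `f1_worked_example = 0.333` — the hand-checkable 3-node F-metric
  construction (F1 = 2/6, F2 = F3 = 1/6).

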