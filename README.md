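# nichescreen

Lineage-resolved ligand–receptor screening for the human blastocyst, as a
tested, reusable Python package.

## The problem

At the blastocyst stage the human embryo contains three lineages — the
pluripotent epiblast (EPI), the primitive endoderm (PE) and the
trophectoderm (TE) — and the signals they exchange define the niche that
maintains the epiblast. Given lineage-labelled single-cell expression data,
which ligand–receptor axes are plausibly active, and between which lineages?
The motivating biological answer is the IGF axis: *IGF1* ligand produced by
the PE signalling to *IGF1R* on the EPI, a paracrine circuit that informed
the design of FGF-free pluripotent culture media. `nichescreen` implements
the computational screen behind that kind of nomination, for anyone who
wants to run it on their own lineage-labelled matrices or to study its
operating characteristics on synthetic data with planted ground truth.

## The method

The screen and its companion analyses:

1. **Ligand–receptor calling.** Curated ligand and receptor lists (as
   extracted from signal-transduction pathway databases) are paired through
   protein–protein interaction evidence (HIPPIE-style scored edges): the
   candidate pairs are `{(ℓ, r) : role(ℓ)=ligand, role(r)=receptor,
   edge(ℓ, r)}`. For each pair and each ordered lineage combination (A, B),
   a call is emitted iff

       median RPKM of ℓ in A ≥ τ  and  median RPKM of r in B ≥ τ,   τ = 5 RPKM

   (boundary inclusive), classed autocrine when A = B. Calls are ranked by a
   specificity score `min(fold(ℓ, A), fold(r, B))` with
   `fold(g, k) = (m_gk + ψ) / (max_{k'≠k} m_gk' + ψ)`, ψ = 1.
2. **Normalisation.** RPKM (`c·10⁹ / (L·T)`), median-of-ratios size factors,
   `log2(x+1)`, per-lineage medians, and Tukey boxplot summaries
   (1.5 IQR whiskers).
3. **Highly variable genes.** A lowess trend fitted to the per-gene
   mean–variance curve of the log matrix is taken as the technical variance;
   `(n−1)·total/trend` is tested against χ²(n−1) with Benjamini–Hochberg
   control at α = 0.01.
4. **Enrichment.** Preranked GSEA on pseudocounted log2 fold changes
   (weighted Kolmogorov–Smirnov running sum, gene-label permutation null,
   NES, pooled-null FDR), hypergeometric over-representation with BH, and an
   enrichment-map style similarity graph (nominal p ≤ 0.05 nodes, overlap
   coefficient ≥ 0.5 edges).
5. **Pathway overlay.** Diagram nodes coloured by `log2(median RPKM + 1)` on
   a fixed 0–15 window in 20 bins; category nodes take the member maximum;
   exports carry per-node bins plus per-member boxplot payloads.
6. **Culture statistics.** Population doublings
   `PDL = log10(N_t / N_{t−1}) / 0.30103`, embryo lineage proportions
   (%NANOG, %SOX17, %ICM = their sum) and a one-tailed two-sample t-test.
7. **Synthetic blastocyst data.** A generator with planted circuits, decoy
   pairs, overdispersed genes and lineage-enriched gene sets, so every stage
   is testable against known truth without downloads.

## Worked example

```python
import nichescreen as ns

config = ns.SimConfig(seed=0)                       # 2000 genes, 3 x 50 cells
counts, lengths, truth = ns.simulate_dataset(config)
medians = ns.lineage_medians(ns.rpkm(counts, lengths))
print(medians.values.loc[["IGF1", "IGF1R"]].round(2))

catalogue, ppi = ns.build_toy_catalogue(truth, config)
pairs = ns.pair_by_ppi(catalogue, ppi)
calls = ns.rank_interactions(ns.call_interactions(pairs, medians, threshold=5.0), medians)
for call in calls[:3]:
    print(f"{call.ligand:>5} -> {call.receptor:<5} {call.source_lineage}->{call.target_lineage} "
          f"({call.interaction_class}), specificity {call.specificity_score:.2f}")
```

prints

```
lineage    EPI     PE    TE
gene
IGF1      0.54  20.45  0.59
IGF1R    10.87   0.51  0.50
 LIGD -> RECD  EPI->EPI (autocrine), specificity 9.44
 IGF1 -> IGF1R PE->EPI (paracrine), specificity 7.88
 LIGE -> RECE  PE->TE (paracrine), specificity 7.32
```

The planted IGF1 ligand is expressed only in the PE (20.45 RPKM, below the
5 RPKM threshold elsewhere) and its receptor only in the EPI, so the screen
emits exactly one directed call for that pair — PE→EPI, paracrine — and all
six planted circuits are recovered with no decoy calls (precision = recall
= 1). The specificity score is the weaker of the ligand's and receptor's
on/off-lineage fold enrichments.

The same pipeline runs end to end from the shell:

```bash
nichescreen run --seed 0 --out results/demo
nichescreen screen --matrix counts.tsv --annotations ann.tsv --lengths len.tsv \
    --catalogue catalogue.tsv --ppi ppi.tsv --threshold 5 --out calls.tsv
```

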