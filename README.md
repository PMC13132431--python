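# cobind

Bin-based co-occupancy analysis of ChIP-seq peak tracks.

`cobind` quantifies how a set of DNA-binding proteins co-localize with
chromatin regulatory complexes across a genome. It was built for studies of
the *Arabidopsis thaliana* TELOMERE REPEAT BINDING FACTOR paralogs
(TRB1–TRB3) and their partner complexes — PEAT (UBP5, EPCR1, PWWP1), NuA4
(HAM1, EPL1B), PRC2 (CLF, SWN) and the JMJ14 demethylase complex — but every
piece (tracks, complex membership rules, bin size, gene models) is
configurable, so it applies to any multi-track peak co-occupancy question.

It is aimed at computational biologists who have peak calls from
heterogeneous ChIP-seq pipelines and want to ask: *which proteins bind
together, where, and does that co-binding explain expression changes?*

## Method

1. **Binning.** The genome is tiled into fixed-width half-open bins
   (default 300 bp). A bin counts as bound by a track if any base of any
   peak overlaps it. Because the tracks come from different pipelines with
   incomparable score scales, each track's scores are rank-normalized into
   deciles 1–10 (0 = unbound):
   decile(b) = ⌈10·r(b)/n⌉ with r the average ascending rank among the n
   bound bins.
2. **Complex assignment.** A bin (or gene) is assigned to a complex when at
   least *m* of its member tracks are bound — any two of the three PEAT
   components, both NuA4 components, both PRC2 components, or JMJ14 alone.
   The assigned subset gives each bin one mutually exclusive category label
   ("PEAT", "JMJ14+PRC2", …, "Unassigned"), alongside its combination of
   bound TRB paralogs.
3. **Exact intersection statistics.** Enrichment of one set of bins/genes
   in another is tested with the exact multi-set intersection test: under
   uniform independent sampling of m sets of sizes n₁…n_m from a background
   of N elements, the intersection size follows the chained hypergeometric
   distribution X₁ = n₁, X_k | X_{k−1}=j ~ Hypergeom(N, j, n_k), computed
   in log space. Fold enrichment is observed / N·∏(n_j/N). For m = 2 this
   is the one-sided Fisher/hypergeometric test. Grids of category ×
   TRB-combination tests are BH-adjusted per grid.
4. **Gene annotation.** Peaks are annotated to every gene whose body they
   overlap (multi-gene spanning peaks map to all spanned genes) plus every
   gene with a TSS within ±2000 bp; gene-level complex assignment reuses
   the bin rules. Any gene→term map can be tested for over-representation
   (one-sided hypergeometric, BH-adjusted).
5. **Expression clustering.** Differentially expressed genes are clustered
   on library-size-scaled, log-transformed, per-gene-centered count
   profiles with PAM (k-medoids, deterministic BUILD + SWAP); k is fixed or
   chosen by mean silhouette. Cluster × complex-category intersections
   reuse the exact test.
6. **Synthetic studies.** A seeded generator plants complex target bins,
   member-track and TRB-preference binding probabilities, gene models,
   negative-binomial counts with five archetype genotype responses, and
   term maps — with full ground truth — so the entire pipeline is testable
   without downloads.

## Worked example

```python
from cobind import (Scenario, simulate, tile_genome, assign_peaks_to_bins,
                    decile_normalize, build_occupancy_matrix, DEFAULT_SCHEME,
                    assign_complexes, categorize, trb_combination,
                    pairwise_grid_tests)

data = simulate(Scenario(seed=1))          # 2-Mb toy genome, 11 tracks
index = tile_genome(data.scenario.layout, data.scenario.bin_size)
deciles = {name: decile_normalize(assign_peaks_to_bins(ps, index))
           for name, ps in data.peaksets.items()}
matrix = build_occupancy_matrix(deciles, index)

cats = categorize(assign_complexes(matrix, DEFAULT_SCHEME))["category"]
trb = trb_combination(matrix)
print(cats.value_counts().head(5))

grid = pairwise_grid_tests(cats, trb)
cell = grid[(grid.label_a == "PRC2") & (grid.label_b == "TRB3")].iloc[0]
print(f"PRC2 x TRB3: observed={cell.observed} expected={cell.expected:.1f} "
      f"fold={cell.fold_enrichment:.2f} p={cell.p_enrichment:.2e}")
```

prints

```
category
Unassigned    5008
PEAT           493
JMJ14          451
PRC2           276
NuA4           253
Name: count, dtype: int64
PRC2 x TRB3: observed=108 expected=17.7 fold=6.10 p=2.61e-60
```

Of the 6668 bins, 276 satisfy the PRC2 rule (both CLF and SWN bound); bins
carrying only TRB3 overlap them 108 times where independence predicts 17.7,
a 6.1-fold enrichment whose exact upper-tail probability is ~10⁻⁶⁰ — the
generator's default scenario plants exactly this TRB3→PRC2 preference.

The same analysis is scriptable from the shell:

```sh
cobind simulate --seed 1 --out study/
cobind run --config run.yaml        # full pipeline + reports
```

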