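# anchorsig

Anchor-gated multi-dataset co-expression meta-analysis.

A recurring strategy for characterizing a poorly understood gene — say an
orphan receptor — is to mine public expression repositories for two-group
studies in which that gene itself moves, and then ask which *other* genes
move with it across many independent datasets. `anchorsig` implements that
strategy as a tested, fully offline pipeline:

1. **Anchor gate** — for each two-group log2 expression dataset, run
   per-gene Welch *t* tests; the dataset contributes its differentially
   expressed (DE) gene list only if the anchor gene is itself significant
   (default α = 0.05) with the required sign of log2 fold change ("up" or
   "down" cohorts are analyzed separately).
2. **Commonality ranking** — tally each gene's membership across the gated
   DE lists into a gene × dataset matrix, rank genes by dataset count
   (ties broken alphabetically), truncate to a top-1000 list, and slice
   the matrix at "common to ≥ k datasets" levels.
3. **Consensus enrichment** — test each commonality slice against a GMT
   collection with the upper-tail hypergeometric test
   `P[X ≥ k]`, `X ~ Hypergeom(N, K, n)`, requiring at least 2 overlapping
   genes and p < 0.05; a pathway is a *consensus* hit when significant at
   ≥ 3 of the 4 levels tested. Benjamini–Hochberg q-values are always
   reported and can drive the significance flag instead.
4. **Reference-set overlap** — intersect the ranked cohort with a
   reference gene set (e.g. a curated aging signature) and compare the
   observed intersection size against `|random set ∩ cohort|` for random
   sets of the same size drawn from the universe, reporting the null
   mean ± SEM, a z-score and the add-one empirical p
   `(1 + #{null ≥ obs}) / (1 + n_perm)`.
5. **PPI subnetwork** — extract the minimum-order connected subnetwork of
   the intersection proteins on an interactome (a node-minimal Steiner
   subgraph: exact search on small components, shortest-path heuristic with
   pruning beyond), cluster the proteins by k-means on a classical-MDS
   embedding of shortest-path distances (default k = 4), and annotate the
   expanded network by the same hypergeometric test.

Because the real inputs of such studies live behind web services, the
package ships a first-class synthetic-data module that generates every
input with planted ground truth — anchor-co-regulated modules, a planted
pathway, a reference set with controlled excess overlap, and an
interactome with planted cliques — so the whole pipeline is testable and
reproducible from a single seed.

## Worked example

```python
import anchorsig as a

module = tuple(f"GM{i+1:03d}" for i in range(30))
spec = a.SimulationSpec(n_genes=2000, module_genes=module, effect_size=2.0,
                        noise_sd=1.0, n_per_group=10, n_datasets=7, seed=42)
gate = a.GateConfig(anchor="GPR19", direction="up", alpha=0.05)

de_lists = {}
for i in range(spec.n_datasets):
    ds = a.generate_dataset(spec, i)
    passed, de = a.gate_and_extract(a.run_de(ds), gate)
    print(f"{ds.dataset_id}: gate {'passed' if passed else 'failed'}, {len(de)} DE genes")
    if passed:
        de_lists[ds.dataset_id] = de

matrix = a.build_matrix(de_lists)
ranked = a.rank_genes(matrix, top_n=1000)
print("genes common to all", len(matrix.datasets), "datasets:",
      a.level_counts(matrix)[len(matrix.datasets)])
print(ranked.table.head(3).to_string(index=False))

coll = a.generate_gmt(spec.genes, 50, (10, 40), module, seed=7)
per_level = {k: a.run_ora(a.slice_at(matrix, k), coll, spec.genes)
             for k in (3, 4, 5, 6)}
for res in a.consensus_over_levels(per_level, min_levels=3):
    if res.consensus:
        print(f"consensus pathway: {res.set_id} "
              f"(significant at levels {list(res.levels_significant)})")
```

prints

```
SIM001: gate passed, 212 DE genes
SIM002: gate passed, 225 DE genes
SIM003: gate passed, 206 DE genes
SIM004: gate failed, 0 DE genes
SIM005: gate passed, 213 DE genes
SIM006: gate passed, 209 DE genes
SIM007: gate passed, 198 DE genes
genes common to all 6 datasets: 28
 gene  count  rank
GM001      6     1
GM003      6     2
GM004      6     3
consensus pathway: PLANTED (significant at levels [3, 4, 5, 6])
```

One of the seven simulated datasets happened to miss the anchor cut and is
gated out (each dataset's anchor reaches significance with probability
equal to the test's power, ≈ 0.99 here), so six datasets contribute. Of the
30 planted module genes, 28 are recovered as DE in *every* contributing
dataset and dominate the top of the ranking, and the planted pathway is the
only consensus enrichment hit at all four commonality levels.

The same analysis runs from the shell against files on disk
(`anchorsig simulate/de/common/ora/consensus/overlap/network`), or as a
single configured run:

```bash
anchorsig run --config run.yaml --out results/
```

which writes `report.json` (deterministic: identical config + seed gives
byte-identical reports), `ranked_genes.tsv`, per-level ORA tables and the
extracted subnetwork as SIF.

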