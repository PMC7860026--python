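# aimpanel

Ancestry-informative SNP panel design and subspecies assignment for
European honey bees (*Apis mellifera*).

European honey bee diversity is structured into four deeply diverged
evolutionary lineages (A, C, M, O) containing at least 14 recently
diverged subspecies. Conservation and breeding programmes need a
reproducible way to (i) pick a small set of ancestry-informative
markers (AIMs) out of millions of variants segregating in
pool-sequenced reference populations, and (ii) assign newly genotyped
individuals to a subspecies — or reject them as *unassigned* when the
evidence is weak. `aimpanel` implements that workflow end to end, plus
a hierarchical simulator so every stage can be exercised and validated
without any external data.

## What it computes

**F_ST branch.** For each SNP and pool pair, the heterozygosity-form
fixation index

F_ST = (H_T − H_S) / H_T, with p̄ = (p₁+p₂)/2, H_T = 2p̄(1−p̄),
H_S = (2p₁(1−p₁) + 2p₂(1−p₂))/2.

For every pool the pairwise values against all other pools are summed
per SNP (a SNP fixed in one pool and absent in the other 21 of a
22-pool design sums to exactly 21), ranked, and the top 20 (loose
filters) plus top 80 (stringent filters) per pool are selected, skipping
SNPs already taken — exactly 2200 SNPs for 22 pools.

**PCA branch.** A scaled PCA of the pools × minor-allele-frequency
matrix, run globally and then within each lineage. SNPs are scored by
their contribution to the significant components
(100·coord²/λ, aggregated over significant PCs by eigenvalue share) and
selected per level under quotas (global 300, M 200, O 600, C 1100).
Merging both branches with deduplication yields 4400 AIMs.

**Assignment.** Panel genotypes are one-hot encoded with an explicit
*missing* state (systematic missingness from null alleles is signal,
not noise), candidate classifiers are compared by stratified 10-fold
cross-validation, and the winner — typically a linear SVC with
cross-validated isotonic calibration — emits per-class probabilities.
Samples whose top probability falls below τ = 0.90 are reported as
`unassigned`.

See `docs/methods.md` for the models, estimators and conventions in
detail.

## Worked example

Simulate the 22-pool / 14-subspecies / 4-lineage reference design,
build a combined panel, train and evaluate:

```python
import aimpanel as ap

cfg = ap.reference_config(n_snps=4000, n_individuals_per_pool=25,
                          quotas={"global": 100, "M": 60, "O": 100, "C": 200})
data = ap.simulate_dataset(cfg, seed=42)

pca = ap.hierarchical_pca_select(data.pool_table, cfg)
fst = ap.select_fst_panel(data.pool_table, k_loose=5, k_stringent=15,
                          exclude=set(pca.snps))
panel = ap.merge_panels(pca, fst)

gm = data.genotypes.subset_snps(panel.snps)
train_ids, test_ids = ap.split_reference(gm.samples, 0.7, seed=42)
train, test = gm.subset_samples(train_ids), gm.subset_samples(test_ids)
model = ap.fit(ap.default_candidates(42)["linear_svc"],
               ap.one_hot_encode(train), train.label_series("subspecies"),
               seed=42, name="linear_svc")
probs = ap.predict_probabilities(model, ap.one_hot_encode(test))
calls = ap.assign(probs, ap.AssignmentConfig(threshold=0.9))
```

Output of the accompanying bookkeeping
(`ap.accuracy_report(ap.confusion(...))`, `ap.call_rate(...)`):

```
panel size: 900 SNPs (460 PCA, 440 F_ST)
median top-class probability: 1.00
test samples: 165, assigned: 165, unassigned: 0
accuracy among assigned: 100.0%
mean call rate: 0.87
```

The panel is exactly the quota arithmetic (460 PCA + 22×20 F_ST); the
held-out subspecies accuracy is perfect on this idealised simulation
(real data adds admixture and label noise; see the methods note); and
the 0.87 call rate reflects the simulated subspecies-specific
null-allele rate of 0.13.

The same pipeline is available from the shell:

```bash
aimpanel simulate --seed 11 --outdir sim/
aimpanel select-fst --freq-table sim/pools.tsv --out fst.tsv
aimpanel select-pca --freq-table sim/pools.tsv --out pca.tsv
aimpanel build-panel --pca pca.tsv --fst fst.tsv --out panel.tsv
aimpanel train --genotypes sim/genotypes.tsv --labels sim/labels.tsv \
               --panel panel.tsv --seed 11 --model-out model.joblib
aimpanel predict --model model.joblib --genotypes sim/genotypes.tsv \
                 --threshold 0.9 --out predictions.tsv
aimpanel evaluate --predictions predictions.tsv --labels sim/labels.tsv \
                  --out report.json
```

Every subcommand writes a `.provenance.json` sidecar with the seed and
a config hash; identical inputs and seeds give byte-identical outputs.

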