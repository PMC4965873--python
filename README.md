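# corecnet

Time-resolved AP-MS interactome analysis: specific-interactor detection,
recruitment kinetics, and co-recruitment correlation networks.

## What this package does

Affinity purification coupled to mass spectrometry (AP-MS) identifies the
proteins (preys) that co-purify with a tagged bait. When pulldowns are
performed at several time points after receptor stimulation — here a
T-cell receptor time course spanning 0–600 s, with bait-tagged and
wild-type control samples, biological and technical replicates — the data
contain two layers of information: *which* preys bind specifically, and
*when* they are recruited. `corecnet` implements both analyses for
label-free protein-group intensity tables (MaxQuant `proteinGroups`
format):

1. **Specific-interactor detection.** After global and per-condition mean
   normalization of log₁₀ intensities and imputation of missing values
   from the wild-type background model, each protein at each time *t* is
   scored by its enrichment
   r(t) = 10^(⟨log I_bait⟩ − ⟨log I_control⟩) and a one-way ANOVA p-value
   P(t) comparing the two run groups. The joint rule *P(t) < P\** and
   *r(t) > r\** (defaults P\* = 10⁻³, r\* = 2) is re-applied over 200
   bootstrap resamples of the run values; *P(Detection)*, the fraction of
   resamples in which a protein passes, must reach 0.9 at some time point
   for the protein to be called a specific interactor.
2. **Co-recruitment networks.** Interactor intensities in bait runs are
   normalized to the bait (constant bait intensity across runs), then each
   biological replicate's series is divided by its maximum-over-time of
   technical-replicate means, giving recruitment profiles in [0, 1]. Every
   pair (i, j) of interactors is scored by the bootstrap-mean Pearson
   coefficient R_ij and p-value P_ij over 1,000 resamples of the paired
   points. Edges of the co-recruitment network are pairs with
   P_ij < α / (N(N−1)/2) (Bonferroni over the N interactors, α = 5×10⁻⁵);
   edges with R > 0.8 form the high-confidence subnetwork. K-means on the
   rows of R partitions the interactors into kinetic modules.
3. **Benchmarking.** Predicted edges are compared against a reference list
   of known physical interactions (two-column or BioGRID tab-delimited):
   precision |predicted ∩ reference| / |predicted|, the random-network
   baseline 2K/(N(N−1)), first-neighbor validation of an anchor node, and
   validation stratified by graph distance.

A fully parameterized synthetic-data generator (`corecnet.synth`)
simulates the whole design — planted preys with module-wise kinetic
profiles, shared module-level recruitment fluctuations, contaminant
background, run-level and protein-level log-normal noise, and
intensity-dependent missingness — so every stage can be validated against
known ground truth.

## Worked example

```python
import corecnet as cn

config = cn.cbl_like_config(seed=1)          # 3 bio x 3 tech, 5 times
table, design, truth = cn.simulate_experiment(config)
ref = cn.truth_reference_list(truth, recall=0.6, seed=2)

result = cn.run_all(cn.PipelineConfig(outdir="demo", kmeans_k=4, seed=1),
                    table=table, design=design, reference=ref)

print("interactors:", len(result.detection.interactors()))
print(result.detection.interactors_per_time().to_string())
net = result.network
print("network nodes:", len(net.nodes), "edges:", len(net.edges),
      "P* = %.3g" % net.p_star)
print(result.report.summary())
```

prints

```
interactors: 38
0.0       7
30.0     26
120.0    10
300.0    18
600.0    24
network nodes: 38 edges: 162 P* = 7.11e-08
nodes: 38
predicted edges: 162 (validated: 92)
precision: 0.57
random baseline: 0.13 (92 reference edges among nodes)
high-confidence edges: 162 (validated: 92; precision: 0.57)
```

Of the 40 planted preys, 38 are recovered with no false positives; the
interactor count per time point follows the planted kinetic modules (26 of
the preys peak at 30 s). The network's 162 edges hit the reference (here a
60%-recall subset of the planted within-module pairs) far above the 0.13
random baseline. The same pipeline runs from the shell:

```sh
corecnet simulate --outdir fixtures --seed 1
corecnet run-all --intensities fixtures/protein_groups.tsv \
    --design fixtures/design.tsv --reference fixtures/reference.tsv \
    --outdir out --seed 1
```

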