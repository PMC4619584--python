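# frugnet

Bipartite plant–frugivore network analysis: weighted consumption matrices
built from focal-tree visit records, species- and network-level indices
with null-model tests, secondary-extinction robustness, phylogenetic
structure of interaction assemblages, and energy-flow keystone scores.

## Who this is for

Community ecologists studying frugivory (or any bipartite mutualism) who
have focal-observation visit logs — which animal visited which plant, for
how long, feeding at what rate — and want the full quantitative toolkit
that is usually scattered across several R packages, in one tested Python
library with a reproducible synthetic-data generator for every stage.

## The quantities it computes

**The consumption matrix.** Each cell X<sub>ij</sub> is the number of
fruits of plant *i* handled by frugivore *j*, estimated as total feeding
time × mean focal feeding rate (fruits·min⁻¹). Marginals A<sub>i</sub>,
A<sub>j</sub>, grand total *M* and fill *F* drive everything downstream.

**Species-level indices** (per trophic level): degree D and normalized
degree ND; nested rank NR; weighted betweenness WB and closeness WC on the
one-mode projection; species strength SS = Σ<sub>j</sub> X<sub>ij</sub>/A<sub>j</sub>;
effective partners EP = exp(Shannon entropy); species specificity SSP
(scaled CV of interactions); and Kullback–Leibler specialization
d = Σ<sub>j</sub> p′<sub>ij</sub> ln(p′<sub>ij</sub>/q<sub>j</sub>) with
its standardization d′ between heuristic extremes. Core/periphery
membership uses the standardized degree G<sub>c</sub> = (k − k̄)/σ<sub>k</sub>,
core at G<sub>c</sub> ≥ 1.

**Network-level structure.** Nestedness by NODF (0–100) against ER and CE
binary nulls; specialization by H2′ ∈ [0, 1] — the deviation of the
interaction entropy from its marginal-constrained maximum — against a
weighted null that conserves *M* and *F* while tracking the marginals
(the `vaznull` scheme).

**Robustness.** Secondary-extinction curves under random species removal;
R is the area under the survivors-vs-removed curve. A one-plant-ablation
experiment re-measures R after deleting single highly connected plants.

**Phylogenetic assemblage structure.** For each plant, the frugivores
visiting it form an assemblage on the frugivore phylogeny; MPD/MNTD are
standardized against an independent-swap null into NRI/NTI and classified
aggregated / random / dispersed.

**Keystone scores.** Pulp-biomass flow = consumption rate × active hours ×
dry pulp mass per fruit × tree density (g·ha⁻¹·day⁻¹), contrasted with the
topological rankings via rank overlap and index correlation tables.

## Worked example

```python
import frugnet as fn

# a synthetic 20x30 web, strongly nested, counts scale
m = fn.gen_matrix(20, 30, nestedness_level=0.8, specialization_level=0.2,
                  mean_weight=5.0, seed=7)
print(m)
res = fn.null_test(m, "nodf", "er", replicates=1000, seed=42)
print(res.summary())
table = fn.species_index_table(m, "plants")
print(table[["D", "ND", "SS", "EP", "d_prime", "core_flag"]].head(4).round(3))
rob = fn.random_robustness(m, "frugivores", n_orders=100, seed=3)
print(f"plant-level robustness R = {rob.R:.3f} (SD {rob.R_sd:.3f})")
```

prints

```
<ConsumptionMatrix 20 plants x 30 frugivores, scale=counts, M=1626, F=321>
NODF = 83.98 vs er (1000 reps): null mean 52.97 (SD 2.533), z = 12.244, p = 0.000999
       D     ND     SS      EP  d_prime  core_flag
P001  27  0.900  3.665  23.025    0.152       core
P002  28  0.933  4.129  20.619    0.154       core
P003  24  0.800  2.046  15.874    0.155       core
P004  23  0.767  2.363  13.368    0.218  periphery
plant-level robustness R = 0.937 (SD 0.027)
```

The web is far more nested than its ER null (z ≈ 12; the empirical p is
floored at 1/(R+1), never exactly 0), the first plants are generalist core
species with many effective partners and low specialization d′, and the
plant level survives random frugivore loss well (R ≈ 0.94, where 1 means
no secondary extinctions until the very last removal).

The same pipeline runs from the shell:

```bash
frugnet synth --n-plants 20 --n-frugivores 30 --nestedness 0.8 --seed 7 --out web.csv
frugnet nulltest --matrix web.csv --stat nodf --model er --reps 1000 --seed 42
frugnet indices --matrix web.csv --level plants --out indices.csv
frugnet robustness --matrix web.csv --remove frugivores --orders 100 --seed 3
```

Field data enter through `frugnet build-matrix --records visits.csv` (one
row per visit: plant, frugivore, duration in minutes, focal counts,
focal-interval seconds) or `fn.read_matrix(...)` for an existing
plants × frugivores table (CSV or spreadsheet, transposed input
supported).

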