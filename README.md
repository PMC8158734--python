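# catadiscrim

Discrimination diagnostics for **check-all-that-apply (CATA)** consumer
panels, built on consensus **binary similarity coefficients**.

## The problem

In a CATA test each assessor ticks, for every product, the sensory
attributes they perceive, yielding one binary vector per (assessor,
product). Consumer panels are untrained, so some participants genuinely
distinguish the products while others tick nearly the same terms every
time — and standard analyses (correspondence analysis, Cochran's Q) are
diluted by the latter group. `catadiscrim` quantifies each assessor's
*discrimination ability* and splits the panel into good and poor
discriminators so the product map can be read per group.

## The method

For one assessor and one product pair, the two binary vectors are reduced
to the 2×2 contingency quad *(a, b, c, d)* — attributes checked in both
products, in the first only, in the second only, and in neither, with
*p = a + b + c + d* the ballot length. A registry of **44 binary
similarity coefficients** (Jaccard–Tanimoto *a/(a+b+c)*, simple matching
*(a+d)/p*, Driver–Kroeber cosine *a/√((a+b)(a+c))*, Yule, Pearson φ,
Baroni-Urbani–Buser, … following the Todeschini collection) is evaluated
on the quad; distance-type entries are converted by *S = 1/(1+D)* and
every coefficient is affinely rescaled onto [0, 1] via
*(S + α)/β*. Their unweighted mean is the **consensus similarity** — no
single coefficient can be privileged a priori, and averaging partially
cancels their individual biases.

Downstream of the pairs × assessors consensus matrix:

* **Consensus limit** — the grand mean; assessors whose column average is
  strictly below it are *good discriminators*; 100× the grand mean is the
  panel-level *discrimination index* (lower = better discrimination).
* **Clustering** — Ward/Euclidean agglomerative clustering of assessor
  columns (silhouette sweep reported, default k = 2); the cluster with
  the lower mean similarity is the good-discriminator group.
* **Per-group statistics** — Cochran's Q screening of attributes,
  correspondence analysis of the product × attribute counts (total
  inertia = χ²/N), and one-way ANOVA + Tukey HSD letters on overall
  liking, each run for the total panel and both clusters.
* **Agreement** — the CATATIS homogeneity index, 100·λ₁/m of the
  assessor × assessor cosine Gram matrix, paired with per-assessor
  discrimination to show that agreeing with the panel and discriminating
  products are different skills.

A synthetic-panel generator with planted good/poor classes and
discriminating/noise attributes makes the whole pipeline testable without
proprietary consumer data, and ships the published 38/34/16-term
attribute ballots of three reference studies (cricket-powder biscuits,
apple-pomace biscuits, strawberries).

## Worked example

Simulate a panel shaped like the apple-pomace biscuit study (60 assessors
× 4 products × 34 attributes) and run the full workflow:

```sh
catadiscrim simulate --preset apple-pomace --seed 7 --outdir demo/data
catadiscrim run-all demo/data/panel.csv \
    --liking demo/data/liking.csv --scale 1 9 --outdir demo/out
```

which prints

```
wrote 21 artifacts to demo/out (consensus limit 0.381, homogeneity 35.2%)
```

The consensus limit 0.381 is the grand mean of the 6 × 60 consensus
similarity matrix (discrimination index 38.1%), and
`discrimination_summary.csv` shows 34 of the 60 assessors fall below it:

```
statistic,value
consensus_limit,0.380709413763
selected_assessors,34
remaining_assessors,26
```

`tukey_letters_good.csv` holds the liking comparison within the
good-discriminator cluster — the enriched product AP10 (mean 3.85,
letter `a`) is liked significantly less than AP2.5 and AP0 (letter `b`),
while AP5 straddles both groups (`ab`):

```
sample,mean_liking,letters
AP10,3.85,a
AP5,5.1,ab
AP2.5,5.75,b
AP0,6.25,b
```

and `catadiscrim agreement demo/data/panel.csv --out demo/agree.csv`
reports the CATATIS view (`homogeneity index: 35.2%`). The other
artifacts — pair similarity matrix, heatmap table, cluster labels and
profile, silhouette sweep, per-group Cochran's Q and correspondence
analysis coordinates — are plain CSVs named after their role, plus a
`manifest.json` echoing the configuration.

The same pipeline is available as a library (`read_panel`,
`pairwise_matrix`, `summarize`, `ahc_cluster`, `cochran_q`,
`correspondence`, `liking_anova_tukey`, `catatis_homogeneity`, …); see
`docs/methods.md` for the statistical details and design choices.

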