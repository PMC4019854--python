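# connrepro

Test–retest reproducibility analysis of structural brain networks built
from tractography streamline counts.

Diffusion-MRI tractography yields, per subject and scan session, a square
symmetric **connectivity matrix** whose entry (i, j) counts the streamlines
joining brain regions i and j. Downstream graph statistics depend strongly
on how this weighted matrix is binarized, so a reliability study needs the
whole chain — thresholding, metrics, and the statistics comparing them —
to be explicit and reproducible. `connrepro` implements that chain for
scientists studying scan–rescan reliability of connectome pipelines:

- **Constant-density thresholding.** Graph density is
  D(G) = 2‖E‖ / (‖N‖(‖N‖−1)). For a target density the top-weighted edges
  are kept (ties broken by index pair, making edge sets nested across
  densities) and binarized.
- **Seven binary undirected network metrics**: mean clustering coefficient
  C̄ with C_i = 2e_i/(k_i(k_i−1)); characteristic path length L on the
  largest connected component; largest-component size; degree
  assortativity A (correlation of edge-endpoint degrees); global
  efficiency F_glob = ⟨1/L_ij⟩; local efficiency F_loc (mean global
  efficiency of each node's neighbor subgraph); rich-club coefficient
  R(G, k), the density of the subgraph on nodes of degree ≥ k.
- **Graph curves**: each metric as a function of density over the highest
  density grid common to all matrices; R(G, k) as a function of k at a
  fixed density.
- **Reproducibility statistics**: edge-wise Dice overlap
  Dice(x, y) = 2‖E(x)∩E(y)‖/(‖E(x)‖+‖E(y)‖) averaged within and between
  subjects; pointwise intraclass correlation ICC = σ²_bs/(σ²_bs+σ²_ws)
  from a one-way random-effects ANOVA, with standard agreement bands.
- **FDA permutation test**: two groups' curves are averaged, the area
  between the mean curves is the statistic, and group labels are permuted
  (default i = 10000) to get p = x/i, x counting permuted areas ≥ observed.
- **Synthetic cohort generator**: modular backbone + log-normal subject and
  session effects + Poisson counts, emulating a 21-subject, 2-session
  test–retest design with controllable variance components and group
  effects — so the full pipeline runs with no imaging data.

## Worked example

```sh
connrepro simulate --out-dir cohort --n-nodes 40 --n-subjects 6 \
    --group euler:1.0 --group tend:1.4 --seed 7
connrepro run-all cohort/manifest.csv --out-dir results \
    --density-step 0.02 --iterations 2000 --seed 7
```

which prints the written tables and, from `results/dice.csv` and
`results/fda.csv`:

```
group,density,intra_mean,inter_mean
euler,0.02,0.75,0.521875
euler,0.04,0.8279569892473119,0.6236559139784946
...
metric,group_a,group_b,observed_area,p_value,...
clustering,euler,tend,0.014492927442927442,0.0,...
```

Read: at 4% density, the same subject rescanned shares ~83% of its edges
with itself but only ~62% with other subjects — topology is far more
stable within than between subjects. The clustering-coefficient curves of
the two simulated groups differ by an area of 0.0145, which never arose in
2000 permuted labelings (p = 0, i.e. p < 1/2000), detecting the injected
group effect.

The same analyses are available as a library:

```python
from connrepro import (SyntheticConfig, GroupSpec, generate_testretest_dataset,
                       common_density_range, dice_curves)
cfg = SyntheticConfig(n_subjects=21, groups=[GroupSpec("g1")], seed=0)
dataset = generate_testretest_dataset(cfg)
grid = common_density_range(dataset, step=0.01)
summary = dice_curves(dataset, grid)   # summary.intra_mean, summary.inter_mean
```

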