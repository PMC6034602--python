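# cytospat

Microspatial analysis of cytotype segregation in mixed-ploidy plant
populations.

When a diploid plant (2x), its derived tetraploid (4x), and their
sterile triploid hybrids (3x) grow together in a contact zone, the
spatial arrangement of individuals carries the signal of how the
cytotypes coexist: whether each taxon clumps with itself, whether one
taxon tracks the density of another, and whether the hybrids sit
closer to their obligate maternal taxon. `cytospat` implements the
statistics needed to read that signal from mapped individuals in
polygonal field plots, plus the quadrat-scale tests used to ask
whether the taxa are ecologically differentiated at all. It is aimed
at plant population biologists working with mapped contact-zone plots
(hundreds to thousands of m², tens to hundreds of individuals per
taxon).

The core statistics:

- **Ripley's K with Monte Carlo envelopes.** For one taxon,
  K̂(r) = |A|/(n(n−1)) · Σ_{i≠j} e_ij 1{d_ij ≤ r} with translation
  edge correction on the actual plot polygon, compared per radius with
  an envelope from 300 simulations of complete spatial randomness
  (CSR) conditioned on the observed count: above = clumped, below =
  regular, inside = random.
- **Equal-area density association.** Taxon A's intensity surface
  (Gaussian kernel or quadrat counts on a 1 m lattice) is cut into
  three equal-area tertiles (low/mid/high); taxon B's individuals are
  counted per tertile and tested against the uniform expectation
  n_B/3 with a df = 2 chi-square.
- **Nearest-parental distance profiles.** Distance from each triploid
  to its nearest diploid and nearest tetraploid; mean ± SE; density
  per m² by distance band (band areas from a distance transform of the
  plot); peak detection.
- **Quadrat ecology.** Wilcoxon rank-sum comparisons of covariates
  between occupied and unoccupied quadrats, Yates-corrected 2×2
  chi-square tests of species co-occurrence, both Bonferroni-adjusted;
  Bray–Curtis dissimilarity matrices; soil grain-size/colour handling
  including the redness index RI = R²/(B·G³).
- **A synthetic-data generator** (CSR, Thomas cluster process,
  mother-attached offspring, quadrat/soil tables with known effects)
  so the whole chain is testable without field data.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a 60 × 60 m plot with 80 clump-free diploids, 60 independent
tetraploids and 25 triploids placed 1 m (Gaussian) from random diploid
mothers, then summarise it:

```python
import numpy as np
import cytospat as cs

w = cs.PlotWindow("demo", ((0, 0), (60, 0), (60, 60), (0, 60)))
dip = cs.simulate_csr(w, 80, seed=1, mark="2x")
tet = cs.simulate_csr(w, 60, seed=2, mark="4x")
tri = cs.simulate_offspring(dip, 25, sigma_d=1.0, seed=3)
pat = cs.MarkedPointPattern(
    w, np.r_[dip.x, tet.x, tri.x], np.r_[dip.y, tet.y, tri.y],
    np.r_[dip.marks, tet.marks, tri.marks],
)
cs.write_point_table(pat, "points.csv")
print(cs.build_summary_table({"demo": pat}).to_csv(index=False))
```

```
plot,area_m2,n_total,density_total,n_2x,density_2x,n_3x,density_3x,n_4x,density_4x,ratio_4x_2x,ratio_3x_2x,ratio_3x_4x
demo,3600.0,165,458.3,80,222.2,25,69.4,60,166.7,0.75,0.31,0.42
```

165 plants on 3,600 m² is 458.3 individuals/ha; the cytotype ratios
(4x/2x = 0.75 etc.) are the per-plot composition summaries. The same
numbers come from the shell (`win.yaml` holds `plot_id` and
`window_vertices`):

```
$ cytospat summary   --config win.yaml --points points.csv
$ cytospat ripley    --config win.yaml --points points.csv --taxon 2x \
      --n-sim 300 --r-max 10 --seed 1 --out rip.csv --plot rip.png
$ cytospat associate --config win.yaml --points points.csv --taxon-a 2x --taxon-b 3x
region,count
low,8
mid,6
high,11
chi2,1.52
df,2
p,0.467666
$ cytospat neighbors --config win.yaml --points points.csv
n,25
mean_m,1.175
se_m,0.1118
peaks_m,0.75
```

The association output reads: of the 25 triploids, 11 fall in the
high-density third of the diploid surface and 8 in the low third —
an excess in the expected direction that is not significant at this
sample size (χ² = 1.52, df = 2, p = 0.47). The neighbour profile
reports the triploids' mean nearest-diploid distance, 1.18 ± 0.11 m,
consistent with the 1 m displacement scale they were generated with
(for an isotropic Gaussian displacement the mean nearest-mother
distance is σ_d·√(π/2) ≈ 1.25 m). `cytospat run --config full.yaml`
executes every stage in sequence and writes one delimited table per
stage plus a manifest with the seed and a config hash.

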