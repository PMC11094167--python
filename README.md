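# spherograph

Per-cell stemness maps and neighbor-graph homophily statistics for
tumorsphere confocal slices.

Tumorspheres — clonal 3-D aggregates of tumor cells grown in suspension —
mix a minority of stem-like cells (CSCs, marked here by nuclear/cytoplasmic
SOX2) with differentiated cells (DCCs). A central question is whether the
stem cells are scattered at random through the aggregate or sit next to
each other, forming connected paths and patches. `spherograph` answers it
quantitatively from a single two-channel confocal plane (nuclear stain +
stemness marker):

1. **Marker cleaning** — the diffuse marker background is removed by a
   top-hat by reconstruction (subtract the morphological reconstruction by
   dilation of the eroded image under the original).
2. **Nuclei enhancement and segmentation** — CLAHE, morphological opening,
   area closing and a bilateral filter, then instance segmentation
   (self-contained Otsu + distance-transform + watershed backend; an
   optional pretrained star-convex CNN backend can be plugged in).
3. **Territory assignment** — each cell's territory is its Voronoi region,
   bounded by artificial sites on a circle enclosing the spheroid; the
   per-cell marker content is the cleaned-channel sum over the region.
4. **Phenotype threshold** — per-cell marker sums are bimodal. After
   trimming below the 5th / above the 95th percentile (those cells are
   force-labeled), a two-component Gaussian mixture is fit and the
   threshold *V* is the equal-posterior crossing between the component
   means: a cell is stem iff its sum exceeds *V*. Cluster-count checks
   (k-means elbow, BIC/AIC) and a seed-robustness report guard the fit.
5. **Homophily statistics** — on the Delaunay graph of cell centroids
   (the dual of the Voronoi tessellation) four statistics measure
   stem-next-to-stem structure: Newman's attribute assortativity *r*, the
   homophily ratio (fraction of same-type edges), the number of connected
   components of the stem-induced subgraph, and its mean degree.
6. **Permutation null** — keeping the graph fixed, the stem labels are
   relocated uniformly at random (10,000 times by default, preserving the
   stem count); each observed statistic gets a z-score
   z = (observed − null mean)/null sd and a two-sided p, tested at
   α = 0.001, plus an empirical-percentile p.

A ground-truthed synthetic-fixture generator (`spherograph.synthetic_fixtures`)
renders spheroid images with planted phenotypes — random labels for the
null, or stem lineages grown as connected paths — so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
import spherograph as sg

# synthesize a spheroid whose stem cells form connected paths
spec = sg.FixtureSpec(n_cells=200, stem_fraction=0.3,
                      arrangement="paths", clustering_strength=20.0, seed=1)
truth = sg.generate_points(spec)
slc, _, _ = sg.render_image(truth, spec)

result = sg.run_pipeline(sg.PipelineConfig(seed=1, n_permutations=10000),
                         slc=slc, out_dir="run1")
print(result.summary)
for name in ("assortativity", "stem_components"):
    e = result.null_report[name]
    print(name, round(e["experimental"], 3),
          "null", round(e["random_mean"], 3), "+-", round(e["random_sd"], 3),
          "z", round(e["z"], 1), "significant", e["significant"])
```

prints (seed 1):

```
{'n_total': 200, 'n_stem': 61, 'n_differentiated': 139, 'n_unassigned': 0,
 'stem_fraction': 0.305, 'stem_percent': 31, 'radius_um': 23.97,
 'threshold_V': 3.87, 'seed': 1}
assortativity 0.43 null -0.005 +- 0.041 z 10.6 significant True
stem_components 3 null 18.804 +- 2.955 z -5.3 significant True
```

Reading: of 200 detected cells, 61 are above the fitted marker threshold.
The observed assortativity (0.43) sits ~11 null standard deviations above
the random-relocation mean (≈ 0), and the 61 stem cells form only 3
connected components against ~19 expected at random — the planted
clustering is detected as highly significant, exactly the signature the
method is built to find in real spheroids. On `arrangement="random"`
fixtures the same statistics fall inside the null band.

The same run is available from a shell:

```
spherograph simulate --n-cells 200 --arrangement paths --seed 1 --out fx/
spherograph run --input fx/image.tif --out run1/ --seed 1
spherograph merge run1/cells.csv run2/cells.csv
```

`run` writes the cell table (CSV), threshold report and null report
(JSON), the neighbor graph (GraphML + edge list), the territory map
(TIFF) and a red/blue phenotype rendering (PNG).

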