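# spotstack

Spatial transcriptomics toolkit for serial tissue sections: tissue masking of
stained section images, rigid section-to-section alignment, spot-graph
spatial statistics, factor analysis, and 3D reconstruction — with a seeded
synthetic-data generator so every step runs and is testable without any
downloads.

Spot-array platforms (10x Genomics Visium and its predecessors) measure
whole transcriptomes at barcoded capture spots laid out on a hexagonal
lattice (100 μm center-to-center for Visium) under a stained tissue section.
A study usually spans several consecutive sections that were imaged and
sequenced separately, so the computational work sits in two places: putting
the sections into one common frame (image processing) and finding spatial
structure in the counts (statistics). `spotstack` covers both ends for
people analyzing such data from Python.

## What it computes

**Tissue masking.** Each section image is downscaled to a 400-px working
width, contrast-normalized around an Otsu threshold, blurred, partitioned
into SLIC superpixels, and k-means-clustered (k = 2) into tissue vs array
background, followed by small-hole/speck cleanup.

**Alignment.** Tissue edges (mask minus its erosion) feed an iterative
closest point (ICP) registration against a reference section: alternating
nearest-neighbor correspondence and a Kabsch/SVD rigid fit, with a coarse
rotation multi-start and an explicit mirrored branch so rotations,
translations *and reflections* are all recovered. Images follow via backward
warping with bicubic interpolation; spot coordinates via the same transform.

**Spatial-lag autocorrelation ranking.** On the spot graph G (spots within
150 μm are neighbors; at most six on the lattice), the spatial lag of gene g
is

    lag_g = x_g · A        (A = adjacency of G, summed neighbor expression)

and genes are ranked by r_g = corr(x_g, lag_g), the Pearson correlation
between a gene's expression vector and its lag vector. Spatially structured
genes resemble their neighborhoods, pushing r_g up; permuting a gene's
values over the lattice destroys it.

**Region neighbors and DE.** For any labeled region, the graph yields its
inner border (region spots touching the outside) and outer neighbor ring,
e.g. a tumor edge; differential expression between groups of spots is a
two-sided Wilcoxon rank-sum test — exact enumeration for small groups,
a tie-corrected Edgeworth-refined normal approximation otherwise — with
Benjamini–Hochberg adjustment.

**Factor analysis.** Counts are normalized to analytic Pearson residuals
under a negative-binomial model, r = (x − μ)/√(μ + μ²/θ), clipped at zero,
and factorized as A ≈ WH with W (genes × k) and H (k × spots) non-negative,
by Frobenius multiplicative updates initialized from an independent
component analysis. The top-loading genes of each W column are the factor's
driver genes.

**Rendering.** The HSV multi-feature view assigns feature i of k the hue
i/k, min-max rescales every feature, and colors each spot by its
highest-valued feature at that brightness (all-zero spots stay black). For
3D models, nuclei are segmented per aligned section (Otsu inside the mask,
connected components, centroids) and stacked with a chosen z-spacing into a
point cloud (CSV/PLY).

## Worked example

`examples/02_spatial_autocorrelation.py` builds a 15×15 hex lattice, plants
one spatially structured gene among 199 permuted null copies, and ranks:

```
225 spots, 616 edges, max degree 6
    gene        r
    bump 0.546572
null0191 0.228291
null0008 0.225781
null0198 0.207486
null0066 0.204564
the spatially structured gene ranks 1 of 200
```

`max degree 6` is the hexagonal-lattice signature (each interior spot has
exactly six neighbors within 150 μm); the planted gene's autocorrelation
(0.55) clearly separates it from the permutation null (≤ 0.23), so it ranks
first. The other examples cover masking + ICP alignment
(`01_mask_and_align.py`: mask IoU 0.994 against the simulated ground truth,
misalignments of ±18–30° recovered to ~1e-13 px), region-border DE, NMF
factor recovery (cosine ≥ 0.93 to the planted patterns, 10/10 drivers from
the planted gene sets), and the 3D nuclei stack.

A thin CLI mirrors the library for shell pipelines:

```sh
spotstack simulate --preset small --seed 7 --out fx/
spotstack mask   --in fx/ --out masks/ --seed 7
spotstack align  --in fx/ --masks masks/ --out transforms.json
spotstack rank   --in fx/ --out ranks.tsv
spotstack nmf    --in fx/ --k 3 --seed 7 --out factors/
spotstack stack3d --in fx/ --masks masks/ --transforms transforms.json --out cloud.ply
```

`spotstack convert` reads real Space Ranger output (MatrixMarket counts,
positions CSV in either dialect, scale-factors JSON, section images) into
the same bundle format; legacy count tables with `x_y` spot headers load via
`spotstack.read_legacy_st`.

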