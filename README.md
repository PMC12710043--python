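# phyllo3d

Multi-view 3-D reconstruction and quantitative genetics of grass phyllotaxy.

Phyllotaxy — the azimuthal angle between successive leaves around the stem —
is routinely assumed to alternate at a clean 180° in grasses like sorghum and
maize, yet it is one of the hardest canopy traits to measure at scale.
`phyllo3d` implements an end-to-end pipeline that extracts phyllotaxy from
calibrated multi-view binary silhouettes (five turntable side views plus a
top view), and carries the resulting phenotypes into a quantitative-genetics
analysis.  It is aimed at plant phenotyping and quantitative-genetics
researchers who want a tested, fully synthetic-verifiable implementation of
the whole chain:

1. **Voxel carving** — intersect silhouette cones into a visual hull
   (`carve`), scored by reprojection Dice against the inputs and accepted at
   an aggregate score ≥ 0.70 with tree topology.
2. **Skeletonization** — topology-preserving 3-D thinning to a voxel graph,
   gap bridging, and pruning of spurious branches (`thin`, `join_gaps`,
   `prune_spurious`).
3. **Organ segmentation** — stem = nodes on more than two root-to-tip paths;
   leaves ranked bottom-up by attachment height (`segment`).
4. **Angles** — per-leaf inclination θ and azimuth ϕ in the stem's
   principal-axis frame; phyllotaxy φᵢ = (ϕᵢ₊₁ − ϕᵢ) mod 360 and deviation
   Φᵢ = |φᵢ − 180|; retention window 90° ≤ φ ≤ 270°; measuring-side
   ambiguity resolved by Pearson-sign conjugate alignment (φ ↔ 360 − φ).
5. **Quantitative genetics** — per-plant summary metrics, broad-sense
   heritability H = σ²G / (σ²G + σ²R/n) from a one-way random-effects
   model, marker QC (biallelic SNPs, missingness < 30 %, heterozygosity
   < 10 %, MAF ≥ 5 %), Bonferroni thresholds from effective marker counts,
   and a resampling association scan reporting per-marker RMIP
   (resampling model inclusion probability: the fraction of masked-data
   reruns in which a marker clears the significance threshold).

A procedural generator (`synthetic_plant`) builds capsule-swept sorghum-like
plants with exactly known per-leaf azimuths and renders their silhouettes
analytically, so every stage is verifiable offline against ground truth; a
companion population simulator produces genotype/phenotype panels with known
variance components and causal markers.

## Worked example

Simulate a six-leaf plant, render its calibrated silhouettes, and measure it
end to end at 256³ voxels:

```bash
phyllo3d simulate plant --seed 11 --n-leaves 6 --resolution 256 --out-dir demo/plant
phyllo3d measure --views demo/plant --resolution 256 --out demo/angles.csv
```

```
accepted: False (Dice 0.985, tree False); leaves: 6
phi_1 =  180.12 deg  Phi_1 =   0.12  kept
phi_2 =  194.53 deg  Phi_2 =  14.53  kept
phi_3 =  123.60 deg  Phi_3 =  56.40  kept
phi_4 =  354.75 deg  Phi_4 = 174.75  removed
```

The generator recorded this plant's true lower angles as 179.91°, 192.18°,
123.44°, 137.75°.  The three retained angles are recovered within 0.2–2.3°:
this plant really does deviate from the textbook 180° alternation (Φ₃ ≈
56°), and the pipeline measures that deviation rather than assuming it away.
`phi_4` involves the second-to-top leaf, where the path-counting rule merges
the uppermost organs; the resulting nonsense angle falls outside the 90–270°
retention window and is removed — exactly the failure mode the filter
exists for.  This reconstruction also kept a phantom loop (`tree False`), so
it is flagged as rejected for downstream genetics even though angles are
still reported from the cycle-broken skeleton.

Downstream, with a simulated panel:

```bash
phyllo3d simulate population --seed 3 --n-geno 200 --reps 2 --n-markers 1000 \
    --h2 0.33 --causal 7:0.25 --out-dir demo/pop
phyllo3d heritability --phenotypes demo/pop/phenotypes.csv
phyllo3d rmip --vcf demo/pop/genotypes.vcf --phenotypes demo/pop/phenotypes.csv \
    --iters 100 --seed 1 --out demo/rmip.csv
```

`heritability` prints the variance components and the broad-sense estimate —
here σ²G = 0.208, σ²R = 0.668, H (n = 2) = 0.38.  `rmip` reports 985 of
1000 markers passing QC and exactly one marker called at RMIP ≥ 0.1: the
planted causal marker `m7`, at RMIP = 1.00.

Everything is also available as a library; `phyllo3d.measure_plant` runs the
whole chain on a `PlantSpec` and returns scores, the segmented skeleton and
the angle series in one record.

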