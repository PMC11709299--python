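# tomo3d

Reconstruction of 3D gene-expression volumes from tomo-seq data by masked
iterative proportional fitting, with the surrounding workflow: mask
construction, normalization, simulation with known ground truth, accuracy
and screening statistics, and static rendering.

## The problem

RNA tomography (tomo-seq) cryosections a sample along three mutually
orthogonal axes — typically anterior–posterior, ventral–dorsal and
left–right — and sequences each section, giving every gene *g* three 1D
expression profiles **X**<sub>g</sub> (length *l<sub>x</sub>*),
**Y**<sub>g</sub> (*l<sub>y</sub>*), **Z**<sub>g</sub> (*l<sub>z</sub>*).
These are the axis marginals of the gene's unknown 3D expression pattern.
`tomo3d` recovers a nonnegative volume
R<sub>g</sub> ∈ ℝ<sup>l<sub>x</sub>×l<sub>y</sub>×l<sub>z</sub></sup>
whose marginals match the three profiles, restricted to a binary mask
**M** that encodes where sample material actually exists. It is aimed at
anyone analysing tomo-seq experiments (zebrafish embryos, planarians, or
any sample sectioned along three axes) who wants reconstruction,
screening and visualization in plain Python.

## The method

**Preprocessing.** Per-section material volumes are the mask marginals
m<sup>(x)</sup><sub>i</sub> = Σ<sub>j,k</sub> M<sub>i,j,k</sub> (and
likewise for y, z). Inter-section normalization rescales each count by
its section's total expression over all genes and the section's material
volume, X′<sub>g,i</sub> = X<sub>g,i</sub> · m<sup>(x)</sup><sub>i</sub> /
Σ<sub>h</sub> X<sub>h,i</sub>, removing depth and volume differences
between sections. A common scaling then sets every gene's three axis
totals to T, the average of the three raw grand totals, so the marginal
constraints are mutually consistent.

**Masked IPF.** Starting from R(0) = M, one iteration set rescales the
slices of each axis in the fixed order x → y → z:

R(t+1)<sub>i,j,k</sub> = R(t)<sub>i,j,k</sub> ·
X″<sub>g</sub>(i) / Σ<sub>j′,k′</sub> R(t)<sub>i,j′,k′</sub>

so that after the step the fitted axis's marginal equals its target
exactly. Updates are multiplicative, so voxels outside the mask stay
exactly zero. The default runs m = 100 sets and records the loss
L = Σ<sub>axes</sub> Σ<sub>sections</sub> (marginal − target)² after each
set. Sections with a positive target but an empty mask slice are
reported as unassignable mass rather than failing the run.

**Evaluation.** Accuracy against a known truth is the Pearson correlation
over mask voxels only; significance comes from a permutation null
(values shuffled across mask voxels, 1,000 times by default) and a
two-sample Kolmogorov–Smirnov test of observed versus pooled null PCCs.
Screening statistics are Moran's I (6-connected, row-standardized
weights inside the mask; expectation −1/(N−1) for spatially random
fields) and masked correlation with a chosen target gene.

## Worked example

Simulate one tomo-seq replicate (ellipsoid sample, five spatial genes,
100 background genes), reconstruct two genes, and score them:

```python
from tomo3d.simulate import simulate_tomoseq
from tomo3d.reconstruct import IPFConfig, reconstruct_batch
from tomo3d.evaluate import pcc_masked, morans_i

truth = simulate_tomoseq(n_background=100, replicate=0, seed=7)
print(f"dataset: {truth.dataset.n_genes} genes, sections "
      f"{truth.dataset.shape3d}, mask voxels {truth.mask.n_voxels}")

recons, report = reconstruct_batch(truth.dataset, truth.mask,
                                   ["Gene1", "Gene4"],
                                   IPFConfig(iterations=100))
for gene, recon in recons.items():
    pcc = pcc_masked(recon.values, truth.truth_volumes[gene], truth.mask)
    print(f"{gene}: PCC vs truth = {pcc:.3f}, "
          f"final loss = {recon.loss_trace[-1]:.2e}, "
          f"Moran's I = {morans_i(recon.values, truth.mask):.3f}")
```

Output:

```
dataset: 105 genes, sections (50, 50, 50), mask voxels 25368
Gene1: PCC vs truth = 0.891, final loss = 4.06e-18, Moran's I = 0.973
Gene4: PCC vs truth = 0.914, final loss = 2.99e-18, Moran's I = 0.947
```

Gene1 is a centered blob and Gene4 a mirrored pair of anterior spots;
both reconstruct with high correlation to their truths, the final loss
shows the marginal constraints are met to machine precision, and the
strongly positive Moran's I reflects their regionalized patterns.

The same workflows are available from the shell:

```sh
tomo3d simulate --n-background 100 --replicates 1 --seed 7 --outdir sim
tomo3d reconstruct --x sim/replicate_00/tomoseq_x.csv \
    --y sim/replicate_00/tomoseq_y.csv --z sim/replicate_00/tomoseq_z.csv \
    --mask sim/mask.nrrd --genes genes.txt --outdir recon
tomo3d screen moran --recon-dir recon --mask sim/mask.nrrd --out moran.tsv
tomo3d render --recon recon/Gene1.nrrd --mask sim/mask.nrrd \
    --axis z --section all --gif gene1_sweep.gif
```

`examples/zebrafish_example.py` shows the real-data workflow
(hollow-hemisphere mask, user-supplied shield-stage tomo-seq CSVs).

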