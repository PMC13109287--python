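# cirfeat

Shape, electrostatic and hydropathy complementarity features for
**core-interacting residue pairs** on protein surfaces — and the analyses
that quantify which of those features actually carry predictive
information.

Proteins recognise each other through binding interfaces whose cores
combine geometric fit, sign-complementary electrostatic potentials and
matched hydropathy.  `cirfeat` is aimed at structural bioinformaticians who
want to (i) measure these complementarities between residue pairs on
surface point clouds, (ii) classify pairs as core-interacting or not with a
compact convolutional network, and (iii) interrogate the feature space with
mutual information, feature-subset ablation, PCA and residue-class-specific
decision thresholds.  Because curated PDB-derived datasets cannot be
bundled, the package ships a synthetic-complex generator with planted,
re-measurable ground truth so the entire pipeline runs and is tested at
desk scale.

## The measures

**Shape and electrostatic complementarity (Z_s, Z_el).**  A patch is the
surface inside a 9 Å sphere around a surface point.  It is oriented along
its fitted plane normal and projected through a 45° cone onto a 25×25 image
on the unit disk (pixel = mean secant distance r, or mean potential), then
expanded in 2D Zernike polynomials

    f(r, ψ) = Σ_{n,m} c_nm R_nm(r) e^{imψ},  order N = 20.

The vector of norms |c_nm| (121 values) is rotation-invariant; the
Euclidean distance between the descriptors of two *oppositely oriented*
patches measures complementarity — an exact mirror scores 0.  Residue-level
Z_s and Z_el are means over patches on the two residues' surface points.

**Hydropathy complementarity (H_r).**  With per-residue hydrophobicity
indices H (hydrophobic ≈ 0, charged high),

    H_r = −a (H_A·H_B)² + b (H_A·H_B),  a = 0.033, b = 0.363,

a parabola with roots at the minimum and maximum index products and maximum
b²/4a ≈ 1: values near 0 mean matched hydropathy character, values near 1 a
hydrophobic/hydrophilic mismatch.

**The classifier** receives, per residue pair, a 3×10 matrix: the three
complementarities between residue A and residue B plus B's nine nearest
neighbors (min–max normalised on the training split), and scores the
probability that the pair sits at an interface core (decision cut-off
0.38, or per-pair-class thresholds).

## Worked example

```python
from cirfeat.pipeline import RunConfig, run

result = run(RunConfig(seed=1), out_dir="runs/demo")
```

prints (one CPU core, a few minutes):

```
[run] master seed 1
[generate] 60 complexes, 292 core + 274 decoy pairs (8.8s)
[features] 566 pair matrices (29.6s)
[train] 47 epochs, test AUC 0.916 (3.5s)
[analyze] done (134.6s)
[run] total 176.5s
```

and `result.summary` contains, among others:

```
test_auc:            0.916
direct_auc:          shape 0.804   electrostatic 0.621   hydropathy 0.724
mi_true_neighbor0:   shape 0.232   electrostatic <0.05   hydropathy 0.124
ablation_median_accuracy:
  electrostatic 0.587 < hydropathy 0.721 < shape 0.773 < all three 0.814
```

Reading these numbers: the held-out ROC AUC (0.916) says the network
separates core pairs from decoys well on the synthetic benchmark.  The
direct per-feature AUCs mirror the contrasts seen on real complexes (shape
strongest, hydropathy next, electrostatics weakest), the mutual-information
ranking puts the shape and hydropathy partner features above every
electrostatic feature, and the ablation shows electrostatics alone is the
weakest input while all three features together train the best classifier —
the triangulated feature-importance picture the analysis stack is built to
expose.

The same pipeline is available stage-by-stage from the shell:

```bash
cirfeat generate --seed 1 --out runs/demo
cirfeat features --out runs/demo
cirfeat train    --out runs/demo
cirfeat analyze  --out runs/demo
cirfeat report   --out runs/demo
```

Completed stages are skipped on re-run; `cirfeat all` runs the chain in one
go, and `--config run.yaml` overrides any generator/classifier/analysis
setting.

To use your own data instead of the generator: surface point clouds are
plain text (`x y z nx ny nz potential chain resnum resname`, optional CSV
dialect), pair tables are TSV, and the hydrophobicity scale is a two-column
CSV (the packaged scale is a documented synthetic surrogate — supply your
own for real analyses).

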