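# varimap

Image-varifold tools for registering spatial-omics data — mRNA detections,
segmented cells, labeled reference atlases — across scales and modalities in
3D, with censored (partial-volume) matching, optimization-based scale-space
resampling, and mutual-information feature selection.

## Who this is for

Spatial transcriptomics experiments (MERFISH, BARseq, deep-tissue HCR, ...)
deliver billions of point detections over feature sets — genes or cell types
— that differ from experiment to experiment and from the region ontology of
tissue-scale reference atlases such as the mouse CCFv3.  Integrating such
data into a common coordinate framework requires (i) a representation that
treats a labeled voxel atlas and a cloud of transcripts as the same kind of
object, (ii) a deformation model, (iii) a way to match an atlas that covers
the whole organ to data that covers only part of it, and (iv) data reduction
along both the spatial and the feature axis.  This package implements all
four at desk scale, with seeded synthetic generators for every input class,
so the entire pipeline runs and is tested without any external download.

## The model

**Particle measures.**  A dataset is a weighted sum of Diracs on
position × feature space,

    mu = sum_i  w_i  delta_{x_i} (x) p_i ,

with mass `w_i` at `x_i` (mm) and a distribution `p_i` over the feature set
F.  Closeness is the RKHS (varifold) norm induced by a product kernel — a
Gaussian (or sum of Gaussians) `K_sigma` in space and an identity/Euclidean
kernel on features:

    <mu, nu> = sum_{i,j} w_i u_j K_sigma(x_i, y_j) <p_i, q_j> .

**Diffeomorphic matching (LDDMM).**  A diffeomorphism phi acts by
`phi . mu = sum_i |Dphi|_{x_i} w_i delta_{phi(x_i)} (x) p_i`; matching
minimizes `reg * H + || phi_1 . mu - mu' ||^2` where the flow is generated
by geodesic shooting: each particle carries a vector space momentum `rho^x_i`
and a scalar mass momentum `rho^w_i`, the state evolves under the Hamiltonian
system `q_dot = dH/drho`, `rho_dot = -dH/dq` (RK4), and `H = |v|_V^2 / 2` is
the kinetic energy of the flow.  `|Dphi|` is recovered from the mass
transport `w_dot = div(v) w`.  Gradients are exact: closed-form `dH`, a
discrete RK4 adjoint via complex-step Hessian-vector products, and analytic
data-term gradients.

**Crossing modalities.**  To match a region-labeled atlas to molecular data,
each region l gets a latent law `p_l` over the target features, assumed
stationary within the region; the deformed atlas carries the mixture
`sum_l pi_i(l) p_l`.  The laws are estimated jointly with the momenta under
a KL prior toward uniform, weighted by each region's deformed mass.

**Censoring.**  When the data covers a subvolume, a support weight
`alpha^lambda(x) in [0, 1]` — two opposing tanh half-spaces, or a small
learned classifier for irregular boundaries — multiplies the deformed atlas
mass, so unmeasured regions exert no matching force.  The bandwidth lambda
is estimated jointly under the penalty
`J_s = u ln u + 1 - u`, `u = lambda^2 / 0.1`.

**Scale-space resampling.**  A measure with millions of particles is
approximated at scale sigma by the measure of a fixed budget minimizing the
varifold distance: lattice initialization (one particle per occupied
sigma-cube), then L-BFGS over weights and laws, then jointly over positions —
which lets particles slide onto curvilinear tissue geometry.  K-means (Lloyd,
positions only) and kernel regridding are included as baselines.

**Feature selection.**  A feature is spatially informative if its local
expression level predicts which half of a neighborhood a subregion falls in.
Detections are rasterized into sigma-squares, quantile-binned, and scored by
the conditional mutual information `I(X; M | C)` over all 2K x 2K
"megasquares" C, half-indicators X in {b, t, l, r} and binned counts M;
features are ranked by descending score.

## Worked example

```python
import numpy as np
from varimap import SpaceKernel, rotation_sweep
from varimap.feature_selection import score_detections
from varimap.fixtures import make_fig2a_toy, make_striped_gene_field

# three-region atlas {R,G,B} vs two-feature target {black,white} whose
# homogeneous regions correspond to the atlas partition under a half-turn
atlas, target = make_fig2a_toy(n_grid=16)
ks = SpaceKernel(((0.08, 1.0),))
angles, losses = rotation_sweep(atlas, target, ks, np.arange(0.0, 360.0, 5.0))
print(f"optimal rotation: {angles[np.argmin(losses)]:.0f} degrees")
print(f"loss at   0 deg: {losses[0]:.5f}")
print(f"loss at 180 deg: {losses[36]:.3e}")

# striped vs intensity-matched uniform gene
det = make_striped_gene_field(seed=0)
scores = score_detections(det, sigma=0.05, q=10, k=4).scores
for gene, s in sorted(scores.items(), key=lambda kv: -kv[1]):
    print(f"MI score {gene:>8}: {s:.4f}")
```

prints

```
optimal rotation: 180 degrees
loss at   0 deg: 0.00664
loss at 180 deg: -2.082e-17
MI score  striped: 0.1880
MI score  uniform: 0.0757
```

The rotation sweep re-estimates the optimal per-region feature laws in
closed form at every angle and evaluates the cross-modality varifold loss;
the minimum sits exactly at the half-turn that aligns homogeneous regions to
homogeneous regions (the loss there is zero to round-off, since the rotated
particle grid coincides with the target grid).  The mutual-information
scores rank the spatially banded gene above a uniform gene of the same total
intensity, which is the basis for selecting informative feature subsets
before mapping.

## Command line

```sh
varimap map --atlas atlas.csv --target target.csv --config cfg.toml --out run/
varimap resample --in particles.csv --sigma 0.2 --out approx.csv --report report.json
varimap mi-score --detections det.csv --sigma 0.05 --q 10 --k 4 --out scores.csv
varimap align-stack sections/*.csv --out rigid.json
varimap make-fixture --kind fig2a_toy --seed 0 --out fixtures/
varimap censor-fit --particles interior.csv --boundary dummies.csv --out censor.json
```

Particle tables are CSV with columns `x,y,z,weight` plus one column per
feature (or a single `label` column); units are declared per file and
converted to mm on read.  Labeled NIfTI volumes are converted to particle
measures with one particle per foreground voxel or per aggregated block.

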