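# artissm — an articulatable statistical shape model of the equine distal limb

`artissm` builds, evaluates and interrogates a multi-component statistical
shape model (SSM) of the equine distal limb: nine bones plus the hoof
capsule (M = 10 surface components) moved rigidly by N_b = 4 skeleton bones
(metacarpal group → P1 + proximal sesamoids → P2 → P3 + distal sesamoid +
hoof capsule), articulated by flexion/extension at the
metacarpophalangeal (MCP), proximal (PIP) and distal (DIP) interphalangeal
joints. It is aimed at veterinary morphometrics and computational anatomy:
population models of bone shape that can be posed, sampled, fitted to new
limbs, and morphed through familiar hoof/bone biometrics.

## The model

Dense correspondence is established by elastically registering a reference
limb onto every subject (per component), so that every subject is described
by the same semantically-indexed mesh. Subjects are scale-normalized by
third-metacarpal length and pose-normalized by the optimal flexion angle
per joint (single-axis Procrustes, solved in closed form):

    theta* = argmin_theta || v_ref_local - R_z(theta) v_subject_local ||^2

Each normalized subject becomes a composite shape vector

    s_i = [ v_i,0 ... v_i,M-1 | log_mu1 a_1 ... log_mu4 a_4 | c_1 ... c_4 ]

concatenating all vertex coordinates with the skeleton's rotation-axis
directions a_b (log-mapped on the unit sphere around their intrinsic
Karcher means mu_b — the principal-geodesic treatment of direction data)
and the joint centres c_b. PCA via the L x L Gram matrix gives the model

    s(b) = s_mean + E D b,     D = diag(sigma_1 ... sigma_m)

and fitting a new shape is `b = D^-1 E^T (s - s_mean)`. Instances are posed
with their own reconstructed skeleton, so joint spaces stay consistent as
the shape changes. Biometrics (toe angle, heel angle, frog width, joint
curvature radii, ...) are computed directly on the 3D geometry from
landmark vertex sets on the reference topology and linked to the mode
weights by linear regression `b(k) = alpha + beta k`, which drives
biometric-controlled morphing and the linearity (confidence-interval)
analysis.

A synthetic articulated-limb generator with exact ground truth (known
latent modes, joint angles, scales, poses; optionally re-meshed so
correspondence must be re-established by registration) makes the entire
pipeline testable without any CT data.

## Worked example

```python
import numpy as np
from artissm import (ArticulatedShapeModel, SyntheticConfig,
                     generate_population, generate_reference_limb,
                     normalize_subject)
from artissm.registration import correspondence_from_matched

ref = generate_reference_limb()
subjects, truth = generate_population(ref, SyntheticConfig(n_subjects=20, seed=3))
cs = correspondence_from_matched(ref, subjects)       # shared topology
normalized = [normalize_subject(sc, ref) for sc in cs.subjects]
results = ArticulatedShapeModel.from_subjects(normalized, ref).fit()
print(results.summary())
print("compactness at 3 modes: %.4f %%" % results.compactness()[2])
limb = results.reconstruct_posed([2.0, 0, 0], {"MCP": np.radians(15)})
```

prints (seed 3):

```
Articulated statistical shape model
===================================================
training shapes (L):     20
shape vector length:     2652
components:              10
skeleton bones:          4
retained modes:          19

mode        sigma    var %    cum %
   1       30.757    69.75    69.75
   2       17.803    23.37    93.12
   3       9.6623     6.88   100.00
   4    3.888e-07     0.00   100.00
...
compactness at 3 modes: 100.0000 %
```

The three constructed latent modes carry all of the variance (modes 4+
sit at the numerical floor), and the posed instance is a full
10-component limb flexed 15 degrees at the fetlock. The command line exposes the same pipeline:

```sh
artissm synth --seed 3 --out pop/
artissm build-ssm --data pop/ --out ssm/
artissm sample --ssm ssm/ --n 5 --seed 1 --out samples/
artissm reconstruct --ssm ssm/ --pc 1=+2.0 --mcp 15 --out instance/
artissm biometric --model pop/reference --id TA
artissm evaluate --ssm ssm/ --out report/
```

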