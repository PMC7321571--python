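# dvcstrain

Full-field strain measurement and uncertainty quantification for
cartilage-bone volumetric image pairs.

## The problem

Digital volume correlation (DVC) measures internal 3D displacement and
strain fields by tracking cubic sub-volumes between two tomograms of the
same specimen — for example phase-contrast micro-CT scans of an
osteochondral plug before and after loading. At the cartilage-bone
interface this is hard: articular cartilage is nearly homogeneous in
gray value, so the measurement rests on sparse texture (chondrocyte
lacunae) and every DVC result must be accompanied by an uncertainty
analysis. `dvcstrain` implements the complete chain for researchers in
hard-tissue biomechanics:

* **synthetic phantoms** — two-region cartilage/mineralized volumes with a
  rough interface, ellipsoidal lacunae texture, acquisition noise and
  optional phase-contrast-like edge fringes, with analytic ground truth;
* **preprocessing** — rigid registration to the first tomogram by
  normalized mutual information, Perona-Malik anisotropic-diffusion
  denoising, two-phase watershed labeling, marrow zeroing, cubic VOI
  cropping;
* **local-approach DVC** — FFT-based zero-normalized cross-correlation of
  cubic sub-volumes with sub-voxel refinement and a multipass predictor
  cascade (80-72-64-56 → 48 voxels by default);
* **strain** — small-strain tensor by central differences on the node
  grid, and the von Mises equivalent strain;
* **uncertainty** — the zero-strain and synthetic-deformation error
  protocols, summarized as MAER/SDER per tissue region per sub-volume
  size, plus normalized equivalent-strain frequency distributions;
* **indentation** — contact stiffness S = dP/dh and flat-punch hardness
  from load-displacement curves, and unconfined-compression
  stress-strain metrics.

## The statistic at the core

For each measurement point *k* the six strain components
ε_xx, ε_yy, ε_zz, ε_xy, ε_xz, ε_yz (µε) are reduced to

    a_k = (1/6) Σ_c |ε_c(k) − ε_c^true(k)|

with ε^true = 0 for the zero-strain protocol and the analytic affine
strain for the synthetic protocol. **MAER** is the mean and **SDER** the
standard deviation of a_k over points, reported separately for articular
cartilage and mineralized tissue using a strict-inclusion region mask
(sub-volumes straddling the interface count for neither region).

The von Mises equivalent strain combines the deviatoric normal
components e_ii = (2/3)ε_ii − (1/3)(ε_jj + ε_kk) and engineering shears
γ_ij = 2ε_ij:

    ε_eq = (2/3) √( 3(e_xx² + e_yy² + e_zz²)/2 + 3(γ_xy² + γ_xz² + γ_yz²)/4 )

It is nonnegative, zero for hydrostatic states, and 2/3·|ε_zz| for
uniaxial strain.

## Worked example

The zero-strain protocol on a phantom pair that differs only by
acquisition noise:

```python
import dvcstrain as ds

spec = ds.PhantomSpec(shape=(128, 128, 128), noise_sd=0.0, seed=3)
clean, labels = ds.generate_phantom(spec)
scan1 = ds.add_noise(clean, sd=4.0, seed=31)
scan2 = ds.add_noise(clean, sd=4.0, seed=32)
report = ds.zero_strain_test(scan1, scan2, labels, sizes=(16, 24, 32), overlap=0.0)
print(report.to_dataframe()[["region", "size", "maer", "sder", "n_valid_nodes"]]
      .to_string(index=False))
```

prints

```
 region  size        maer         sder  n_valid_nodes
      1    16 2650.156956  2081.670564             43
      1    24 1097.576909   829.447185             38
      1    32  475.902702   306.863602             16
      2    16 2047.402877  5687.131471            126
      2    24  179.942577    98.589682             50
      2    32   88.344037    26.301814             16
```

Any nonzero strain here is measurement error: in articular cartilage
(region 1) the mean absolute strain error falls from ~2,650 µε at
16-voxel sub-volumes to ~480 µε at 32 voxels, and in mineralized tissue
(region 2) from ~2,050 µε to ~90 µε — the precision/spatial-resolution
trade-off that motivates the sub-volume-size sweep. The `examples/`
directory holds one short narrative script per capability (phantom +
virtual deformation, multipass strain recovery, zero-strain uncertainty,
indentation metrics); each prints the numbers it computes and a line on
what they mean.

A thin CLI wraps the same functions for batch use:
`dvcstrain phantom|preprocess|dvc|strain|uncertainty|indent|pipeline --help`.

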