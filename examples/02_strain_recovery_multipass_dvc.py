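"""Measure a known 1% axial compression with multipass DVC.

Correlates a speckle phantom against its virtually compressed copy using
the predictor cascade 64-48-32 (scaled down from the full 80-72-64-56-48
protocol to keep this example quick), differentiates the nodal strain
per tissue region and compares the recovered axial strain with the
imposed -10,000 µε. Following the measurement protocol, the volume of
interest is cropped from the middle after the virtual deformation and
statistics are reported per region: windows that contain — or whose edge
plane abuts — the cartilage-mineralized interface anchor onto its strong
edge, so the strict-inclusion mask with a 2-voxel buffer excludes them.
"""

import numpy as np

import dvcstrain as ds

spec = ds.PhantomSpec(
    shape=(144, 144, 144), interface_roughness_amp=0.0, noise_sd=0.0, seed=2
)
vol, labels = ds.generate_phantom(spec)
_, deformed, truth = ds.make_synthetic_pair(vol, strain_level=0.01)

ref = ds.crop_voi(vol, 136)
dfm = ds.crop_voi(deformed, 136)
lab = ds.RegionLabelMap(labels.labels[4:140, 4:140, 4:140], labels.voxel_size)
truth_c = ds.AffineDeformation(truth.matrix, truth.center - 4.0)

field = ds.run_multipass(ref, dfm, sizes=(64, 48, 32), final_overlap=0.5)
print(f"final grid: {field.grid.n_nodes} nodes, {field.n_valid} valid")

t = truth_c.strain_tensor() * 1e6
truth_eps = np.array([t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]])
for region, name in ((ds.CARTILAGE, "articular cartilage"), (ds.MINERALIZED, "mineralized tissue")):
    masked = ds.mask_by_region(field, lab, region, margin=2)
    strain = ds.compute_strain(masked)
    eps = strain.eps[strain.valid]
    maer = np.mean(np.mean(np.abs(eps - truth_eps), axis=1))
    print(f"{name}: {eps.shape[0]} nodes, "
          f"mean eps_zz {np.mean(eps[:, 2]):8.1f} µε (target -10000), "
          f"MAER {maer:6.1f} µε")
# MAER is the per-node average absolute error of the six strain
# components vs the analytic truth, averaged over nodes. At this
# scaled-down setting the node spacing is only 16 voxels, so the
# ~0.03-voxel sub-voxel interpolation bias floors the axial-strain
# accuracy near 10-20%; at the full protocol scale (240^3 volume,
# 48-voxel final sub-volumes — see scripts/acceptance.py) the same chain
# recovers the imposed strain to about 1%.
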