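"""Quantify DVC strain uncertainty with the zero-strain protocol.

Two copies of the same phantom differing only by acquisition noise are
correlated at several sub-volume sizes; any nonzero strain is measurement
error. MAER/SDER are reported per tissue region and shrink as the
sub-volume grows — the fundamental precision/resolution trade-off.
"""

import dvcstrain as ds

spec = ds.PhantomSpec(shape=(128, 128, 128), noise_sd=0.0, seed=3)
clean, labels = ds.generate_phantom(spec)
scan1 = ds.add_noise(clean, sd=4.0, seed=31)
scan2 = ds.add_noise(clean, sd=4.0, seed=32)

report = ds.zero_strain_test(scan1, scan2, labels, sizes=(16, 24, 32), overlap=0.0)
print(report.to_dataframe()[["region", "size", "maer", "sder", "n_valid_nodes"]]
      .to_string(index=False))
# region 1 = articular cartilage, 2 = mineralized tissue; MAER/SDER in µε.
# Expect both to drop by roughly an order of magnitude from 16- to
# 32-voxel sub-volumes on this noise level.
for region, name in ((1, "cartilage"), (2, "mineralized")):
    m16, m32 = report.maer(region, 16), report.maer(region, 32)
    print(f"{name}: MAER {m16:.0f} -> {m32:.0f} µε as sub-volume grows 16 -> 32")
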