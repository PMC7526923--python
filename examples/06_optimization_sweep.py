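"""Fence-height x clutter-threshold optimization sweep.

For each fence-to-antenna height difference h_CFR and each clutter
threshold, the detection volume is computed with and without the fence
on a paired synthetic scene (the with-fence image has its ground clutter
attenuated by the fence's two-way knife-edge suppression).  The ratio
column shows the volume gain the fence buys.
"""

import batradar as br

system = br.furuno_far2117()
sphere = br.mie_pec_rcs(0.005, system.wavelength_m)
pmin = br.pmin_from_range(system, 550.0, sphere.sigma_m2)
calibrated = system.calibrated(pmin)
pattern = br.gaussian_pattern()

scene = br.SceneSpec(
    shape=(330, 330),
    radar_origin=(165, 165),
    blobs=(
        br.ClutterBlob(center=(100, 230), radius_px=40, base_level=14, fluctuation=0),
        br.ClutterBlob(center=(200, 250), radius_px=25, base_level=10, fluctuation=0),
    ),
    seed=7,
)
sector = br.SectorSpec(25.0, 120.0, 490.0)
fence_template = br.study_csf()

rows = br.optimization_sweep(
    calibrated, pattern, 12.7e-4, pmin, sector, fence_template,
    h_cfr_values_m=[0.0, 0.16, 0.4],
    thresholds=[0, 8, 16, 24],
    image_pair_fn=lambda geom: br.render_csf_pair(scene, geom, calibrated),
)

print("h_CFR   thr   V no fence (km^3)   V fence (km^3)   ratio")
for r in rows:
    print(f"{r['h_cfr_m']:5.2f}   {r['threshold']:3d}   "
          f"{r['volume_no_csf_m3'] / 1e9:17.5f}   {r['volume_csf_m3'] / 1e9:14.5f}   "
          f"{r['ratio']:5.2f}")
print()
print("ratios > 1 appear where the fence pushes clutter below the")
print("threshold (here level 8: clutter at 14/10 drops to ~6/2); at")
print("stricter thresholds even suppressed clutter still blanks the area,")
print("at looser ones the raw clutter was already tolerated, and the")
print("fence's high-angle interference then slightly trims the volume.")
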