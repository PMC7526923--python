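# batradar

Spatial detection-volume modelling for onshore radar monitoring of
bat-sized targets.

Marine X-band pulse radars are an inexpensive way to track bats (and
birds) around wind turbines at ranges far beyond acoustic detectors, but
two things stand between a radar image and a biologically meaningful
number: the radar must be *calibrated* (what cross section is detectable
out to what range?), and *ground clutter* must be accounted for (which
parts of the scene can hide a weak echo?).  This package implements an
analytical model of the 3D detection volume that combines both, plus the
physics of a clutter shielding fence (CSF) — a reflective ring around
the antenna whose knife-edge diffraction shadows the ground and unmasks
clutter-hidden terrain.

It is aimed at radar aeroecologists and wind-park consultants who need
comparable, calibrated detection volumes (for object densities and
traffic rates) rather than raw echo counts.

## The model

**Link budget.** The monostatic radar equation

&nbsp;&nbsp;&nbsp;&nbsp;P_r = P_t g² λ² σ / (R⁴ (4π)³)

relates echo power to target cross section σ and range R.  Setting
P_r = P_min (the minimum detectable signal power, which absorbs every
system loss) and solving for R or σ gives the calibration chain: a metal
sphere of exactly computable RCS (the perfectly-conducting Mie
backscatter series) is tracked to its maximum range, which fixes P_min;
any other object's measured maximum range then yields its RCS.

**Target models.** Sphere RCS across all regimes: Rayleigh
(∝ (ka)⁴), resonant Mie (exact series, conducting and dielectric), and
optical (σ = f·k·πr², with k = 0.56 for water).  Bat-sized animals
follow the classic water-sphere simplification of radar ornithology.

**Fence diffraction.** The CSF top edge diffracts per the sharp-edge
Fresnel model: v₁ = z√(2(ρ₀+r₀)/(λρ₀r₀)),
I_P/I₀ = ½[(½−C(v₁))² + (½−S(v₁))²], applied twice (transmit and
receive): P_rm = P_r·(I_P/I₀)².

**Detection volume.** A 2D power field over (distance, height),
thresholded at P_min, gives the detectable height extent h(d); a
clutter-thresholded PPI image gives the visible pixels; the volume is
V = Σ_p A_px·h(d_p) over visible pixels p, extrapolated by sector angle
for full-circle operation.

## Worked example

`examples/01_calibration.py` runs the calibration chain:

```
wavelength            : 3.186 cm
range resolution      : 10.5 m
1 cm sphere Mie RCS   : 2.84 cm^2  (rayleigh regime)
P_min from 550 m      : -74.0 dBm
RCS of bat model                (R_max   800 m):  12.7 cm^2
RCS of water bottle / dead bat  (R_max   650 m):   5.5 cm^2
RCS of empty bottle             (R_max   350 m):   0.5 cm^2
check: R_max(12.7 cm^2) = 800 m
```

Reading: the exactly-known 2.84 cm² sphere seen out to 550 m implies the
radar detects −74 dBm echoes; a winged bat model seen to 800 m therefore
has a 12.7 cm² cross section — the reference target for all detection
volume simulations.  The other examples cover the sphere-RCS regimes
(`02`), the fence's ground suppression of ≥ 11 dB one-way (`03`), the
2D detection boundary with and without the fence (`04`), the full
volume pipeline on a synthetic cluttered scene with the acoustic-
detector comparison (`05`), and the fence-height × clutter-threshold
optimization sweep (`06`).

A thin CLI wraps the same functions:

```
batradar calibrate-rcs --rmax 800        # -> {"rcs_cm2": 12.71, ...}
batradar detection-range                 # -> {"max_range_m": 795.0, ...}
batradar sweep --scene-config scene.yaml # fence/threshold sweep table
```

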