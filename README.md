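# spiralpvm

Simulation and analysis of retrospectively gated spiral **myocardial phase
velocity mapping** (PVM): three-directional regional velocities of the left
ventricle over the *entire* cardiac cycle, including atrial systole.

Phase-contrast CMR encodes tissue velocity into image phase,
φ = π·v/venc. A 13-interleave spiral readout acquires reference plus three
velocity encodings in 53 cardiac cycles at 21 ms / 1.4 mm resolution;
retrospective ECG gating interpolates the acquired frames onto 60 phases
covering 100% of the cycle, so late-diastolic (atrial) motion is measurable.
Background-corrected velocities are resolved in the LV cylindrical system
(longitudinal v_L, radial v_R, circumferential v_C) and quantified as named
peaks — systolic S, early-diastolic D, atrial-systolic AS, and the
circumferential triplet C1/C2/C3 — with times to peak (TTP) reported from
the R-wave, as percentages of systolic/diastolic length, and on a
fixed-length cycle (350 ms systole + 650 ms diastole):

    TTP_fixed = percent/100 × 350 ms            (systolic peaks)
    TTP_fixed = 350 + percent/100 × 650 ms      (diastolic peaks)

The package is aimed at CMR physicists and cardiac-motion researchers who
want a fully tested, ground-truthed reference implementation of this
analysis. Because no raw scans accompany the study, a moving-annulus
digital phantom (`spiralpvm.phantom`) generates velocity-encoded series
with known kinematics — regional modulation, transmural gradients,
respiratory traces for navigator gating, polynomial background phase and
noise — and every analysis stage is validated against it.

## Modules

| module       | role                                                        |
|--------------|-------------------------------------------------------------|
| `acquisition`| sequence constants (venc, interleaves, FOV, phases, …)      |
| `phantom`    | moving-LV annulus simulator, phase encoding, navigator model|
| `spiral`     | spiral trajectory design, DFT oracle, Kaiser–Bessel gridding|
| `velocity`   | phase-difference velocities, retro-gating, background corr. |
| `geometry`   | contours → masks, cylindrical axes, AHA/24 segments, layers |
| `curves`     | phase markers, peak detection, TTP / E-A quantification     |
| `cohort`     | four-section cardiac-phase normalization, colour maps       |
| `repro`      | signed differences, Bland–Altman, reproducibility tables    |
| `pipeline`   | seeded end-to-end cohort runs                               |
| `cli`        | `spiralpvm simulate / reconstruct / analyze / run-all`      |

## Worked example

```python
import numpy as np
from spiralpvm import (AcquisitionParams, build_motion_model,
                       render_velocity_frames, encode_phases,
                       generate_stationary_series)
from spiralpvm.phantom import annulus_contours, random_background_coeffs
from spiralpvm.velocity import reconstruct_velocities
from spiralpvm.geometry import compute_geometry, to_cylindrical, region_average
from spiralpvm.curves import detect_end_systole, detect_phase_markers, detect_peaks

params = AcquisitionParams()                      # venc 30/20, 21 ms, 60 phases
model = build_motion_model("mid", seed=1)         # healthy mid-slice kinematics
sim = render_velocity_frames(model, params, grid_size=128)
bg = random_background_coeffs(1)
subject = encode_phases(sim.truth, params, bg, noise_sd=0.05, seed=2,
                        magnitude=sim.magnitude)
phantom = generate_stationary_series(params, 128, sim.truth.frame_times,
                                     1000.0, bg, noise_sd=0.05, seed=3)

field = reconstruct_velocities(subject, phantom)  # 60-phase, corrected
endo, epi, lm, _ = annulus_contours(model, field.frame_times)
geom = compute_geometry(endo, epi, lm, 128, params.pixel_spacing, "mid")
curves = region_average(to_cylindrical(field, geom))

t_es = detect_end_systole(curves["radial"], smooth_window=1)
markers = detect_phase_markers(curves["radial"], t_es, smooth_window=1)
peaks = detect_peaks(curves["radial"], "radial", "mid", markers, smooth_window=1)
print(f"end systole {t_es:.0f} ms")
for name in ("S", "D", "AS"):
    p = peaks.get(name)
    print(f"{name}_R {p.amplitude:+.2f} cm/s @ {p.ttp_ms:.0f} ms")
```

prints

```
end systole 350 ms
S_R +2.33 cm/s @ 102 ms
D_R -3.52 cm/s @ 459 ms
AS_R -1.53 cm/s @ 869 ms
```

— the radial systolic peak early in ejection, the deep early-diastolic
filling peak, and the late atrial-systolic peak, each within a few percent
and one reconstructed phase of the prescribed mid-slice kinematics
(S_R 2.38 cm/s @ 109 ms, D_R −3.61 @ 458, AS_R −1.59 @ 866), with end
systole detected at the prescribed first negative radial peak (349 ms).
(The `run_cohort` pipeline additionally applies a one-pixel boundary guard
to the averaging mask, recovering the remaining 2–3%.)

A full two-visit cohort with curve tables, 24-segment colour maps and
reproducibility statistics:

```bash
spiralpvm run-all --seed 1 --subjects 10 --out results/cohort
```

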