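# respitune

Respiratory frequency-tuned dynamic imaging from chest X-ray cine sequences.

Resting-breathing fluoroscopy of the chest (≈12.5 frames/s for 10–20 s)
contains, mixed into every pixel's time series, a respiratory luminance wave —
the anterior–posterior thickness of aerated lung oscillating with breathing —
plus cardiac-band pulsation, static anatomy and noise.  `respitune` isolates
the respiratory component regionally and renders it as a color dynamic image
drawn in the deforming lung-field shape, giving a regional ventilation map
from a plain fluoroscopy acquisition: no forced expiration, no
radiopharmaceuticals, no mouthpiece.  It is aimed at researchers in dynamic
chest radiography and at anyone building ventilation-mapping pipelines on
cine X-ray data.

## Method

Given a cine sequence and the lung-field control points annotated at maximal
inspiration (IP_i) and maximal expiration (EP_i) — quadratic Bezier chains
over 12 points (left lung) and 10 points (right) — the pipeline computes:

1. **Respiratory phase.**  From the diaphragm point's y-coordinate y5_t
   (annotated trace, or tracked from the images):
   r_t = (y5_t − y5_min)/(y5_max − y5_min), so r = 1 at maximal inspiration
   and r = 0 at maximal expiration.
2. **Per-frame contours.**  P_{i,t} = (1 − r_t)·EP_i + r_t·IP_i.
3. **Deformable block grid.**  At maximal expiration the shorter
   apex-to-base boundary curve is divided into 4-pixel arc lengths (M
   bands); M+1 interpolated Bezier band curves split the field, and each
   band is cut into N_m ≈ 4 px cells.  The same (M, N_m) subdivides every
   frame, so each cell follows its patch of lung.
4. **Block signals.**  Mean luminance per cell per frame; by default the
   adjacent-frame differences feed the spectral stage.
5. **Band-pass.**  Per block: FFT, keep only the bin at the respiratory
   fundamental (±1 bin), inverse FFT.  Amplitude and phase per block, and a
   per-frame reconstruction rendered in color inside the lung shape.

A fully synthetic phantom generator (deforming lung templates, known
amplitude/phase maps, cardiac confounder, noise, optional
reduced-amplitude/reversed-phase lesions) makes the whole pipeline testable
without any clinical data.  See `docs/methods.md` for the model details and
numerical choices.

## Worked example

```python
import numpy as np
import respitune as rt

config = rt.fast_profile(seed=1)          # 256x256, 101 frames, SNR 10
phantom = rt.generate_phantom(config)

result = rt.analyze(phantom.cine, phantom.annotation)

log = result.run_log
print(f"frames               : {log['n_frames']} @ {log['frame_rate']} Hz")
print(f"respiratory frequency: {log['f_resp']:.4f} Hz (bin {log['fundamental_bin']})")
print(f"grid                 : left M={log['M']['left']} ({log['total_cells']['left']} cells), "
      f"right M={log['M']['right']} ({log['total_cells']['right']} cells)")

merged = result.maps.merge(phantom.truth, on=["side", "m", "n"],
                           suffixes=("_est", "_true"))
rel = np.abs(merged.amplitude_est - merged.amplitude_true) / merged.amplitude_true
phase_err = np.abs(np.angle(np.exp(1j * (merged.phase_est - merged.phase_true))))
print(f"median amplitude     : {merged.amplitude_est.median():.2f} counts "
      f"(truth {merged.amplitude_true.median():.2f})")
print(f"median |rel amp err| : {100 * rel.median():.2f} %")
print(f"median |phase err|   : {np.median(phase_err):.4f} rad")
```

prints

```
frames               : 101 @ 12.5 Hz
respiratory frequency: 0.2475 Hz (bin 2)
grid                 : left M=34 (640 cells), right M=33 (628 cells)
median amplitude     : 30.03 counts (truth 30.00)
median |rel amp err| : 0.53 %
median |phase err|   : 0.0024 rad
```

The phantom breathes at 0.25 Hz with a 30-count respiratory amplitude, a
10-count cardiac confounder at 1.25 Hz and pixel noise of 3 counts; the
estimated fundamental lands on the nearest DFT bin (0.2475 Hz at this record
length), the grid tiles both lungs into ≈4×4 px cells, and the recovered
amplitude map matches the ground truth to about half a percent with
millirad-scale phase error — the cardiac component is rejected by FFT
orthogonality.

The same pipeline runs from the shell:

```sh
respitune simulate --out phantom/ --seed 1
respitune analyze --cine phantom/cine --annotation phantom/annotation.json \
                  --fps 12.5 --out results/
```

`results/` then holds the block-signal CSV, amplitude/phase maps
(`maps.csv`), a machine-readable run log and the rendered PNG frames.

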