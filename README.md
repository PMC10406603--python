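# sim3d

Multilayer **3D structured-illumination microscopy (3D-SIM) reconstruction**
with fluorescent **dipole-orientation mapping**, plus a forward simulator
that makes every stage testable without microscope data.

## The problem

3D-SIM illuminates the sample with a three-beam interference pattern (three
orientations × five phase steps, 15 raw images per z-plane).  Each raw image
mixes five frequency bands of the sample: orders 0, ±1, ±2 of the pattern
frequency **p**.  Unmixing them and shifting them to their true positions
doubles the lateral resolution; because the ±1 orders are modulated axially
at q_z = (n − √(n² − |p|²λ²))/λ, their two-lobe transfer functions fill the
widefield OTF's *missing cone* and restore optical sectioning, doubling
axial resolution as well.

The pipeline implemented here:

1. **Load** raw multi-page TIFF stacks in any of three vendor page orderings
   (OMX, N-SIM montage, home-built) into canonical (angle, phase, z, y, x).
2. **Separate** the five bands per angle with the pseudo-inverse of the
   phase matrix M[p,m] = e^{imφ_p} after Tukey edge tapering.
3. **Estimate** the pattern: cross-correlation between the zero band and the
   +2 band (peak at 2p) with a peak-contrast reliability criterion; when the
   second order is too weak (low SNR) the estimator falls back to the +1
   band, whose peak survives much deeper noise.  Phase, and modulation
   depths follow from the correlation at the refined peak.
4. **Assemble**: shift each band by m·p on a 2× padded lateral grid and
   merge with a generalized Wiener weighting of the (notch-attenuated) band
   OTFs — Filter 1 — then flatten the envelope and apodize over the extended
   support — Filter 2:

       S(k) = Σ m̂ conj(O_notch) B̃ e^{−imφ₀} / (Σ m̂²|O|² + w²) · Apo(k)

5. **Orientation** (optional): per-angle widefield intensities follow
   I_a = dc + A cos 2(α_a − θ); three polarization azimuths determine the
   in-plane dipole angle θ ∈ [0, π) exactly, with bead-based calibration of
   inter-angle illumination ratios (calib1 = map₂/map₁, calib2 = map₃/map₁).

See `docs/methods.md` for the model, defaults, and numerical choices.

## Worked example

Simulate a filament network, reconstruct it, and inspect the estimated
pattern parameters:

```python
import numpy as np
from sim3d import SimConfig, make_phantom, simulate_raw_stack, reconstruct

cfg = SimConfig(seed=3, peak_photons=500.0)        # OMX-like geometry
gt = make_phantom("filaments", (8, 128, 128), seed=3)
stack, truth = simulate_raw_stack(gt, cfg)

rec = reconstruct(stack)
print(rec.volume.shape)
for p, t in zip(rec.provenance["pattern_params"], truth):
    err = np.hypot(*(np.array(p["p_cycles_per_px"]) - t.p))
    print(f"angle {p['angle_index']}: source={p['source']}  "
          f"|p| error={err:.5f} cycles/px  m1={p['m1']:.2f}")
```

Output:

```
(8, 256, 256)
angle 0: source=second_order  |p| error=0.00000 cycles/px  m1=0.51
angle 1: source=second_order  |p| error=0.00005 cycles/px  m1=0.51
angle 2: source=second_order  |p| error=0.00019 cycles/px  m1=0.51
```

The volume is 2× upsampled laterally (the spectrum support was doubled);
each angle's pattern frequency was recovered by the second-order
cross-correlation to well under a thousandth of a cycle per pixel, and the
estimated modulation depth m1 ≈ 0.5 weights the ±1 bands in the Wiener
merge.  At 5 peak photons the same call reports
`source=first_order_fallback` — the low-SNR path.

The same pipeline from the shell:

```bash
sim3d simulate --out-dir fx --phantom filaments --seed 4 --shape 6,64,64
sim3d reconstruct fx/raw_omx.tif -o recon.tif \
      --layout omx --na 1.4 --lambda-exc 488 --lambda-em 525 \
      --dxy-nm 80 --dz-nm 125
sim3d orientation fx/raw_omx.tif -o pol --layout omx --na 1.4 \
      --lambda-exc 488 --lambda-em 525 --dxy-nm 80 --dz-nm 125
```

`reconstruct` writes the volume (float32 TIFF, pixel-size tags embedded) and
a provenance JSON with every estimated parameter and filter setting needed
to re-run bit-identically.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch — it simulates a
three-angle, five-phase acquisition of a filament phantom at the default
geometry, runs the full reconstruction (separation, estimation, band
shifting, two-step filtered Wiener combination), checks the run, and writes
the results JSON to `--out`.
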