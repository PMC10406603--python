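# Methods

`sim3d` reconstructs multilayer three-dimensional structured-illumination
microscopy (3D-SIM) volumes and maps fluorescent dipole orientation.  This
note records the model, the numerical choices, and what the synthetic tests
do and do not establish.

## Image-formation model

Three-beam interference (an axial beam plus two symmetric side beams from a
diffraction grating) produces an illumination pattern whose intensity carries
five lateral Fourier orders m ∈ {0, ±1, ±2} at multiples of the pattern
frequency **p**.  Because the side beams are tilted, the first orders are
additionally modulated along z at

    q_z = (n − sqrt(n² − |p|² λ_exc²)) / λ_exc ,

fixed by the geometry (n = immersion index).  In a z-stack the pattern is
locked to the objective focus, so the axial modulation multiplies the
detection PSF, not the sample: the m = ±1 bands are sample spectra carried on
the *two-lobe* transfer function ½[H(k−q_z ẑ) + H(k+q_z ẑ)], where H is the
widefield OTF.  Those lobes are what fill the widefield OTF's *missing cone*
(H ≡ 0 on the axial frequency axis), i.e. they restore optical sectioning;
the m = ±2 bands extend the lateral support toward |p|·2 + k_cutoff.

The widefield PSF is the scalar defocus-propagated pupil model: per plane,
the coherent field is the inverse transform of
P(k)·exp(i2πz·sqrt((n/λ_em)² − |k|²)) over the pupil disc |k| ≤ NA/λ_em,
and the PSF its squared modulus.  No vectorial or apodization factors are
included; simulator and reconstructor share this model.

**Pupil-edge clamp.** The default synthetic pattern frequency
(|p| = 0.8 × 2NA/λ_em) exceeds what a side beam inside the pupil can deliver
(|p| ≤ NA/λ_exc); the q_z rule clamps the side-beam transverse frequency at
the pupil edge so the axial frequency stays defined and saturates at the
marginal-ray value.  For OMX-like sampling (80/125 nm, NA 1.4, n 1.518)
q_z ≈ 0.24 cycles per z-step and q_z + k_cutoff_axial < 0.5, so no axial
padding is needed.

## Band separation

With five phase steps φ_p the raw images satisfy D_p = Σ_m B_m e^{imφ_p};
the bands are unmixed by the left pseudo-inverse of M[p,m] = e^{imφ_p}
(for equally spaced phases, Mᴴ/5).  Each plane is edge-tapered with a
separable Tukey window (fraction 0.1) before one 3-D transform of the whole
stack — the axial band structure requires the full 3-D spectrum.  Per-angle
mean intensities are normalized to the first angle before separation to
absorb slow illumination drift.

## Pattern-parameter estimation

All searches run on the 2× laterally padded grid (same frequency sampling,
doubled range).  The correlation between two bands over all integer lateral
shifts is one lateral FFT of the z-summed real-space product of the
(weighted) bands; fractional shifts are evaluated exactly with a zoomed DFT
and polished with a Nelder–Mead simplex on |C|.

Weighting and search:

* each band is restricted to its own OTF support (the ±1 band to the
  two-lobe support) above an |OTF| floor of 5·10⁻³;
* a lateral DC disc of 0.15 × k_cutoff is excluded — the object's DC energy
  otherwise swamps the pattern peaks;
* the integer search maximizes a constant-false-alarm statistic: the
  correlation magnitude divided by the median magnitude in a surrounding
  5–15-sample ring, which whitens the shift-dependent noise floor (overlap
  area and object power both vary with shift).

**Aliased second order.**  At |p| = 0.8 k_cutoff the +2 peak at 2|p| lies
beyond the raw-sampling Nyquist: the second-order content is recorded
aliased, and its correlation peak appears at 2p *wrapped* into the original
Nyquist square.  The +1 peak (always sub-Nyquist within the search annulus
0.3–1.1 × k_cutoff on |p|) therefore seeds a local search around the wrapped
position of 2p̂₁, and the refined peak is unwrapped with the lattice offset
implied by the seed.  If the +2 peak contrast reaches R_min = 4.0 the
second-order frequency is used; otherwise the estimator falls back to the
first order (reported per angle), failing only if the +1 contrast is below
2.0.  This reproduces the intended behavior — the second order is sharper
when trustworthy, the first order survives low SNR.

The initial phase is the argument of the +1 correlation at the refined p
(the +2 argument is 2φ₀ with a π ambiguity).  Because a residual frequency
error δ rotates the measured phase by 2πδ·r̄ (r̄ ≈ the object centroid in the
origin-referenced frame), phase accuracy is meaningful at the field center;
tests compare phases there.  Modulation depths are the ratio of each order's
correlation magnitude to the OTF-matched zero-band overlap weight at the
same shift (exact in the noiseless limit), floored at 0.15 before use as
Wiener weights — at very low SNR the estimate biases low and the floor, not
the estimate, sets the weight.

Degenerate scenes: a laterally structureless object (e.g. an axially
modulated sheet) has no band-0 content outside DC — precisely because the
missing cone removes it — so cross-correlation estimation is impossible;
`ReconstructConfig.freq_override`/`phase_override` (CLI `--freq-override`)
drive the reconstruction with known parameters in that case.

## Assembly and the two-step filter

Bands are embedded in the padded grid and shifted by m·p with an exact
real-space phase ramp; the band OTFs are shifted the same way.  The combined
spectrum is the regularized least-squares merge

    S(k) = Σ_{a,m} m̂_m conj(O^notch_{a,m}(k)) B̃_{a,m}(k) e^{−imφ₀,a}
           ───────────────────────────────────────────────────────── ,
           Σ_{a,m} m̂_m² |O_{a,m}(k)|²  +  w²

with w = 0.05 by default.  Filter 1 is a cylindrical Gaussian notch
(σ = 2 frequency samples, depth 0.98 at DC and at the band centers ∓m·p)
applied to the *numerator* transfer functions: it suppresses the residual
band-center spikes (leaked object DC from imperfect phase stepping or
illumination flicker — the "hammerstroke" artifact) and the defocus haze.
Attenuating the denominator as well would *amplify* the spectrum at the
notch centers (the numerator keeps the true OTF through the data), so the
denominator uses the plain band OTFs.  A pattern-peak depth of 0.9 leaves
10% of strong spikes — still visible against the local background — hence
the 0.98 default.

Filter 2 first divides out the lumpy Wiener signal envelope
T = Σm̂²|O|²/(Σm̂²|O|² + w²) (boost capped at 10 to bound noise
amplification at the support edge) and then applies the generalized-
ellipsoid apodization (1 − d)^0.9 with cutoffs k_cutoff + |2p| laterally
(capped at the padded Nyquist) and k_cutoff_axial + q_z axially.  The
flattening is what makes the final spectrum follow the smooth apodization
ideal instead of OTF² bumps; without it the apodization stacks on the Wiener
roll-off and the effective resolution gain drops from ~2× to ~1.4×.

The inverse transform is real to rounding (conjugate-symmetric inputs);
negative intensities are clipped at zero by default and the clipped fraction
recorded in the provenance, which also stores every estimated parameter and
filter setting needed to re-run bit-identically.

## Dipole orientation

Under polarized excitation rotating with the pattern azimuth, per-angle
phase-averaged intensities follow I_a = dc + A·cos 2(α_a − θ); three angles
determine (dc, A, θ) exactly through the basis {1, cos 2α, sin 2α}, with θ
reported in [0, π).  Pixels with A/dc < 0.05 (or dc not above 3× background
sd when provided) are masked — the angle of near-zero modulation is noise.
Illumination non-uniformity is calibrated from three bead widefield images:
bead intensities (pixels above 20% of each image's maximum) are interpolated
into smooth per-angle maps and the ratios calib1 = map₂/map₁,
calib2 = map₃/map₁ divide the second and third angle images before the fit.

## Synthetic data

The simulator renders D = conv(gt, psf) + 2m₁·Re{e^{iφ}conv(gt·e^{i2πp·r},
psf·cos 2πq_z z)} + 2m₂·Re{e^{2iφ}conv(gt·e^{i4πp·r}, psf)} per image —
the focus-locked pattern model — then applies Poisson noise at a
configurable peak-photon scale plus Gaussian read noise (default 1 e⁻;
`peak_photons=None` is the noiseless forward model).  Defaults: OMX-like
geometry (3 × 5 images, 80/125 nm, NA 1.4 oil), pattern at 0.8 of the
lateral cutoff at 0°/60°/120°, beam ratio E₀:E₁ = 2:1 hence band weights
m₁ = 2/3, m₂ = 1/6 (the physical three-beam pattern then touches zero
intensity).  Optional acquisition imperfections: per-image phase-step jitter
(grating stepper) and per-image illumination flicker (laser stability,
~1% typical) — both zero by default; they are what generate the residual
pattern peaks the notch filter exists to remove.  Phantoms: beads with a
minimum-separation constraint, dense filament networks (default 24 curves —
an actin-like density; sparse scenes starve the correlation of photons),
axially modulated sheets, and uniform volumes; all seeded and deterministic.

What a green test does **not** establish: the simulator shares the scalar
OTF with the reconstructor (no model mismatch), uses circular convolution
(no boundary truncation), and omits aberrations, depth-varying OTFs, sample
motion, and bleaching.  Performance on real microscope data will be bounded
by those effects, chiefly OTF mismatch.

## Numerical choices and limitations

* All spectra are DC-centered; frequency bookkeeping is in cycles per
  original pixel laterally (padded-grid sample spacing is unchanged by the
  2× embedding) and cycles per z-step axially.
* Lateral padding 2×, no axial padding (q_z + k_cutoff_axial < axial
  Nyquist for the supported geometries; checked at OTF build time).
* Content beyond the padded Nyquist (the outer ~0.1 k_cutoff sliver of the
  shifted ±2 bands at |p| = 0.8 k_cutoff) wraps circularly; its energy is
  OTF-edge attenuated and negligible.
* Peak tie-breaks are row-major (lexicographically smallest (k_y, k_x));
  a featureless correlation surface reports contrast 1 and is unreliable.
* Double precision throughout the spectral pipeline; reconstructions are
  bit-reproducible for a fixed input and configuration.
* The ±2 band of high-frequency patterns is partially aliased in the raw
  sampling (see above); the affected content is strongly OTF-attenuated but
  is a genuine physical limitation of such acquisitions, not of the code.
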