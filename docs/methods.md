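# Methods

## The measurement model

Cine DENSE encodes, at every pixel and cine frame, the in-plane displacement
of the tissue currently at that pixel relative to its position at
end-diastole (the first frame after the R-wave trigger): the two phase
channels hold `wrap(2π·ke·u_x)` and `wrap(2π·ke·u_y)` with encoding
frequency `ke` in cycles/mm.  The emulated protocol matches a small-animal
acquisition: 32 mm field of view, 128×128 matrix (0.25 mm pixels), TR
7.1 ms, ke ∈ [0.8, 1.0] cycles/mm, 15–20 frames per cardiac cycle at mouse
heart rates; the frame count is `floor(60000 / HR / TR)`.  Five views are
analysed: three short-axis slices prescribed at 30%/50%/70% of the
*end-systolic* long-axis length above the apex, and two orthogonal
long-axis views.  Phase values live in (−π, π] (the boundary maps to +π).

## Phantom

The synthetic ventricle is a pair of half-ellipsoids of revolution sharing
a flat base plane: epicardial apex at z = 0, base at z = L (default
L = 10 mm), endocardial apex one apical wall thickness (0.8 mm) higher.
Equatorial radii are derived from the prescribed mid-ventricular
end-diastolic radii; the packaged `lowfat.yaml` / `highfat.yaml`
configurations choose them so the analytic cavity volume and wall mass
match the respective group means (≈61/58 µL and ≈100/115 mg at
1.05 mg/µL).

The deformation map, in cylindrical coordinates about the long axis:

* **Circumferential**: deformed radius `r = [1 + (λc(d) − 1)·a(t, θ)]·R`,
  where the peak stretch `λc` interpolates linearly in wall-depth fraction
  `d` between the prescribed endocardial and epicardial values (low-fat:
  0.83 and 0.906, i.e. −17% and −9.4% engineering strain).
* **Twist**: a per-slice rigid rotation, linear in z between the
  twist values anchored *at the basal and apical slice planes* (low-fat:
  0° and 8.8° over a 1.0 cm ventricle → torsion 8.8 °/cm).  Anchoring at
  the imaged planes makes the configured twist difference exactly the
  quantity the analyser measures.
* **Longitudinal**: z → `[1 + (λl − 1)·a₀(t)]·z` (apex fixed; low-fat
  λl = 0.88 → −12%).
* **Activation** `a(t, θ)`: a raised-cosine pulse, zero until the sector
  delay, peak 1 at delay + systolic interval (45 ms), relaxing to zero at
  the cycle end.  No temporal waveform is prescribed by the underlying
  physiology beyond "smooth rise to a systolic peak", so the envelope is a
  modelling choice.  Dyssynchrony is a smooth septal-to-lateral delay
  gradient `delay(θ) = D/2·(1 − cos(θ − θ_early))` with `θ_early = 135°`
  (between the anterior wall at 90° and the septum at 180°), so the septum
  and anterior wall peak before the inferior and lateral walls.

Images are rendered by inverting this map at every pixel centre (the radial
equation is quadratic in R and solved in closed form), encoding the
displacement into phase, optionally adding Gaussian phase noise (noise
enters DENSE in the phase domain), and painting the magnitude as a bright
annulus.  Long-axis views are rendered without the twist component:
through-plane motion is outside the phantom's scope, and twist would move
long-axis material points out of plane.

**Emergent radial strain.**  A kinematically consistent in-plane map cannot
prescribe circumferential and radial stretch independently: with
`r = λc(R)·R` and λc linear in depth, the radial stretch is
`∂r/∂R = λc + R·∂λc/∂R`, which for λc_endo < λc_epi is *always* larger at
the epicardium (the difference is exactly `2(λp − λe)`), and is below 1 at
the endocardium for the packaged geometry (≈ −4.8% endo, +10.4% epi at
mid-ventricle).  The phantom therefore reports its analytic ∂r/∂R as the
radial truth, and the radial recovery tests compare the analyser against
that truth rather than against in-vivo-like positive endo > epi
thickening, which this map family cannot produce.

**Consequences for global function.**  Because the prescribed surface
stretches are subendocardial-layer-like values, the analytic ejection
fraction is `100·(1 − λc_endo²·λl) ≈ 39%` — lower than a real mouse
(≈ 59%), whose endocardial *surface* shortens much more than its
subendocardial layer.  Similarly, sector delays shift circumferential and
radial sector curves identically, so phantom CURE and RURE drop together;
the phantom cannot emulate a radial-only synchrony deficit.  The high-fat
delay amplitude (32.4 ms) was calibrated by bisection on the analytic
sector curves so that RURE = 0.91.

## Analysis chain

1. **Masking** — per-frame myocardial masks threshold the magnitude image
   at half its maximum (the rendered annulus is bright on a dark
   background).
2. **Unwrapping** — quality-guided region growing over the connected mask:
   quality is the negative variance of the wrapped gradients to the
   4-neighbours; growth starts at the best pixel and proceeds through a
   max-heap, each pixel unwrapped against the mean of its already-unwrapped
   neighbours; ties break by row-major index, so the result is
   deterministic.  The remaining global multiple of 2π per frame is
   resolved temporally: frame 0 has u ≡ 0 by construction, and each frame's
   offset is chosen to match the previous frame's median on the mask
   overlap.
3. **Decoding** — `u = φ/(2π·ke)`.
4. **Tracking** — one material point per end-diastolic myocardial pixel
   (by default on a 2×2 subpixel grid).  For each frame the forward map is
   sampled at the pixels (`X_i = x_i − u_i → x_i`) and inverted by
   moving-least-squares interpolation (locally quadratic, 20 nearest
   neighbours, Gaussian distance weights).  Each trajectory is checked
   against the consistency residual `‖x − u(x,t) − X‖ < 0.1` pixel; failed
   points are flagged invalid and stay invalid.
5. **Strain** — per point, current positions are regressed on reference
   offsets over all valid neighbours within 2 pixels (weighted least
   squares, local cubic polynomial; its linear part at the point is F;
   exact for affine motions).  On a mouse wall only ~4 pixels thick the
   stencil spans a large arc and much of the wall, and a plain affine fit
   is biased by wall curvature and transmural gradients (it underestimates
   |Ecc| at the endocardium by >1 strain-%); the cubic local model removes
   this bias at negligible cost.  E = (FᵀF − I)/2 is projected on the
   radial direction (end-diastolic epicardial-centroid ray), its 90° CCW
   rotation (circumferential), or the local wall tangent (longitudinal,
   from the gradient of the wall-depth field), and converted to
   engineering percent.
6. **Layers and segments** — wall depth is the normalised endo→epi
   distance along the centroid ray; segments split the angle 6/6/4
   (basal/mid/apical, ids 1–16) from a configurable origin (default
   "image up"; the anterior-septal insertion is not identifiable without a
   right ventricle, and the origin affects labelling only).  *Layer curves
   are computed by per-frame linear regression of point strain on depth,
   evaluated at depth 0 (subendocardial), 0.5 (mid), 1 (subepicardial).*
   Band means over transmural thirds are also available
   (`layer_method="band_mean"`), but on a 4-pixel wall a third contains
   barely one pixel and its mean sits at the band centre (−15.7% instead
   of −17% for the linear low-fat profile), so the regression evaluated at
   the surfaces is the reported definition.  Global layer curves average
   the three short-axis slices; peaks are minima for circumferential and
   longitudinal strain, maxima for radial.
7. **Longitudinal strain** — both long-axis views are tracked the same
   way; points in the apical 30% of the long-axis length are excluded
   (the wall direction is ill-defined where the ventricle curves), and the
   reported Ell is the mean of the two views' layer curves.
8. **Twist and torsion** — per-slice twist is the mean signed rotation of
   the tracked points about the end-diastolic epicardial centroid
   (counter-clockwise positive); torsion = (apical − basal twist)/L with L
   the end-diastolic epicardial long-axis length (mean of the two long-axis
   views, measured as the extent along the contour's principal axis); peak
   torsion is the signed value of maximal magnitude.
9. **CURE/RURE** — 24 equal angular sectors per short-axis slice; the
   index is the power ratio `Σ_t P0 / Σ_t (P0 + P1)` (no square root),
   which is bounded by (0, 1], equals 1 exactly for uniform profiles, and
   matches the printed 0.91–0.99 range; the reported value averages the
   three slices.  Whether the original index family includes a square root
   or per-frame averaging is not restated in the source; any such variant
   could be swapped behind the same interface.
10. **Volumetrics** — end-diastolic contours are propagated to every frame
    by the same scattered inverse interpolation (motion-guided
    segmentation); the endo/epi surfaces are reconstructed per angular ray
    as a cubic profile of *squared* radius versus height, pinned to zero at
    the apex (from the long-axis views) and capped at the base plane.
    Interpolating ρ² makes the reconstruction exact for ellipsoids and
    keeps the cylinder check within 2%.  The end-systolic frame minimises
    the reconstructed cavity volume; EF = 100·(EDV − ESV)/EDV and
    mass = 1.05·(epi − endo wall volume) at end-diastole.

## Statistics

Exact Mann–Whitney U: mid-ranks, `U = min(U_a, U_b)`, one-sided tail
`P(U_A ≤ U_obs)` by complete enumeration of all `C(n1+n2, n1)` labelings
(valid up to combined n = 20), two-sided p = min(1, 2·tail).  At 5 vs 5
without ties this yields the attainable values 2/252 = 0.008 (U = 0),
4/252 = 0.016, 8/252 = 0.032 (U = 2), 14/252 = 0.056 (U = 3).  Percent
change uses the control mean as baseline.  Pearson R uses the t-transform
with n − 2 df.  α = 0.05 is reported, never used to filter rows.

## Numerical choices and tolerances

* Fit defaults: radius 2 px, cubic local model, ≥20 neighbours, 2×2
  subpixel seeding.  With them the noise-free low-fat phantom is recovered
  to ≤0.15 strain-% (layer Ecc), ≤0.1 °/cm (torsion), ≤3% (EDV, mass).
* The discrete frame grid undersamples the activation peak by up to
  ~0.7% of the amplitude (frames at 42.6/49.7 ms around the 45 ms peak);
  recovery tolerances (±0.5 strain-%, ±0.2 °/cm) absorb this.
* MLS/LS systems carry a 1e-9 ridge; rank-deficient or under-populated
  neighbourhoods are flagged invalid rather than solved.
* Degenerate inputs: a strain-free phantom would make the uniformity index
  0/0 — the measured operator raises an undefined-index error, while the
  phantom truth reports 1 (a uniform zero field is synchronous).

## What the phantom does and does not establish

Passing recovery shows the chain is internally consistent and unbiased for
smooth, noise-free, in-plane deformations of an idealised ventricle.  It
does not exercise: through-plane motion, intramyocardial signal variation
and fat artifacts, papillary muscles, respiratory/gating errors, realistic
noise correlations, or segmentation of real magnitude images (end-diastolic
contours are supplied, per the semi-automated workflow).  Reported radial
strains inherit the phantom's emergent (not physiological) transmural
pattern.  Phantom EF and the CURE/RURE coupling are idealisations, as noted
above.
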