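# Methods

`synapse4d` quantifies the choreography of cytotoxic T lymphocyte (CTL)
killing from 4D microscopy-style data: how long CTLs dwell on targets, when
and whether the centrosome docks at the immune synapse, whether lytic
granules are delivered with it, the structure of the cytosolic Ca²⁺ flux
that precedes these events, and how much of the synapse is depleted of
cortical actin and membrane charge. Because no raw imaging data are
publicly deposited for this system, the package pairs the measurement
pipeline with a ground-truthed synthetic generator whose latent statistics
are calibrated to the published population readouts of the OTI CTL / EL4
altered-peptide-ligand (APL) system. Every analysis in `analysis/` and
every acceptance quantity is a *recovery* experiment: the generator plants
known choreography, the pipeline must measure it back.

## Generative model

### Conditions

Four presets encode TCR signal strength: N4 (SIINFEKL, strong), T4
(intermediate), G4 (weak), NP68 (irrelevant peptide). Calibration anchors
(the printed statistics the presets are built to reproduce):

| statistic | N4 | T4 | G4 | NP68 |
|---|---|---|---|---|
| mean interactions / CTL / 40 min | 4.03 | 4.77 | 5.63 | 6.8* |
| conjugates docked by 600 s | 0.80 | 0.55 | 0.20 | 0 |
| conjugates docked by 750 s | ~1.0 | 0.66 | 0.30 | 0 |
| median primary Ca²⁺ flux (s) | 100 | ~80* | 60 | 30 |

(*) never printed; chosen to preserve the cross-condition ordering.

### Contact episodes

Each CTL draws a Poisson number of contact episodes (mean =
`contacts_per_ctl_mean`, scaled to the observation window), packs them
sequentially with ≥25 s gaps against distinct targets, and truncates
dwells to the remaining movie when over-full. Dwell times are log-normal
(σ = 0.8; medians 120/90/70/35 s for N4/T4/G4/NP68), chosen so that
P(dwell ≥ 120 s) equals each condition's stable-conjugate probability. A
*stable conjugate* is an interaction with dwell ≥ 120 s (configurable);
this cutoff is our operationalisation — the source analyses tracked
"stable conjugates" without printing one.

### Docking

Stable conjugates dock with probability `p_dock` (1.0 / 0.70 / 0.35 / 0);
the contact→docking latency is log-normal, calibrated point-wise to the
docked-by-600 s and 750 s fractions above (N4: median 480 s, σ 0.265; T4:
480 s, σ 0.28; G4: 560 s, σ 0.38). The centrosome distance-to-synapse
profile is biphasic at a constant approach speed of 0.05 µm/s shared by
all conditions (the published observation is that timing and maximum speed
do not vary with signal strength; no value is printed, so the speed is a
documented free parameter): hold at the initial distance d₀ ∈ [4.5, 5.8]
µm, rapid traverse to a 2.2 µm membrane-proximal hold, then a final
approach that crosses the 1 µm docking threshold exactly at the drawn
docking time and settles at 0.35 µm. Docking state, closest approach and
class are *realized* from the piecewise-linear profile, so clipped
episodes demote gracefully. Non-docking cells approach a drawn closest
distance (proximal U(1.6, 4.5) µm; distal/uropod >5.2 µm, the uropod class
additionally flagged rear-positioned), hold, and withdraw.

### Ca²⁺ flux

The first-flux onset latency after contact is a 50/50 log-normal mixture
of fast and slow responders — LN(median 19 s, σ 0.45) and LN(85 s, 0.35) —
which simultaneously matches the three printed statistics (42% within
30 s, median 46 s, mean 55 s); no single log-normal can. The primary flux
duration is conditional on docking, identically in every condition:

* docked cells: LN(median 190 s, σ 0.414), truncated at ≥50 s
  (mean 207 s);
* non-docked cells: LN(median ≈55–57 s, σ 0.385) (≈60 s means), except
  NP68 (median 30 s).

Condition-level flux medians are therefore *emergent* from the docked
fraction — e.g. N4's P(dwell≥120 s)·p_dock = 0.5 puts the population
median at 100 s. This mirrors the central biological claim the package
exists to quantify: signal strength sets the rate at which cells enter a
conserved killing program, not the program itself. Uropod retraction
(flux + LN(66.5 s, 0.80)) and polarisation start (flux + LN(70 s, 0.77))
are ordered flux → retraction → polarisation → docking by construction;
when a drawn docking time is too close to polarisation for the fixed
approach speed, the crossing shifts late rather than breaking the order
(rare). Extra short oscillations (Poisson(0.8) events of ~25 s) follow the
primary flux. Granule delivery: docked cells deliver ≥1 granule to within
0.5 µm of the synapse with probability 0.93, independent of condition.

### Rendering

Movies are rasterised at desk scale (default 9×56×56 voxels of
0.4×0.4×0.9 µm for recovery protocols; the generic default is 12×96×96 at
0.4/0.8 µm; fixed stacks 56×108×108 at 0.2 µm): CTL as a sphere (radius
3.2 µm) with a rear uropod ellipsoid until retraction, flattened against
the synapse plane during contact (0.8 µm indentation → 2.1 µm contact
disc); target as a membrane shell apposed across the contact disc;
centrosome and granules as analytic Gaussian spots; Ca²⁺ as whole-CTL
intensity switched by flux state. Granule clusters sit rearward of the
centrosome with ≥1.25 µm clearance from the synapse plane so that
delivery (<0.5 µm) is unambiguous at the rendered resolution; the lateral
spread follows the per-condition cluster radius (1.2/1.5/1.9/2.0 µm).
Noise: Poisson shot noise on signal-bearing voxels plus Gaussian read
noise (σ = 2 photons); pure-background voxels use the Gaussian
N(λ, λ+σ²) approximation to the same model, which at the 10-photon
background is indistinguishable to every detector downstream. There is no
bleaching, aberration, or target-death rendering.

Movie lengths for flux recovery are condition-dependent (900/900/750/450 s
for N4/T4/G4/NP68) so that fewer than ~3% of primary fluxes are
right-censored; censored events are excluded from duration statistics.

Fixed conjugate stacks render a tilted (10–30° off-axis) synapse disc of
radius 2.2 µm whose depleted centre — radius √f·R for true depleted
fraction f — is genuinely dark through the en-face slab. A cortical rim of
≥0.3 µm always remains: a fully depleted synapse with zero residual
signal could not be located by any footprint rule, so true fractions near
1 compress to a rim-limited maximum (~50–65% measured). Recovery is
accurate to ~5 percentage points over the 0–0.6 range that the
measurements of interest occupy.

## Measurement pipeline

* **Segmentation** — per frame: Gaussian smoothing (σ = 1 voxel in XY,
  anisotropy-scaled in Z), global Otsu threshold with a contrast guard
  (foreground must exceed background by 4× its spread, else the frame has
  no objects), morphological closing (suppresses single-voxel boundary
  raggedness that would otherwise thicken contact surfaces and bias
  distances low), hole filling, connected components, minimum volume
  30 µm³ (4 µm³ for fine-z fixed stacks whose structures of interest are
  thin). Identities are linked by greedy nearest-centroid matching with a
  5 µm/frame gate.
* **Spots** — scale-matched Laplacian-of-Gaussian filtering with
  anisotropy-corrected sigmas and minimum separation, threshold at 5 MADs
  above the median response, plateau-tie suppression, and sub-voxel
  intensity-weighted centroid refinement. Spots at the mask edge adopt
  the modal label of their immediate neighbourhood; for the centrosome
  only the brightest maximum per CTL is kept. The conjugate pipeline
  additionally prunes granule detections below 10% of the brightest
  response in the cell (near-threshold noise maxima sit ~30× below
  genuine granules).
* **Synapse surface** — CTL boundary voxels reached by a 1-voxel dilation
  of the target mask; with exclusive instance masks this realises the
  "overlapping models" definition. All distances are Euclidean in
  physical µm against surface voxel centres.
* **Interactions** — maximal runs of contact frames per (CTL, target)
  pair, merging gaps ≤1 frame; half-open frame intervals, so dwell =
  (end − start) × Δt.
* **Centrosome kinematics** — per-frame distance to the nearest surface
  voxel; docking = first frame <1 µm (strict), classes docked <1 µm,
  proximal 1–5 µm (boundaries inclusive), distal >5 µm, uropod >5 µm AND
  fractional position ≥2/3 along the synapse→rear axis (a configurable
  heuristic; no numeric definition exists). Maximum speed from raw
  finite differences.
* **Ca²⁺** — trace = mean reporter intensity in the CTL mask (nan when
  absent, never interpolated); background = median of pre-contact frames
  (first three frames as fallback), spread = MAD floored at 0.5% of
  background; an event runs while the trace exceeds background + k·MAD
  (k = 3, the reproducible proxy for "visibly exceeded background") and
  ends at the first frame back at or below it. Raising k shrinks the
  above-threshold set — total detected duration is non-increasing and
  every high-k event nests in a low-k event — but a noise dip can *split*
  an event, so the event count alone is not monotone in k.
* **En face** — least-squares plane through the surface voxels (normal
  oriented CTL→target), trilinear resampling onto an in-plane grid,
  maximum projection through a 3 µm slab. Depletion % = 100×(1 −
  above-threshold area / gap-filled footprint area), computed on the
  largest connected component; sub-pixel rim breaks are bridged by a
  binary closing before the topological fill (the closing is a no-op on
  clean fixtures, so the formula identity is exact there). The default
  background threshold is the background-to-plateau midpoint
  ((median + 99th percentile)/2), which places the binary edge at the 50%
  intensity crossing of a PSF-blurred boundary — the unbiased edge
  position; Otsu and isodata weight class histograms and systematically
  expand smooth-edged bright regions (~10 points of depletion bias on
  rendered conjugates), so they are available but not default.
* **Assays/statistics** — the standard LDH-release formula
  100×((exp−blank)−(eff_spont−blank)−(tgt_spont−blank)) /
  ((tgt_max−lysis_control)−(tgt_spont−blank)); the printed source
  expression is typographically damaged ("%Lysis was calculated as:
  ((effector induced cell death – blank)-(effector spontaneous death –
  blank) – (target spontaneous death))/ ((Lysed targets – lysis
  control)") and this is the kit formula it denotes. Group comparisons
  use two-tailed Mann–Whitney U (exact for tie-free n ≤ 20, else normal
  approximation with tie correction) with Bonferroni correction over the
  comparisons actually drawn.

## Trace-level bridges

Population statistics that do not require optics (contact rates, latency
fractions, flux/docking association) are computed at trace level: contact
episodes are frame-sampled into boolean series, Ca²⁺ traces are
synthesised from the latent flux state with noise σ = 0.35 (matched to
the ~0.36 empirically measured on the rendered whole-cell-mean readout),
and centrosome traces are frame-sampled from the latent profile — the
same detection code paths as the imaging route, minus rasterisation.

## Problem sizes

Recovery protocols use 50 rendered interactions per condition for flux
medians, 25 rendered stable conjugates per condition for docking
fractions, 40 rendered docked conjugates for delivery, and 200 (trace
level) for contact rates and latency fractions — sizes at which the
sampling error of each statistic is comparable to or larger than the
pipeline's measurement error, i.e. the measurement is no longer the
bottleneck.

## What passing does and does not show

The generator emulates geometry, optics and noise only coarsely: spherical
cells, a planar synapse, isotropic PSF per axis, no bleaching, no cell
deformation beyond the uropod, granules as permanent spots. Passing
recovery therefore demonstrates that the measurement operators are
faithful to their definitions under realistic sampling, quantisation and
shot noise — not that they are robust to segmentation failure modes of
real movies (touching same-channel cells, debris, drift, photobleaching).

## Known limitations

* In rendered 6.4 µm cells any closest approach >5 µm is geometrically in
  the rear third, so the distal and uropod classes are not separable on
  rendered movies (they are at trace level, where the rear flag is
  latent); class proportion tables should merge them for rendered data.
* Depletion fractions above ~0.6 are compressed by the residual-rim
  requirement (see above).
* The docked-group flux mean is biased low by ~1–2 s because a pre-onset
  noise blip occasionally becomes the "primary" event; the association
  report flags docked fluxes <50 s rather than re-picking.
* The schedule packer shrinks dwells when a draw over-fills the movie,
  coupling dwell length weakly to episode count.
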