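# Methods

## Problem and scope

`qctpeep` quantifies how positive end-expiratory pressure (PEEP) redistributes
lung aeration when the abdomen is under pressure (intra-abdominal
hypertension, IAH). It implements the quantitative-CT side of a PEEP
titration protocol — PEEP steps of 5, 12, 17, 22 and 27 cmH2O at an
intra-abdominal pressure of 27 cmH2O, in healthy and oleic-acid-injured
lungs — together with the respiratory-mechanics endpoints used to pick a
"best PEEP" at the bedside. Image segmentation (mask creation), mixed-model
statistics, hemodynamic modeling and anything upstream of a rescaled-HU CT
volume with a lung mask are out of scope.

## Aeration quantification

Voxels inside the lung mask are classified by Hounsfield unit into
overdistended [−1000, −900), normally aerated [−900, −500), poorly aerated
[−500, −100) and atelectatic [−100, 200]. Bins are lower-inclusive
half-open (the top edge closed): on integer HU this reproduces the standard
integer ranges (−1000…−901, −900…−501, −500…−101, −100…200) exactly, while
staying well defined for interpolated non-integer HU. In-mask voxels outside
[−1000, 200] are excluded from compartment fractions but reported, so the
conservation identity

    Σ compartment volumes + excluded volume = mask volume

holds to within one voxel. Gas and tissue come from the linear air–tissue
mixture: gas fraction = clamp(−HU/1000, 0, 1), tissue volume fraction its
complement, tissue density = clamp((HU+1000)/1000, 0, 1.2) g/mL. The density
clamp at 1.2 g/mL keeps mildly hyperdense voxels (HU up to 200) physical.
Hence gas volume + tissue volume = included volume exactly, whereas tissue
*mass* may exceed tissue volume where HU > 0. No partial-volume correction
or HU smoothing is applied.

Segmental analysis cuts the mask's bounding extent along the dependent
(ventral→dorsal) axis into three equal-thickness slabs; when the depth is
not divisible by three the remainder voxels go to the ventral-most slab(s).
Slabs are equal thickness, not equal volume — the simplest reproducible
rule. Left/right are split at the midpoint of the mask's bounding extent on
the first array axis. Convention throughout: the dependent axis is the last
array axis, index 0 = ventral (supine subject); this is fixed once so the
generator and the segment partition can never disagree silently.

## Pressure–volume modeling

Each compartment's volume across the PEEP ladder is fitted with three
families:

* sigmoid: V = a + b/(1 + e^−(P−c)/d), d > 0, b free-signed;
* saturating exponential: V = a + b(1 − e^−P/τ), τ > 0 (the classic
  single-compartment respiratory PV form);
* linear: V = a + bP.

The winner is the converged, non-degenerate fit with the smallest RMS
residual; exact ties break toward the more expressive family. No
degrees-of-freedom penalty is applied — raw RMS is the selection rule, which
is knowingly biased toward the sigmoid.

The four-parameter sigmoid is weakly identified on five pressures, so the
fit is a deterministic multi-start: c on five equally spaced values across
the observed pressure range × d ∈ {1, 3, 6} cmH2O, with a and b solved
exactly by linear least squares at each start (the model is linear in them),
followed by bounded trust-region refinement (analytic Jacobian,
xtol = ftol = gtol = 1e−14). d is bounded to (0.1, 50) cmH2O to exclude
step-function degeneracies; c is bounded to the data range ± 2 spans. Fits
with |b| below 1e−6 of the volume scale or a width pinned at its bound are
flagged degenerate (e.g. constant volumes) and excluded from model
selection, never silently returned as NaN.

For a sigmoid fit the lower and upper inflection (corner) points are
P = c − 2d and P = c + 2d: the tangent at the midpoint (c, a + b/2) has
slope b/(4d) and meets the asymptotes V = a and V = a + b at exactly those
pressures (a geometric identity the tests verify numerically). The *optimal
CT inflation PEEP range* runs from the lower inflection point of the
atelectatic compartment to the lower inflection point of the overdistended
compartment; an inverted window is flagged via `well_formed`, never
reordered. Fits default to raw volumes; `to_fractional` rescales a
trajectory to the fraction of its change across the pressure range (an
affine map, leaving c and d — and therefore the inflection points —
unchanged). A residual-bootstrap utility for corner-point intervals exists
but is off by default.

## Respiratory mechanics and titration

Static elastances use the two-point occlusion method: E_rs = ΔP_aw/V_T,
E_W = ΔP_es/V_T with Δ the inspiratory-minus-expiratory plateau difference,
and E_L = E_rs − E_W, so E_rs = E_W + E_L holds by construction. The
expiratory airway pressure is the *total* end-expiratory pressure (set PEEP
plus intrinsic PEEP when measured; set PEEP otherwise). Transpulmonary
pressure is airway minus esophageal pressure at matching phase; P/F =
PaO2/FiO2, with P/F < 300 mmHg (strict) classifying lung injury.

The best-PEEP selector extremizes the per-PEEP median of an endpoint over
the descending phase only (physiology and CT are measured on the descending
limb of the protocol). Ties resolve to the lowest PEEP — the clinically
conservative choice, and the resolution consistent with the published tied
rows. Hysteresis is descending minus ascending per cell, with single-phase
cells skipped and reported.

Missing cells are imputed from average relative differences: for subject s
missing endpoint e in cell j (a condition/phase/PEEP triple), the imputed
value is mean_others(e at j) × r_s, where r_s is the mean over s's observed
cells of e_s(j′)/mean_others(e at j′). Ratios are averaged per endpoint,
not pooled across endpoints (endpoints have different units; pooling would
mix scales). The rule is a no-op on complete tables and scale-equivariant
per endpoint. Cells that cannot be imputed (no peer observed at j, or s
observed nowhere for e) stay missing and are reported.

Both conditions' descending-phase median endpoints ship as a packaged CSV
(transcribed from a published porcine IAH titration experiment) so the
selector's worked examples run offline. One caveat discovered on those
tables: for healthy chest-wall elastance the minimum of the per-PEEP
medians (PEEP 17) differs from the published median of per-animal optima
(PEEP 22). A medians-based selector cannot reproduce that one cell; the
other 17 target × condition cells agree.

## Synthetic CT phantom

The phantom is an ellipsoidal lung (semi-axes 0.84 × each half-extent of
the grid; default 64³ voxels of 2.5 mm, ≈1.27 L) whose voxels follow a
logistic recruitment law. At normalized depth h (0 ventral, 1 dorsal) and
pressure P:

    g(h, P) = g_min + (g_max − g_min) · σ((P − P_open(h)) / w)
    P_open(h) = θ0 + θ1·h + k_iap·IAP

HU = −1000·g plus optional Gaussian noise (default sd 30 HU); tissue
outside the lung is set to +50 HU. Injury lowers the achievable gas
fraction by 0.15 and adds 40 cmH2O/unit-depth of opening-pressure slope in
the dependent half (h > 0.5) only, mirroring the dorsal dominance of
injury-related de-recruitment. k_iap defaults to 0.5 — roughly half of
abdominal pressure transmitted to the pleural space, the literature-typical
abdomino-thoracic transmission ratio.

Defaults (θ0 = −41, θ1 = 85, w = 9 cmH2O, g ∈ [0.02, 0.95], IAP 27) were
chosen by closed-form analysis of ellipsoid cap volumes so that, noiselessly,
the atelectatic fraction falls strictly (≈31 → 3%) and the overdistended
fraction rises (≈2 → 26%) across PEEP 5 → 27. A single-logistic law with a
depth-linear opening pressure cannot simultaneously match published
compartment percentages at both ends of a 22 cmH2O PEEP span — keeping
dependent tissue recruitable at PEEP 27 forces either more low-PEEP collapse
or more high-PEEP overdistension than real pigs show — so the defaults trade
the two errors evenly and should be read as a severe-IAH caricature with the
correct *directions*, not calibrated magnitudes. Consequences for testing:
phantom-based tests establish conservation, monotonicity, segment gradients
and oracle agreement of the *analysis*, not fidelity of the phantom to
porcine anatomy, real HU textures (no beam hardening, no motion, no
partial-volume mixing at the pleura), or real PV hysteresis (the phantom's
g(h, P) has none).

The physiology-table generator is a purely statistical fixture:
multiplicative lognormal noise (exp of Normal(0, cv)) around per-endpoint
medians, an optional fixed descending-minus-ascending offset, and
deterministic blanking of named cells for imputation tests. It makes no
attempt at mechanistic hemodynamics.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations are bit-identical.

## Numerical choices and problem sizes

* Unit-test phantoms run at 40³ voxels, the acceptance computations at the
  default 64³ — sizes at which every closed-form check is exact to
  float64 rounding while the whole suite stays interactive.
* Sigmoid recovery is characterized on 200 seeded five-point datasets with
  noise at 2% of the span |b|; the median corner-point error (≈0.6 cmH2O)
  and the non-convergence count are both reported, never hidden.
* Pressures are cmH2O everywhere; mmHg inputs are converted on read at
  1 mmHg = 1.36 cmH2O.
* CSV/JSON writers are byte-stable (sorted keys, fixed column order);
  NIfTI determinism is guaranteed at the array level.

## Known limitations

* No lung segmentation, no inter-PEEP registration, no DICOM networking.
* The exponential and linear family parameterizations are the field's
  standard forms; other reasonable choices could select differently on
  borderline real data.
* Whether real analyses fit absolute or fractional volumes is ambiguous;
  both are supported, raw volumes are the default, and the inflection
  points are invariant between them for a given sigmoid.
* The imputation rule assumes missingness unrelated to value (it transfers
  a subject's average relative level, not its trend shape).
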