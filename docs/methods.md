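# Methods

## The estimation problem

Dual-calibrated fMRI modulates arterial CO2 and O2 while acquiring
interleaved pCASL (TE1 = 10 ms) and BOLD-weighted (TE2 = 30 ms) images
with a dual-excitation readout. Hypercapnia raises cerebral blood flow
without changing oxygen metabolism; hyperoxia raises arterial oxygen
content without changing flow. Together the two challenges make the
composite BOLD calibration amplitude and the baseline deoxyhaemoglobin
content separately identifiable, from which the resting oxygen
extraction fraction (OEF0) and, with baseline perfusion, the absolute
CMRO2 follow. `qdcm` extends this estimation with a capillary
oxygen-exchange model so that the effective oxygen diffusivity of the
capillary network, Dc, is estimated simultaneously.

## Capillary oxygen-exchange model

A representative capillary with haemoglobin-bound content Ct exchanges
oxygen with a well-stirred tissue pool at mitochondrial tension Pm
(default 0). Plasma oxygen is in Hill equilibrium with the bound pool,

    P(Ct) = P50 * (Ct / (phi*[Hb] - Ct))^(1/h),    phi = 1.34 ml/g, h = 2.8,

and the content along the fractional coordinate x obeys

    dCt/dx = -(Dc / CBF) * (P(Ct) - Pm),

with inlet Ct(0) = 0.95 * phi * [Hb] and OEF = 1 - Ct(1)/Ct(0). Dc = k*V
(effective permeability times capillary volume, ml/100g/mmHg/min) and
CBF share the per-100 g basis, so only the ratio Dc/CBF enters.
Dissolved plasma oxygen is neglected inside the capillary but included
in the arterial content used for Fick arithmetic — an intentional
asymmetry: the dissolved term is ~2% of content and negligible for the
transit ODE, but hyperoxia acts on the BOLD signal almost entirely
through it.

Numerics: for h > 1 the content extinguishes at finite x (the
right-hand side is non-Lipschitz at Ct = 0), so the ODE is integrated in
the transformed variable v = u^((h-1)/h) (u = Ct/(phi*[Hb])), whose
right-hand side stays bounded through extinction. An explicit adaptive
Runge-Kutta scheme at rtol 1e-10 then agrees with a 1e5-step fixed-step
Euler reference to |dOEF| < 1e-4 everywhere tested, and total oxygen
flux is conserved to ~1e-7 relative.

The (CBF, Dc) -> OEF lookup table is solved on a 96x96 log-spaced base
grid (CBF 5-150 ml/100g/min, Dc 0.005-0.35 ml/100g/mmHg/min — spanning
grey/white matter and pathological margins) in a single vectorised
integration over the distinct Dc/CBF ratios, then resampled to 512x512
with monotone PCHIP interpolation so that cheap bilinear interpolation
can be used inside the fit. OEF is strictly decreasing in CBF and
increasing in Dc except in the complete-extraction corner (low CBF,
high Dc), where it genuinely saturates at 1 and ties occur. Inversion
for Dc is a bracketed monotone root-find on the table's own
interpolant; out-of-range extractions return the boundary Dc with a
warning. Micromolar conversion uses the ideal-gas molar volume at body
temperature (25.45 ml/mmol; STPD 22.414 available as an option).

## Arterial inputs

End-tidal tensions are taken as arterial (PaO2 = PETO2, PaCO2 =
PETCO2). Saturation uses the Severinghaus closed form
S = (23400/(P^3 + 150P) + 1)^-1 — the standard algebraic variant in
calibrated fMRI. Content is CaO2 = phi*[Hb]*SaO2 + eps*PaO2 with eps =
0.0031 ml/mmHg/dl rescaled to per-ml; [Hb] is stored in g/ml and g/dl
inputs are converted with range guards. Blood T1 follows R1 =
1.527e-4*PaO2 + 0.1713*(1-SaO2) + 0.5848. Baseline pH and P50 are
scalars from the mean PaCO2 over air-breathing volumes (identified as
|dPETCO2| < 1 mmHg and |dPETO2| < 15 mmHg from the scan-start median):
pH = 6.1 + log10(HCO3/(0.03*PaCO2)) with HCO3 = 24 mmol/L, and P50 =
221.87 - 26.37*pH. Traces are aligned to the MR timeseries by
maximising the normalised cross-correlation between PaCO2 and the mean
grey-matter ASL signal over lags within +/-30 s at the trace's native
sampling; boundary lags and weak peaks raise warnings. Trace-to-volume
resampling is linear — end-tidal plateaus are slow relative to the
4.4 s TR.

## Signal models

BOLD (TE2, fractional):

    dS/S0 = TE * kappa * [dHb]0 * {1 - (CBF/CBF0)^theta * [dHb]/[dHb]0},

theta = 0.06; kappa absorbs venous blood volume and diffusion effects
and carries units 1/ms per (g/ml). [dHb]0 = [Hb]*(1 - SvO2,0) with
SvO2,0 = SaO2,0*(1 - OEF0). The deoxyhaemoglobin ratio under
isometabolic gas modulation is

    [dHb]/[dHb]0 = CBF0/CBF - (1/[dHb]0) *
        { (CaO2 - (CBF0/CBF)*CaO2|0)/phi + [Hb]*((CBF0/CBF) - 1) }.

ASL (TE1, tag/control difference), single-PLD pCASL:

    dS = 2*alpha*alpha_inv*CBF*T1b*M0*(1-exp(-tau/T1b))*exp(-PLD/T1b)
         / (6000*lambda),

alpha = 0.85, alpha_inv = 0.88, tau = PLD = 1.5 s, lambda = 0.9, with
T1b varying per volume (hyperoxia shortens it and attenuates the
label). CBF is driven by PaCO2 only, CBF(t) = CBF0*(1 +
CVR/100*dPaCO2(t)); hyperoxic vasoconstriction is neglected, and a hook
accepts an arbitrary measured CBF(t) instead.

Raw interleaved series are composed symmetrically (control = static +
dS/2, tag = static - dS/2), with the BOLD fraction scaled by TE1/TE2 at
the first echo and a T2*-attenuated residual label (factor 0.67 for the
20 ms echo gap at 3 T) at the second. This composition is one shared
code path between the phantom generator and the fitter's prediction, so
a noiseless phantom voxel is an exact stationary point of the fit and
recovery experiments isolate estimation error rather than model
mismatch.

## Preprocessing

Surround subtraction (each volume minus the mean of its two
opposite-condition neighbours, sign-corrected, one-sided at the ends)
isolates the ASL difference and cancels linear drifts; surround
averaging isolates the BOLD component. A 3-point sliding kernel passes
a period-P modulation with gain (1 + cos(2*pi/P))/2: distortion is
below 1% only for periods of roughly 30 TRs and longer, which the
~3-minute gas blocks (~40 TRs) satisfy; faster structure is attenuated
by design. The initial perfusion estimate inverts the kinetic model at
the baseline blood T1; the grey-matter partial-volume surrogate is that
map normalised by the median of its 100 brightest voxels (top 10% for
small masks), clipped to [0, 1]; the diffusivity prior is 0.15
ml/100g/mmHg/min times that partial volume. Motion correction,
registration and segmentation are upstream responsibilities.

## Voxelwise fitting and regularisation

Free parameters per voxel: (CBF0, Dc, kappa, CVR); OEF0 is tied to
(CBF0, Dc) through the lookup table. Bounded trust-region least squares
(bounds: CBF0 [1, 199], Dc the table span, kappa (0, 10], CVR
[-0.99, 9.9]) minimises

    sum (ASL residual/sigma_ASL)^2 + sum (BOLD residual/sigma_BOLD)^2
      + w_oef*(OEF0 - 0.4)^2 + w_dc*(Dc - dc_prior)^2,

where the per-voxel channel noises come from a first-difference
estimator over baseline volumes (an unregularised-first-pass residual
estimator is available). Because the data terms are noise-normalised
while the priors are not, the priors' relative influence grows with
voxel noise — the adaptive behaviour the design intends. Initialisation
is deterministic: CBF0 from the baseline ASL level, CVR from a linear
regression of ASL on dPaCO2, kappa from a one-parameter BOLD amplitude
fit at nominal OEF, Dc from the partial-volume prior. Flat voxels are
skipped and masked, not zero-filled.

Penalty weights are calibrated by grid search on a digital-phantom bank,
minimising the spread-normalised MSE of (OEF0, Dc) against ground
truth; a stronger prior is accepted only when it improves the objective
by more than 1%, so flat directions resolve to the least informative
prior. One documented calibration run (partial-volume-graded bank,
tSNR 200, fixed seed) fixed the package defaults at oef_weight = 3000,
dc_weight = 0; re-tuning at tSNR 50 activates the diffusivity prior
(1000, 1000), and noiseless banks tune to zero weights.

An identifiability analysis (Cramér-Rao bound on the voxel Jacobian)
shows why the priors matter: hyperoxia pins TE*kappa and hypercapnia
then determines the product of [dHb]0 with a flow-dependent factor, so
voxelwise OEF0 precision is limited by CVR precision, which rests on
the intrinsically low per-volume ASL SNR. At realistic noise the
unregularised voxelwise Dc standard error exceeds its physiological
spread; the OEF prior and the partial-volume structure of the Dc prior
supply exactly the information the group-level method assumes.
The cost is a small shrinkage bias: group-mean OEF0 is pulled toward
the 0.4 prior by up to ~2%, which the lookup inversion and the Fick
product amplify into a +2-8% group-mean bias on Dc and CMRO2,0 under
phantom conditions. Group means of the directly identified parameters
(CBF0, OEF0, kappa, CVR) recover within 5%.

## Task-state quantification

Percent BOLD and CBF changes come from a two-regressor (boxcar +
constant) least-squares fit — a deliberate lightweight substitute for a
full GLM package, adequate for block designs without autocorrelation
modelling. Task CMRO2 inverts the resting calibration model,

    CMRO2 = CMRO2,0 * (1 - dBOLD/(BOLD0*TE*kappa*[dHb]0))
                    * (CBF/CBF0)^(1-theta),

with kappa and [dHb]0 from the resting fit of the same voxels; task OEF
follows from the Fick principle at resting arterial content and task Dc
from lookup inversion at constant [Hb] and P50. ROI analysis uses
ROI-mean timeseries by default (voxelwise available). On
forward-modelled activation (flow +21.4%, metabolism +15.1%) the chain
recovers the CMRO2 ratio to 0.2% and implies a ~13% diffusivity rise,
i.e. a flow-volume coupling exponent of ~0.62.

## Digital phantoms

The default protocol is an 18-minute schedule (244 volumes at TR
4.4 s): air 90 s, hypercapnia 180 s, air 90 s, hyperoxia 180 s,
repeated, ending in air, with plateaus at PETCO2 41.6/51.7 mmHg and
PETO2 116/325.2 mmHg and first-order 15 s wash-in transitions. Noise is
additive white Gaussian per channel; tSNR is defined on the baseline
TE2 signal and the TE1 channel uses a thermal-noise ratio of 1. The
default tSNR of 200 represents spatially smoothed (4.5 mm FWHM)
3.4x3.4x7 mm voxels at 3 T under thermal noise alone — in-vivo total
tSNR is lower because of physiological noise, which the phantom does
not model; 50 serves as the low-SNR condition. Ground-truth maps
emulate a 0.5-thresholded grey-matter mask: partial volume pv ~
U(0.3, 1) with CBF0 = 10 + 70*pv, Dc = 0.1415*pv, kappa = 0.092*pv,
CVR = 3.7*pv (each with modest multiplicative jitter), reproducing the
group grey-matter means at the mean pv. The pv co-variation embodies
the capillary-density/partial-volume assumption that also motivates the
Dc prior. What passing phantom tests do not show: robustness to
physiological noise, motion, arterial transit heterogeneity, or
spatially correlated noise — none of which are simulated.

## Known limitations

- Single representative capillary: no flow or [Hb] heterogeneity, no
  axial diffusion, steady-state transport only. Pm defaults to 0 and is
  exposed for sensitivity analyses (OEF decreases monotonically with
  Pm).
- The adaptive regularisation is a reconstruction of the published
  intent (the original appendix formula is not reproduced here),
  validated by phantom behaviour only.
- Voxelwise Dc is prior-informed at realistic SNR; its voxelwise
  contrast partly reflects the perfusion-derived partial-volume
  structure rather than independent per-voxel measurement.
- The simplified single-PLD kinetic model ignores transit delays and
  dispersion; slice timing of the multi-slice readout is not modelled.
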