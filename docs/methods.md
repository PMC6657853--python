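# Methods

`conesim` simulates the dim-flash electrical response of a cone
photoreceptor outer segment with four model tiers that share one
biochemical parameterization.  This note records the model, the numerical
choices, and the judgment calls a maintainer would want to know about.

## Geometry and scales

The outer segment is a right circular truncated cone (tip radius
r = 1.15 um, base radius R = 3.08 um, height H = 15 um by default)
packed with n = 500 lamellar membrane discs.  Cytosol is confined to the
thin interdiscal chambers (thickness nu*eps0 = 15 nm each) and to the
*closing sliver*: the strip of lateral membrane of angular width
omega0 = pi and radial thickness sigma*eps0 = 15 nm that is the only
connection between chambers and the only location of the CNG channels and
the Na+/Ca2+-K+ exchanger.  Two geometric scales coexist: the organelle
(~10 um) and the chamber/sliver thickness (~10 nm).  The cytosol fraction
is nu/(1+nu) = 1/2 independent of eps0 to second order.

Axially, z = 0 sits at the larger base and z = H at the tip, so photon
positions quoted as fractions of height read directly; a `z_origin="tip"`
flag flips the convention without changing any physics.

## Biochemistry

Second messengers cGMP (opens the CNG channels) and Ca2+ (inhibits
guanylyl cyclase via GCAPs) obey Fickian diffusion with boundary fluxes:

* disc faces: synthesis eta*alpha(Ca) with the decreasing Hill law
  alpha(Ca) = alpha_min + (alpha_max - alpha_min)/(1 + (Ca/K_cyc)^m_cyc),
  and dark hydrolysis -eta*beta_dark*cG, where eta = nu*eps0/2 = 7.5 nm is
  the chamber volume-to-surface ratio and
  beta_dark = k_sigma_hyd [PDE] / eta = 67 1/s;
* the activated face: additional hydrolysis -k*_hyd [E*] cG with
  k*_hyd = 0.83 um^3/s (equivalently k_cat/K_m = 500 1/(uM s) per E*
  dimer);
* the sliver exterior: the calcium flux
  (1/(B_Ca F)) (f_Ca J_cG(cG)/2 - J_ex(Ca)) with the channel Hill law
  J_cG = J_cG_max cG^m_cG/(K_cG^m_cG + cG^m_cG) and Michaelis-Menten
  exchanger J_ex = J_ex_sat Ca/(K_ex + Ca), both as densities over the
  sliver area Sigma_cone.  The 1/2 reflects calcium's two charges through
  the channel vs one net charge per exchanger cycle.  Currents in pA/um^2
  convert to molar fluxes in uM*um/s through the single factor
  1e9/F (pinned by a dimensional-analysis unit test).

Hill exponents: m_cyc = 2.5 and m_cG = 2.0 by default.  The channel
exponent and the current convention (channel-only) are fixed by requiring
the dark steady state to reproduce the reference dark current: solving
alpha(Ca) = beta_dark*cG together with f_Ca J_cG/2 = J_ex gives
cG_dark = 1.548 uM, Ca_dark = 0.701 uM and j_dark = J_cG(cG_dark) =
14.88 pA with this combination, and 9.9-19.4 pA with every other one.
Both remain configuration switches.  The measured current j(t) is the
sliver integral of the channel density (optionally plus the exchanger).

## Activation cascade

A photon fixes an active opsin R* at a point of one disc face.  R*
produces activated transducin T* at rate nu_j = nu_RT e^{-k_v (j-1)}
(nu_RT = 125 1/s, k_v = 0.5), where j-1 counts attached phosphates; T*
diffuses on the disc (D_T = 2.2 um^2/s) and converts to activated effector
E* on encounter with dark PDE; E* diffuses (D_E = 1.2 um^2/s) and decays
at k_E = 18.5 1/s.  The conversion rate is calibrated as
k_TE [PDE] = c_TE nu_RE = 125 1/s, i.e. a fully active receptor drives E*
production at nu_RE after an ~8 ms transducin delay.

Shutoff is a continuous-time Markov chain: from a state with j phosphates
the receptor either gains a phosphate (rate lambda0 = 105 1/s) or is
arrested (mu0 = 12.5 1/s, allowed from every state).  The mean absorption
time with these rates is exactly 80 ms.  Three deterministic reductions of
the chain are implemented:

* `mean_path` (default): the receptor lives exactly the mean lifetime and
  phosphorylates at the mean pace 1/lambda0, so the activity decays
  geometrically every 9.5 ms.  The resulting E* pulse peaks near 40 ms.
* `state_occupancy`: stage durations equal the expected occupancy of each
  chain state bounded by n_step; with n_step = 1 the activity stays at
  nu_2 = 75.8 1/s until shutoff and the E* pulse peaks at the 80 ms
  quench, retarding every response tier by ~35 ms relative to the
  mean-path kinetics.
* `constant`: a single activity nu_RT over the mean lifetime.

The mean-path reduction is the default because it is the one whose
response kinetics (time to peak near 55 ms, reduced tiers earlier, dim
flash amplitudes of a few hundredths of a percent) match the reference
behaviour of this parameter set; the chain rates themselves are never
adjusted.  Stochastic sampling of the shutoff sequence and Brownian R*
motion (D_R) are available behind flags but excluded from reference runs.

The cascade solver uses P1 elements on the shared cross-section
triangulation with a mass-lumped implicit Euler scheme (lumping keeps the
point-source solution nonnegative).  The Dirac production term is lumped
onto the containing node; nodal values near the source are
mesh-dependent, integrals are not, and only integrals (through
k*_hyd E* cG, itself integrated against the fold's mass) enter the
volumic tiers.  Spatially integrated totals obey the lumped ODE pair
exactly (Galerkin conservation), which is also how the reduced tiers
consume the cascade.

## The four tiers

**NHOM** resolves the layered geometry explicitly: every chamber is a thin
truncated-cone slab discretized with two vertical node levels (so
intra-chamber vertical gradients are represented), disc-face reactions on
both faces, and a radially-lumped volumic sliver shell joining all
chambers.  At reduced chamber counts n the disc spacing is rescaled so the
stack fills H (n (1+nu) eps = H), preserving the cytosol fraction; the
biochemical rates keep the physical 15 nm spacing (beta_dark stays
67 1/s) while the geometric face weight eta_n = nu*eps_n/2 and sliver
capacity sigma*eps_n follow the mesh.  This is the homogenization family
read backwards, so NHOM(n) -> HOM is a meaningful desk-scale convergence
family.

**HOM** is the homogenized/concentrated-capacity limit: per-slice 2D
horizontal diffusion in the interior (vertical interior diffusion is
blocked by the chambers), Laplace-Beltrami surface diffusion on the
limiting sliver with concentrated capacity sigma*eps0, volumic reactions
alpha - beta_dark*cG from the homogenized disc faces, the activated fold
as a singular cross-section reaction, and the channel/exchanger flux on
the sliver.  The discretization is a single conforming Galerkin form with
one unknown per physical location: sliver nodes *are* the rim nodes of
their cross-section, so the trace-equality conditions and the
fold-to-sliver edge fluxes of the continuum system hold by construction,
and the diffusion blocks are symmetric positive semidefinite (asserted in
tests).  Cross-sections are vertex-centered (z = 0..H inclusive) with
trapezoid capacity weights, which makes the discrete sliver area converge
to Sigma_cone.

**LWS** collapses the cone to its axis: 1D reaction-diffusion on (0, H)
weighted by the cytosol cross-section A_c(z) = (nu/(1+nu)) pi lambda(z)^2,
with each activated disc a point sink k*_hyd E*_tot(t) cG(z0) and the
channel/exchanger fluxes converted to volumic rates through the sliver
area density omega0 lambda(z)/cos(gamma).  The taper enters through both
weights, and the 1D dark current integrates to the same whole-cell value
as the 3D tiers.  **GWS** removes axial diffusion as well (four ODEs).

Both reduced tiers reproduce the dark steady state exactly, and LWS
converges to GWS under diffusivity scaling (a tested limit, as is
HOM -> GWS).

## Why the sliver shields the response

The quantity the cell reports is cGMP *at the channels*.  In the 3D tiers
a depletion created at a disc reaches the channels only through the
sliver, whose capacity (sigma*eps0 ~ 15 nm of cytosol) is minute compared
to the interior it must drag along.  Two analytic estimates bracket the
resulting longitudinal localization.  If each cross-section were fully
stirred, the sliver signal would diffuse with
D_eff = D_cG sigma eps0 / (theta_c pi lambda cos(gamma)/omega0)
~ 1.6 um^2/s and decay over l = sqrt(D_eff/beta_dark) ~ 0.15 um (a
1/e-interval of ~0.31 um).  In fact the interior deficit penetrates the
cross-section only to the reaction-diffusion depth sqrt(D_cG/beta_dark)
~ 1.3 um (comparable to the disc radius), so the slab presents the
impedance theta_c sqrt(D_cG beta_dark) per unit sliver length and the
decay length is l = sqrt(D_cG sigma eps0 / (theta_c sqrt(D_cG
beta_dark))) ~ 0.20 um; the simulator's measured profile decays with
exactly this l, and its 1/e-interval at peak time is ~0.42 um.  The
fully-stirred value ~0.31 um is what a cross-sectionally coarse
discretization converges to.  Either way, the shielding explains why the
well-stirred tiers, which let the depletion reach the channels directly,
overestimate the response and peak earlier.

## Lumping the activated disc in the 1D tier

Collapsing the activated disc onto the axis admits two readings, both
implemented (``SolverConfig.lws_sink_lumping``).  The default,
``mass_consistent``, gives the Dirac sink the strength
k*_hyd E*_tot(t) cG(z0), so the 1D tier hydrolyzes exactly as much cGMP as
the 3D tiers; its exaggeration then comes only from reading the current at
the unshielded axis value.  The ``concentrated`` variant evaluates the
sink with the volumic rate k*_hyd/eta applied to the disc-averaged E*
surface density at the axis point; this overweights the sink by
~1/(eta pi lambda^2) ~ 8x — the arithmetic a coarse model commits when it
concentrates a surface reaction at a point — and produces the much deeper
local cGMP hole at the isomerization site that extreme 1D reductions
exhibit.  Well-stirred-limit identities (LWS -> GWS under diffusivity
scaling) hold in the mass-consistent configuration, which is why it is the
default.

## Numerics

Backward Euler with Delta_t = 1.5/900 s (900 steps over 1.5 s, the
reference time grid).  Nonlinearities (cyclase, channel, exchanger) are
resolved by Picard iteration to 1e-9 relative per step, with the exchanger
slope at the dark state folded into the constant calcium operator as a
semi-implicit stabilizer (same fixed point, about half the iterations).
The stiff activated-fold hydrolysis stays inside the linear operator as a
per-step diagonal update.  Linear systems use a block-Schur factorization:
batched dense factorization of each cross-section block (the only
inter-block coupling is the sliver), a sparse LU of the Schur complement
on the sliver strip, and per-step refactorization of activated-fold blocks
only while max E* exceeds 1e-9 /um^2.  Starting from the computed dark
state the discrete scheme is stationary to machine precision, and with all
reactions disabled the capacity-weighted cGMP content is conserved to
1e-8 relative (both tested).

Reference resolution: 500 cross-sections (one per disc period), polar
cross-section meshes with 10 rings x 20 spokes (mirror-symmetric about the
sliver mid-angle, so centered photons give theta-symmetric fields to
solver precision), about 100k unknowns per field, roughly two minutes per
run on one CPU.  Tests use 16-40 slices and coarser cross-sections;
NHOM cross-validation runs at n = 20/40/80 chambers.  t_peak is located by
parabolic interpolation through the discrete maximum of the relative-drop
trace; undershoot requires the trace to stay below -0.001% for at least 3
consecutive steps.

## What the scenarios emulate, and what they do not

The canonical scenarios place one photon (SPR) at the center of the disc
at 40% of the height, or ten photons (TPR) at disc centers spanning
40-58% of the height, at t = 0 from the dark-adapted state.  They emulate
a noise-free virtual cone: thermal pigment activation, channel noise,
photon-arrival statistics, the calcium dependence of K_cG reported for
cones, and calcium-regulated opsin phosphorylation are all outside the
model, so agreement of the tiers here says nothing about those effects.
Real cones also taper non-affinely, have incisures and a non-ideal sliver;
the geometry here is the idealized frustum.  Parameters mix species
(striped-bass geometry, mouse-rod diffusivities and channel affinity), as
no complete single-species cone set exists; simulation outputs are
model-hierarchy comparisons, not predictions for a particular animal.

## Known limitations

* The homogenized weak form is a reconstruction; its correctness is
  argued by the symmetry of the assembled bilinear form, the analytic
  sliver-shielding estimates above, and NHOM->HOM convergence, not by
  comparison with the original unpublished formulation.
* NHOM at small chamber counts has a physically thicker sliver
  (sigma*eps_n), so NHOM(n) and HOM agree only as n grows; the desk-scale
  suite asserts monotone convergence at n = 20/40/80 rather than the
  sub-percent 500-chamber agreement, which requires cluster-scale runs.
* The deterministic shutoff reduction is a modeling choice (see above);
  stochastic trial-to-trial variability is available but not validated
  against single-photon response distributions.
* First-order time accuracy: peak-drop values carry O(Delta_t) bias
  (Richardson ratio ~2 is tested); halving Delta_t changes peak drops by
  under 2% at reference resolution.
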