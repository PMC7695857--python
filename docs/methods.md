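# Methods

This note documents the models implemented in `helixbreak`, the defaults
and why they were chosen, what the synthetic event generator does and does
not emulate, and the numerical conventions a user should know before
trusting — or extending — a result.

## Geometry

Chromatin is modelled as straight rods: each segment is a canonical B-DNA
double helix along the x axis with 0.34 nm rise and 34° azimuthal twist per
base pair. Each bp contributes six molecule sites in a plane perpendicular
to the fibre axis: two spherical phosphates (r = 0.228 nm, placed at 1.0 nm
radial distance), two spherical deoxyriboses (r = 0.263 nm at 0.75 nm) and
two ellipsoidal bases (half-axes 0.35 × 0.35 × 0.17 nm at 0.30 nm). Only
the twist angle and the two backbone radii carry model weight: bases are
geometry-only (they count as "DNA molecule centres" for the radical
production cut but never yield breaks), and the helix radius, rise and base
dimensions are the standard B-DNA convention, configurable in
`GeometryConfig`. The AT/CG label of each pair is drawn with equal
probability and is currently bookkeeping only.

Histones are 2.5 nm spheres placed on the fibre axis at the midpoint of
each spacing window (default one per 200 bp). On-axis placement is a
deliberate simplification of nucleosome wrapping: a histone locally
enshrouds the fibre and acts as a perfect radical sink, which is exactly
the scavenging role it plays in the damage model. No fractal folding,
supercoiling or nucleosome geometry is modelled; because all yields are
normalized per Gy per Gbp, the pipeline is scale-invariant in segment
length.

Containers are ellipsoids given by full axis lengths in μm. The cell
preset (nucleus 14.2 × 14.2 × 5.0 μm ≈ 528 μm³, cytoplasm 28 × 28 × 5 μm ≈
2052 μm³, 6.4 Gbp ⇒ 0.012 bp/nm³) reproduces a human fibroblast; note the
two ellipsoids legitimately share the 5 μm z-axis, so containment is
validated as axis-wise ≥ with strictly larger volume. Desk-scale runs use
`fitted_container`, a snug ellipsoid around one segment (default
transverse margin 15 nm in cell mode, 60 nm in plasmid mode) whose margin
sets the effective bp density.

All spatial queries (nearest backbone site, radical culling, encounter
tests) go through lazily built `scipy.spatial.cKDTree` indexes, keeping
query cost sublinear in site count. Nearest-site ties within 1e-9 nm are
broken deterministically: lowest strand, then lowest bp index, then
phosphate before deoxyribose.

## Surrogate track source

The generator replaces track-structure transport with the minimal
stochastic structure the damage chain is sensitive to: spatially clustered
deposits along straight parallel tracks, with co-located radical spawns.
Tracks run along the short (z) container axis with entry points uniform
over the elliptical cross-section. Along each chord, deposits form a
Poisson process with mean linear density 100 /μm (the LET-like knob);
deposit energies are i.i.d. shifted-exponential, 1 eV minimum and 45 eV
mean, chosen so that both sub-5 eV (never breaking) and > 37.5 eV (always
breaking) deposits occur with the default ramp — with that spectrum the
default density corresponds to ≈ 4.5 keV/μm. A transverse Gaussian of
σ = 2 nm stands in for the secondary-electron penumbra. Hydroxyl radicals
spawn at deposit positions with expected count E·G/100 eV, G = 2.5 per
100 eV (the conventional early-time value for OH). No claim is made that
the surrogate reproduces any real particle's LET dependence.

Track count is dose-driven: tracks accumulate until the summed energy over
the nucleus water mass (1 Gy = 1 J/kg, unit-density water) reaches the
target; the crossing track is truncated at the deposit whose running total
lands closest to the target (or dropped entirely if that is closer). This
keeps the realized dose within a small fraction of a percent whenever the
target energy spans many deposits. A consequence of honest desk-scale
dosimetry: a fitted container around 10⁵ bp holds ~10⁻¹⁷ kg of water, so
1 Gy deposits only ~100 eV and produces almost no damage. Meaningful
desk-scale statistics therefore come from kGy doses — the same regime real
plasmid strand-break assays use — and yields are reported per Gy per Gbp,
which the dose-linear generator makes scale-free.

Radicals born farther than d_kill = 9 nm from every DNA molecule centre
are killed at creation; 9 nm is the maximum plausible OH diffusion
distance within the 5 ns chemical stage.

## Radical chemistry

Surviving radicals perform isotropic Gaussian steps (per-axis variance
2·D·Δt, D = 2.8 nm²/ns, Δt = 0.001 ns) until the first of: entering a
histone (scavenged), entering the encounter sphere of a backbone site
(reacted, one encounter event, radical consumed — even if the later
Bernoulli trial yields no break, preventing double-counting), or exceeding
T_chem = 5 ns (timed out). A radical born inside a histone or encounter
sphere terminates at t = 0; histone scavenging is checked before reaction
when both apply in one step. The encounter sphere is the site radius plus
a 0.22 nm reaction radius; among overlapping spheres the closest centre
wins. Steps are discrete with no sub-step root finding — the overshoot
bias this introduces shrinks with Δt and is bounded by a Δt-convergence
test in the suite.

Two implementation choices exist purely to make paired comparisons exact:
displacements are drawn for every radical at every step regardless of
status, so two runs differing only in geometry (histones on/off) give each
radical an identical trajectory; and the indirect-damage Bernoulli uniform
of each encounter is indexed by radical id rather than drawn in encounter
order. Together these guarantee, pathwise, that removing histones never
decreases indirect damage and that break counts are monotone in P_OH at a
fixed seed.

## Damage scoring

Direct: each deposit assigns its full energy to the nearest backbone site
if within R_dir = 0.35 nm, else nothing. Energies are accumulated over the
entire irradiation first; the phosphate and deoxyribose of one nucleotide
pool into a single sugar-phosphate scoring unit; one Bernoulli trial per
unit uses the linear ramp (0 below 5 eV, 1 above 37.5 eV). Pooling the two
backbone molecules is a modelling decision: the break probability is
defined on energy "in the sugar-phosphate moiety", and testing the two
molecules separately would double-count near-threshold units.

Indirect: each encounter breaks its nucleotide with P_OH = 0.405. A
position hit both directly and indirectly keeps one break attributed to
the direct source (direct physics is resolved first; a deterministic rule
is required for the source classes). Duplicate successes collapse.

## Classification

Clusters split at runs of strictly more than 100 unbroken bp (breaks at
bp 0 and 101 share a cluster; 0 and 102 do not) and never span segments.
DSB pairing within a cluster is a maximum-cardinality matching of
opposite-strand breaks with |Δbp| ≤ 10, realized deterministically in
ascending (|Δbp|, bp) order with a cardinality-preserving lookahead —
pure nearest-first greed is provably suboptimal (strand-0 breaks at
{0, 10} against strand-1 at {9, 19}: greedy pairs 10–9 and strands the
ends; the optimum pairs 0–9 and 10–19).

Complexity: ≥ 2 DSBs → DSBpp (three or more DSBs still count as one
DSBpp); one DSB plus an additional break within d_DSB of either paired
break → DSBp; one DSB → DSB; else SSB_cluster. SSBs are counted as
individual unpaired breaks, not clusters. N_cDSB = N_DSBp + 2·N_DSBpp and
N_ncDSB is the remaining paired-DSB count.

Source classes partition DSB clusters: all-direct → DSBdir, all-indirect
→ DSBind; otherwise delete every indirect break and re-pair — if no DSB
survives the damage existed only by virtue of indirect chemistry (DSBhyb),
else DSBmix. This removal test operationalizes a prose definition that is
genuinely ambiguous; it is the one reading that is deterministic and
reduces to the obvious answer on two-break clusters. The scavengeable DSB
fraction is (N_DSBind + N_DSBhyb)/(N_DSBdir + N_DSBmix + N_DSBind +
N_DSBhyb), counting DSBmix as non-scavengeable.

The distant-DSB filter sorts DSB midpoints (mean of the paired bp indices)
per segment and keeps a DSB only if it lies ≥ 10 kbp after the last kept
one, scanning left to right with segment ends as infinite boundaries.

## Repair kinetics

Five pathways are linear chains of enzyme-bound intermediates fed by the
remaining-DSB pool N₀: NHEJ (Ku → DNA-PKcs → Artemis → Pol μ/λ →
XRCC4-LigIV → ligation, 11 rate constants), HR (MRN → CtIP resection →
RPA → Rad51 → D-loop → Pol δ → resolution, 13), SSA (11), micro-SSA (9)
and Alt-NHEJ (9): 53 attachment/detachment constants in total, validated
against a closed schema. Internal steps are reversible; the final step of
each chain releases repaired DNA irreversibly. Irradiation is
instantaneous: the induction term α(L)·(dD/dt)·N_cDSB collapses to the
initial condition N₀(0) = N_ncDSB + N_cDSB with all intermediates zero
(the printed form's units are unusual — α is per Gy per cell yet
multiplies a DSB count — so the induction functional is kept configurable
rather than reinterpreted). An irreparable sub-pool (default fraction
N_cDSB/N₀) is held out of the kinetics and re-added to the reported
remaining-DSB curve, which is therefore monotone non-increasing with a
late-time plateau.

The published values of the 53 constants are not available to this
package; the shipped defaults (per hour; NHEJ forward rates ~2–4 h⁻¹, HR
and SSA an order of magnitude slower, micro-SSA/Alt-NHEJ minor, detachment
one tenth of attachment) are package defaults chosen to give qualitatively
realistic kinetics — a fast NHEJ component with half-time near an hour and
a slow tail — and every shipped test of this module is property-based
(null case, closed-form exponential limit, non-negativity, monotone decay,
conservation, tolerance-halving stability), never a fit to published
curves. Users with a calibrated table load it via JSON.

Integration uses `scipy.integrate.solve_ivp` with the implicit Radau
method (mass-action networks are stiff), rtol 1e-8 / atol 1e-9, dense
output on a 0–25 h grid at 0.1 h. Solver failure raises; state is never
clamped.

γ-H2AX(t) is the Michaelis–Menten transform (default V_max = 1, K_M = 10
DSB-equivalents) of the summed active DNA-PKcs-bearing NHEJ complexes plus
the irreparable pool, which persists bound to repair factors; the default
output is scaled to the curve's maximum ("absolute" mode is available).
Ku, DNA-PKcs, RPA and Rad51 curves are read directly off the corresponding
intermediates.

## Degree of protection

DP = (ln SF₀ − ln SF_x)/ln SF₀ for survival fractions with and without a
radical scavenger at concentration x; the reciprocal fit 1/DP = k/x + y_∞
(ordinary least squares on 1/x) extrapolates to the maximal protection
1/y_∞ at infinite concentration, the experimental analogue of the
simulated scavengeable fraction. A non-positive intercept is returned
flagged as non-physical rather than raised, since noisy data can
legitimately produce it.

## What the generator does and does not emulate

Emulated: spatial clustering of deposits along tracks, dose-linearity,
radical co-location with deposits, the scavenging geometry of chromatin,
and all parameter sensitivities downstream of the event lists.
Not emulated: real proton/photon cross-sections and energy spectra,
secondary-electron transport, LET dependence of radical survival,
inter-radical recombination, species other than OH, base damage, and
supercoiled plasmid topology (plasmid mode is a density/scavenger preset
on the same straight fibre). Passing tests therefore validate the damage
bookkeeping, the classification rules and the kinetics — not absolute
yields for any specific beam quality.

## Problem sizes used in the shipped tests

Module and acceptance tests run segments of 200–5000 bp at 2–6 kGy with a
2 ps chemistry step; the smoke test runs ten replicates of 10⁵ bp at 1 Gy
with the 1 ps default step; oracle suites use 500–1000 random points or
clusters. These sizes were chosen so the full suite exercises every code
path, including the paired-seed monotonicity comparisons, in about a
minute on one core.

## Known limitations

Direct damage is rare under the default surrogate because deposits are
spread over the container rather than concentrated near the fibre as real
track structure would; consequently DSBdir/DSBmix classes are sparse in
pipeline output (the classification logic is instead exercised on
constructed break tables). The discrete-step chemistry carries an
O(√Δt) overshoot bias. The repair defaults are qualitative, not a
cell-line calibration; cell-cycle dependence, dose-rate protraction and
survival prediction are out of scope.
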