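# Methods

This note documents the models implemented in `xsikit`, the defaults and
why they were chosen, the numerical behavior of the solvers, and what the
synthetic-data generator does and does not emulate.

## Scattering model

**Form factor and basis functions.** Gold nanocrystal labels are modeled
as homogeneous spheres of radius R = 7 Å with amplitude
F(q,R) = 3[sin(qR) − qR cos(qR)]/(qR)³ (a 5th-order series is used below
qR = 10⁻³ to avoid cancellation). The gold–gold interference basis is
B(q,d) = F²·sinc(qd); its overall amplitude is deliberately left as a free
scale fitted during inversion, since the absolute gold intensity depends on
concentration and contrast factors the pipeline does not model.

**Debye simulation.** Labeled constructs are coarse-grained to one bead
per base pair on the helix axis plus 0–2 gold beads; radial helical detail
is far below interferometry resolution. The orientationally averaged
intensity is the Debye double sum I(q) = Σᵢⱼ fᵢfⱼ sinc(q·rᵢⱼ) with
fᵢ = wᵢ·F(q,R) for gold and wᵢ for DNA beads. The gold:DNA weight contrast
is 25:1 — large enough that gold terms dominate, as the method requires.
No solvent-excluded-volume or hydration corrections are applied: the
extraction arithmetic cancels the molecule term identically, so only the
gold cross-terms need to be physically sensible.

**q-grid.** Default 0.01–0.35 Å⁻¹, 256 linear points. This spans the
oscillation periods of all distances of interest (2π/d for d = 50–95 Å
gives periods well inside the window) and matches typical small-angle
bench geometry; the source study does not state its binning.

## Interference extraction

I_AuAu = w₁·AB + w₂·U − w₃·A − w₄·B on buffer-subtracted profiles, default
weights (1,1,1,1) assuming equal molar concentrations. When the four
constructs share one conformer ensemble the molecule term and both
molecule–gold cross terms cancel exactly; uncertainties propagate in
quadrature. For real data with concentration error an optional high-q
rescaling step fits w₃, w₄ on q ≥ 0.25 Å⁻¹, where the interference term
has decayed. The free-gold profile is not used in the arithmetic; it is
reserved for form-factor calibration.

## Maximum-entropy inversion

The distribution lives on a uniform 5–150 Å grid with 1 Å step (all
reported junction distances, 54–93 Å, sit well inside). Among all weight
vectors p ≥ 0, Σp = 1 reproducing the pattern to a target discrepancy, the
solver returns the one maximizing S = −Σ pᵢ ln(pᵢ/mᵢ) against a uniform
prior m. The fit constraint is χ²/N ≤ 1 with a ±0.05 acceptance window.

Implementation: for a fixed trade-off multiplier λ the Lagrangian
S − (λ/N)·χ² is maximized by multiplicative exponentiated-gradient updates
(pᵢ ← pᵢ·exp(η·(gᵢ − ḡ)), renormalized), which preserve positivity without
explicit bounds; the overall amplitude is re-fitted by closed-form weighted
least squares at every step, and the step size η adapts by backtracking. λ
is grown geometrically and then bisected until χ²/N lands in the window.
Weights below 10⁻¹² are reported as exactly zero. On grids of ≤ 12 points
the solution matches an independent constrained optimizer (SLSQP on the
entropy objective with the χ² constraint) to ‖ΔP‖∞ < 10⁻⁴ when the window
is tightened (the window is an exposed parameter; at the default ±0.05 the
two answers differ by the window itself).

**Unreachable targets.** χ²/N of pure noise fluctuates with standard
deviation √(2/N) ≈ 0.09 at N = 256, so for an appreciable fraction of
realizations no mixture can reach χ²/N ≤ 1.05 and the literal λ→∞
least-χ² solution would chase noise, fragmenting the distribution into
ripple peaks. The solver instead detects the χ² plateau, sets the
`infeasible` diagnostic (the flag is set exactly when the least achievable
χ²/N exceeds the target), and returns the maximum-entropy solution at the
plateau discrepancy plus two windows — the discrepancy-principle reading
of "least χ²" at its own statistical resolution. No additional smoothness
regularization is applied beyond entropy, which may leave small ripple
(typically ≤ 3–5% of mass, often at the grid edge); the peak-merging step
in the ensemble analysis absorbs ripple below 2% area.

## Ensemble analysis

Peaks are local maxima of the weight vector; boundaries sit at the minimum
between adjacent modes; modes are reported at grid resolution (1 Å)
without sub-grid interpolation, an honest statement of the method's
resolution. Peaks with area < 0.02 (default) are merged into the nearest
retained peak — this suppresses max-ent ripple while preserving total
probability. Populations are renormalized peak areas, and
ΔΔG = RT ln(p_major/p_minor) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ at
T = 298.15 K by default. The measurements being emulated were collected at
5–15 °C and the temperature behind the published "~1 kcal/mol" preference
is not stated, so the standard state is used and exposed as a parameter
(the difference across 278–298 K is ~7%).

## Junction geometry models

Four arms X, B, H, R in cyclic order (X–H and B–R opposite) radiate from a
center; each gold label sits at
reach = gap/2 + bp·rise + axial_offset + salt_shift along its arm, with
11 bp arms (four 22-mer strands), 3.3 Å B-form rise, a 16.3 Å central gap
for open states (from a protein-bound planar crystal structure) and zero
gap for stacked forms. The per-label axial offset of 10.2 Å is an
*effective* value folding the rotational offset into the axial one,
calibrated so the continuous-helix prediction 2·11·3.3 + 2·offset equals
the published 93 Å; the underlying calibration of separate axial and
rotational offsets is in work not reproduced here. The salt-dependent
offset increase is +2 Å at intermediate salt.

Model families for fitting measured distances: planar cross (no free
parameters), square pyramid (apex half-angle; 90° recovers planar),
tetrahedron (fixed), and free arm directions (8 angles, deterministic
multi-start Nelder-Mead seeded from the named presets plus fixed random
starts). Since the families are nested and each optimizer evaluates the
smaller family's optimum as a start, RMSD is non-increasing along
planar ⊂ pyramid ⊂ free. A pyramid fixes the adjacent/opposite distance
ratio at 1/√2 ≈ 0.71 regardless of apex angle, which is why near-equal
measured distances (ratio ≈ 0.95) exclude it. The inter-duplex angle of a
stacked form inverts d = 2L′ sin(IDA/2) with L′ = bp·rise + offset; with
the effective offset this gives ~71° for the 54 Å short pair, higher than
the ~60° canonical X-structure value — a known consequence of folding the
rotational offset into L′, recorded as a limitation.

## Synthetic data

**XSI bundles.** A scenario is a mixture of states, each a mean label-pair
distance with a weight; presets encode the published ensembles
(high_Mg_BH 54/89 Å at 84:16, high_Mg_HR 89/57 Å at 84:16,
intermediate_Mg_BH 61/84 Å, low-salt BR/HR/RX at 93/90/87 Å). The two
high-Mg BR peak positions are not printed in the source study (they
overlap strongly); the preset uses 70/75 Å as a stand-in preserving that
overlap. Per state, 200 conformers are sampled with Gaussian jitter of the
label distance (σ = 5 Å default — the published distributions' widths are
in unavailable supplementary material, so this reproduces the same visual
order of peak width); the jitter enters directly in distance space, the
quantity the interference measures, rather than through explicit
arm-angle/rise perturbations. The same conformer set parameterizes AB, A,
B and U so the extraction cancellation is exact by construction; real data
would break this through inter-sample variation, so passing the
machine-precision cancellation tests says nothing about concentration
matching in practice. Free gold is simulated as two spheres beyond
coherent separation; buffer is a flat 50 a.u. baseline added to every
sample. Noise is Gaussian with σ(q) = noise·√(I(q)·I(q₀)) per exposure
(1% at the low-q anchor), averaged over 10 exposures, with the standard
error of the mean recorded as the profile uncertainty — a
counting-statistics-like model without detector artifacts, radiation
damage or q-dependent systematic error.

**FRET traces.** A continuous-time two-state telegraph path (exponential
dwells; defaults k_I→II = 45.6 s⁻¹, k_II→I = 7.9 s⁻¹, started from the
stationary distribution) is integrated over each frame at 306 fps, so
transition frames carry fractional occupancy. E = 0.14/0.58 for
isoI/isoII; total emission 1000 a.u. with independent per-channel Gaussian
noise of 80 a.u., which makes the two states clearly resolvable as in the
published traces. Intensities are clipped at zero to stay physical, which
biases the low state's apparent E slightly upward (~4% of low-state
acceptor frames clip); no blinking, bleaching or γ-correction is modeled.

## Dwell-time kinetics

Idealization thresholds E at the midpoint of the state means (0.36) and
then deterministically erases runs shorter than 2 frames, shortest-first.
Rates are reciprocals of mean dwell times with first/last (censored)
dwells dropped. Because the idealizer cannot see dwells below the
detection limit, observed dwells are left-truncated; for exponential
dwells E[observed] = τ_d + 1/k, so the estimator subtracts the dead time
τ_d = (min_dwell − 0.5)/fps — with majority-occupancy binning a dwell
yields ≥ min_dwell frames when its true duration exceeds roughly
(min_dwell − 0.5) frames, averaged over frame phase. Standard error is
k/√n_dwells. A residual downward bias remains for the *slower* rate at
strongly asymmetric rates: missed excursions of the fast-exiting state
merge the surrounding dwells, which truncation correction cannot undo
(≈ −15% on k_II→I at the default rates, while the forward rate k_I→II is
recovered within a few percent; simulation-validated against the latent
path in the test suite). A likelihood-based (HMM) idealizer would reduce
this but is deliberately out of scope in favor of a transparent,
assumption-light estimator.

## Problem sizes and determinism

Default problem sizes — 200 conformers/state on a 256-point q-grid,
146-point distance grid, 77×10 s traces at 306 fps — were chosen so a full
condition analyzes in seconds to tens of seconds on one core while keeping
Monte-Carlo error well inside the tolerances of interest. Every stochastic
routine takes an explicit seed and is bit-reproducible given one; pipeline
outputs embed a hash of the run configuration.
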