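# Methods

## Scope and data model

`monofilm` analyses Langmuir-monolayer compression runs: paired arrays of mean
molecular area A (Å²/molecule) and surface pressure π (mN/m), recorded at
fixed temperature while a barrier compresses a spread film.  Rows are stored
in acquisition order (decreasing area); for a compression run this is also
increasing-pressure order, and all analysis happens on that branch.  The CSV
dialect is two columns with the fixed header `area_A2,pressure_mN_m`;
film metadata (components, mole fractions, temperature, label) lives in a
key–value sidecar with the same stem and extension `.meta`.  Duplicate-area
rows are averaged rather than rejected, because real troughs emit them.

## Descriptor extraction

**Compression modulus.**  C_s⁻¹ = −A·(dπ/dA).  Raw finite differences are
unusable at the ±0.1 mN/m accuracy of a Wilhelmy plate, so the derivative
comes from a local least-squares cubic evaluated per point over a sliding
window (default 11 points; exposed as `smoothing_window`).  This handles
non-uniform area spacing, which the uniform-grid Savitzky–Golay filter does
not.  Differentiation starts at the lift-off onset: windows straddling the
kink where the flat zero-pressure foot meets the rising branch otherwise
overshoot the slope by several percent exactly where the modulus peaks.
Under pressure noise the modulus maximum is still biased high (derivative
noise rectifies under the max); widen the window for noisy data.

**Phase class.**  Banding on the modulus maximum follows the conventional
ranges: < 12.5 mN/m gaseous, 12.5–50 liquid-expanded, 50–100 liquid, 100–250
liquid-condensed, above solid.  A pure, total function of one number.

**Lift-off.**  The onset of measurable pressure.  The detector finds the
largest area with π ≥ threshold (default 0.5 mN/m) for a run of 3 consecutive
points — the run guard keeps single noise spikes from defining lift-off —
then refines the onset by a local linear back-extrapolation of π(A) to π = 0
over max(run, 7) points.  Without the refinement the estimate is biased low
by threshold·|dA/dπ|, which exceeds 1 Å² for expanded films.

**Extrapolated area A₀.**  A line is fitted to all pre-collapse points with
C_s⁻¹ ≥ 0.85 × max (the "steepest linear segment" practice) and evaluated at
π = 0.  Raising the fraction toward 1 shrinks the fit region below the
5-point minimum and raises `FitError`.

**Collapse events.**  A collapse is reported at onset: the first point, above
a minimum pressure gate (default 5 mN/m), where |dπ/dA| drops below 0.1 × its
running maximum or where pressure falls on further compression (0.2 mN/m
deadband).  The gate is widened by 3 estimated noise standard deviations
(robust MAD of the smoothing residual) so that a liquid-expanded/condensed
transition plateau sitting exactly at the gate cannot leak through via
jitter.  After an onset, the search re-arms once the slope re-steepens above
3 × the running plateau slope, allowing a secondary collapse — the signature
of an immiscible film in which the less stable component is ejected first and
the survivor collapses at elevated pressure.  A secondary event must lie at
least 0.5 mN/m above the previous one, which suppresses noise re-triggering
on a flat plateau.  An empty result is valid: runs can end before collapse
when the barrier range is exhausted.

**LE–LC transition.**  A local minimum of C_s⁻¹ below 30 mN/m flanked on both
sides by maxima exceeding max(30, 2·min + 20) mN/m.  The prominence guard
keeps noise dips in a liquid film from reading as transitions; because the
profile is truncated at the first collapse, post-collapse plateaus can never
qualify.

## Mixing thermodynamics

The ideal reference at each pressure is A_id(π) = Σ Xᵢ·Aᵢ(π) over the pure
components; the excess area is A^exc = A_mix − A_id and

  ΔG^exc(π) = N_A ∫₀^π A^exc dπ′.

With A in Å² and π in mN/m, 1 Å²·mN/m = 10⁻²³ J, so the conversion to J/mol
is the exact factor N_A·10⁻²³ = 6.02214076.  Quadrature is trapezoidal on a
uniform grid (default 0.25 mN/m), robust to kinks and convergence-testable
(halving the step changes results by < 0.05 %).  Isotherms are resampled onto
the grid by monotone piecewise-linear interpolation — splines overshoot at
plateaus and collapses — with A(0) anchored at the lift-off area so the
integral starts exactly at π = 0 (below lift-off the film exerts no pressure
and the area is read as the lift-off plateau).

For ternary films built by adding a probe lipid to a fixed-ratio binary host,
the default ideal reference is the three-component weighted sum, the direct
generalization of the binary formula.  Because it is a genuinely open
convention whether such films should instead be referenced against the intact
host film, a pseudo-binary reference (probe vs the zero-probe member of the
series) is available via `reference="pseudo_binary"`; the two differ in
meaning, not in sign, for the bundled fixtures.  Analysis defaults to
π = 30 mN/m, the pressure region where monolayer packing corresponds to
bilayer packing; the pipeline sweeps {5, 10, 20, 30, 35} mN/m.

**Miscibility (2-D phase rule).**  Mixed components show a collapse pressure
that varies with composition; immiscible ones collapse independently.  Per
composition the classifier reports *immiscible* when a run shows ≥ 2
collapses with the first at a pure component's π_coll (within a tolerance,
default 1.5 mN/m, reflecting typical isotherm reproducibility), or when a
single collapse is pinned at a pure value with a neighbouring composition
pinned there too; *miscible* when the single collapse lies away from both
pure values or varies across the grid; *partial* otherwise, including runs
truncated before any collapse.  The two-collapse rule deliberately does not
require the second collapse to match the second pure component's value: in a
partially miscible film the surviving component collapses at an elevated
pressure, not at its pure-film pressure.  Pure vertices (X = 0, 1) in a
series are excluded — they are one-component films and would trivially pin
their neighbours.

## Packing geometry

Chain volume and critical length for a saturated chain follow the increment
formulas V = 27.4 + 26.9·n_c (Å³) and l_c = 1.5 + 1.265·n_c (Å), where 27.4
and 26.9 Å³ are the CH₃ and CH₂ volumes, 1.265 Å the projected C–C bond and
1.5 Å the CH₃ radius.  The convention that reproduces the bundled
single-chain reference rows is n_c = chain carbons − 1 (15 for hexadecyl, 17
for octadecyl); the API also accepts explicit (l_c, V) overrides, which is
how the two-chain lipids (DPPC 847 Å³, POPC 910 Å³) and the cis-unsaturated
erucyl chain (24.400 Å, 582.9 Å³ — not reproduced by the saturated-chain
increments at any integer n_c) are stored.

The packing parameter s = V/(a·l_c) is banded into shape classes at 1/3 and
1, with a ±0.05 cylinder band around 1 and a 0.005-wide band just under 1/3
read as truncated cone — an s that rounds to 0.33 is conventionally assigned
the denser class, and a hard boundary would flip on the last printed digit
(the erucyl chain sits at 0.3332).  Complementarity (cone-family with
inverted truncated cone; cylinder with cylinder) is a qualitative geometric
heuristic that rationalizes why single-chain phosphocholines pack favourably
with cholesterol but not with phosphatidylcholines; it is not a
thermodynamic prediction.

## Synthetic data

The generator exists because no raw trough data ships with the package; its
closed forms are the oracles for every analysis stage.

Pre-collapse branch: A(π) = a_coll + (a_lift − a_coll)·((π_coll − π)/π_coll)^γ,
so A(0) = a_lift and A(π_coll) = a_coll exactly.  The implied modulus at
π = 0 is π_coll·a_lift/(γ·(a_lift − a_coll)), which is how fixtures hit a
target C_s⁻¹ max.  Limitations of this one-parameter family, hence of what
passing tests show: its modulus extremum sits at an endpoint of the branch
(for γ ≤ 1 at π = 0, for γ > 1 the continuum modulus diverges toward
collapse), so fixtures cannot place the modulus peak at interior pressure as
condensed films do, and their fitted A₀ lies close to the lift-off area.
A₀ extraction against a genuinely distinct intercept is therefore tested on
a hand-built two-segment fixture (shallow foot + exactly linear steep
branch).  Optional features: an LE–LC plateau of stated width at π_t (the
condensed branch is affinely remapped so a_coll is preserved), a
post-collapse plateau or decline, and a secondary collapse (plateau at
π_coll, linear rise to π₂, plateau at π₂).

Mixtures: A_mix(π) = Σ Xᵢ·Aᵢ(π) − β·X_a·X_b·(1 + π/π_ref), a single symmetric
interaction between a designated pair; β > 0 gives negative excess area
(attraction).  The exact ΔG^exc is −N_A·10⁻²³·β·X_a·X_b·(π + π²/(2π_ref)).
Generated mixed films collapse at the lowest pure π_coll among their
components, so the generator does not emulate composition-dependent collapse;
miscibility fixtures are instead assembled per composition from single-film
specs with prescribed collapse pressures.  Gaussian pressure noise (default
0.05 mN/m in the bundled fixtures, half the plate accuracy) is applied with a
mandatory seed; unseeded generation is an error.  What the generator does not
emulate about real data: hysteresis and relaxation, temperature dependence,
surface-potential channels, correlated (non-white) sensor drift, and any
physically derived equation of state — recovery results on fixtures bound
algorithmic error, not instrumental systematics.

### Bundled fixtures

Single films are parameterized from the measured characteristics of the
studied lipids — the antitumor alkylphosphocholines HePC (miltefosine, C16),
OcPC (C18) and ErPC (C22:1): lift-off 98/70/93 Å², collapse 31/38/44 mN/m at
32/28/40 Å², modulus maxima 41/63/78 mN/m — and from textbook behaviour for
the membrane lipids (DPPC: transition plateau near 5 mN/m, collapse 63 mN/m,
condensed; POPC: liquid-expanded, collapse 50 mN/m; cholesterol: collapse
44 mN/m, C_s⁻¹ ≈ 1000 mN/m, solid).  `ocpc_chol_x07` reproduces the
two-collapse signature (38 then 53 mN/m) of an OcPC-rich cholesterol film.

Mixture fixtures encode the reported interaction patterns as study
conditions: `hepc_chol` uses β = 36.9 Å² so the 1:1 film has
ΔG^exc(30 mN/m) = −2500 J/mol, the reported strength of the
alkylphosphocholine–cholesterol attraction; `normal_membrane` is a
cholesterol/DPPC host at ratio 0.67 (X_chol = 0.67/1.67 ≈ 0.40 of the host
film, the normal-leucocyte model) with a repulsive probe term (ΔG^exc > 0:
drug incorporation unfavourable), and `tumor_membrane` a cholesterol/POPC
host at ratio 0.25 (leukemic-cell model) with an attractive term
(ΔG^exc < 0).  The ternary β magnitude (15 Å²) is chosen so interior
compositions sit a few hundred J/mol from ideality — comparable to the
binary phosphatidylcholine systems and well clear of the < 1 J/mol numerical
floor.

## Numerical choices and problem sizes

Default 400 points per synthetic run (≈ 0.15 Å² spacing), pressure grid
0.25 mN/m, smoothing window 11, cubic local fits; at these sizes the full
test suite and the acceptance script each run in seconds.  Ties and
degenerate inputs: duplicate areas are averaged on read; area jitter up to
0.5 Å² against acquisition order is tolerated; pressures down to −0.5 mN/m
are accepted as sensor noise; resampling beyond an isotherm's usable range
raises `RangeError` naming the limiting film and its maximum usable pressure.

## Known limitations

Compression–expansion hysteresis, relaxation kinetics and temperature series
are out of scope.  The regular-solution interaction parameter is not fitted.
The modulus maximum under noise is biased high at the default window.  The
miscibility classifier is a rule set over collapse pressures, not a
thermodynamic phase construction, and inherits the ambiguity of films whose
pure components collapse at nearly equal pressures.
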