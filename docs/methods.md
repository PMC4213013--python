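# Methods

## Stroke kinematics

A flipper beat is four phases — down stroke, bottom turn, up stroke, top
turn — each accruing a fixed net angle in four degrees of freedom: roll
(about the swimming axis, positive counterclockwise seen from the front),
pitch (about the lateral axis, seen from the side), yaw (about the dorsal
axis, seen from the bottom) and bend (same convention as roll, hinged at the
start of the outer span zone). The neonate program uses absolute phase
durations (0.384 / 0.199 / 0.497 / 0.163 s, period 1.243 s); the juvenile
program uses phase fractions (32.3 / 17.0 / 33.7 / 17.0 %) of a period set
by the beat frequency, plus a 0.5 s setup hold during which the mesh is
frozen and which all averaging discards.

Node motion composes rotations in the stated frame order — roll global, yaw
in the rolled frame, pitch in the rolled-and-yawed frame, bend local — which
is the intrinsic matrix product `Rz(roll)·Ry(yaw)·Rx(pitch)` applied after
the bend rotation about the spanwise hinge. Four spanwise zones
(cumulative bounds 0.14, 0.36, 0.57, 1.0 of span) activate the DOFs
progressively; within an activation zone the weight ramps **linearly** in
span fraction (a smoothstep alternative is configurable). The ramp shape is
a modeling choice: only the zone boundaries are prescribed.

Within a phase the angular rate is constant except over the first 10 % of
the phase (the blend fraction), where it eases along a raised cosine from
the previous phase's steady rate. The four steady rates per DOF solve a
cyclic 4×4 linear system so that (i) every phase accrues exactly its printed
net angle, and (ii) the rate is continuous across all boundaries including
the period wrap. Consequences used by the tests: accumulated down-stroke
roll is exactly −1.15 rad (neonate) and −0.95 rad (juvenile), and the
juvenile pose returns to its start after one period to round-off precision.
Past one period the stroke repeats from the accumulated pose, keeping
trajectories continuous for programs (like the neonate's) with a small
non-zero net angle per beat.

Velocities are central differences of the analytic pose at a 10 µs internal
step, independent of the animation step, and verified to agree with
position central differences at second order.

Meshes are parameterized idealizations (tapered elliptic-thickness flipper
plate, ellipsoidal rigid body with all activation weights zero), since the
original anatomical surfaces are not available; OBJ/STL import/export goes
through trimesh.

## Surface integrals

Thrust, power and heat-transfer coefficients are face-centroid quadratures
(finite-volume surface quadrature) rather than node sums; the two converge
to the same integrals under refinement, and the per-face form makes the
brute-force loop oracle exact. Tractions use the `p·n + τ` sign convention
with thrust positive along the swimming direction and power positive when
the flipper works on the water. The skin temperature in the
heat-transfer-coefficient integral is a single per-part value by default
(per-face values are accepted through the flux field itself). Averages
discard everything before the setup time (the juvenile runs drop the 0.5 s
setup, i.e. the initial 500 steps at 1 ms) and use the 0.01 s sampling
cadence.

## Synthetic flow

The generator stands in for a moving-mesh Navier–Stokes solve and makes no
fidelity claim; it exists so the whole chain runs and the integrators can be
tested end to end. Per face: dynamic pressure `½ρC_p|v·n|(v·n)`, an
added-mass term `ρ C_am L d(v·n)/dt` that produces the pressure pulses at
stroke reversals, skin friction `½ρC_f|v_t|v_t`, and heat flux from a
turbulent flat-plate transfer law `h = h₀ + 0.0296 (k/L) Re^0.8 Pr^{1/3}`
evaluated with the local face speed (floor h₀ = 50 W/K·m² for still water).
`C_p = 1`, `C_f = 0.005`, `C_am = 1`, `L = 0.1 m` are free knobs with
order-of-magnitude defaults. Seawater properties: ρ = 1015 kg/m³,
c_p = 4053 J/kg·K, k = 0.6 W/m·K, μ = 9.68×10⁻³ kg/m·s — the viscosity is
carried verbatim from the source property set although it is an order of
magnitude above typical seawater; it only rescales the synthetic Reynolds
number. Fields are deterministic given the seed (optional multiplicative
noise).

What passing tests show: the integrators are exact against closed forms and
loop oracles, and the synthetic fields reproduce the qualitative structure
(flipper flux ≫ body flux, monotone h with beat frequency, added-mass
pulses at turns). What they do not show: any quantitative hydrodynamic
agreement — published per-run thrusts, powers and heat-transfer
coefficients are used as authoritative inputs downstream.

## Bioenergetics

Whole-body RMR at 30 °C is `m · a·m^b` W with per-mass coefficients
`a = 1.05 W/kg`, `b = −0.25` (whole-body ∝ m^0.75). The level is set so a
36.9 kg juvenile has ≈ 0.43 W/kg (15.7 W), inside the measured leatherback
range reviewed by Wallace & Jones (2008); the coefficients are mandatory
configuration — the model refuses to run on an unconfigured allometry —
because no single canonical pair exists. Temperature scaling is
Boltzmann–Arrhenius with E = 0.76 eV and K = 8.617×10⁻⁵ eV/K (a 20→30 °C
step multiplies RMR by ≈ 2.70). Stroke power converts to metabolic cost at
35 % aerobic efficiency. The internal-heat mode defaults to
`net_of_external_work` (cost minus the useful work exported to the water,
P/η − P) on energy-conservation grounds; `all_internal` (P/η) is provided
because the original treatment is ambiguous — the difference is the
hydrodynamic power itself, at most 1.4 W against ~12–22 W of total heating.

## Heat balance

Geometry: a prolate spheroid trunk with semi-major axis set by the 0.72 m
carapace length and volume by the 0.036 m³ total minus the flipper; the
flipper is a uniform slab whose wetted area is the remainder of the 0.89 m²
total surface (≈ 0.36 m²). Default blubber thickness 12 mm reproduces the
36.9 kg mass from the region densities (1035 core / 980 blubber kg/m³) to
0.1 %. The trunk is discretized into similar-spheroid shells (1-D in the
scaled radial coordinate, exact for a sphere), the flipper into a cell
chain attached to the outermost core shell; the proximal 25 % of the
flipper span is the counter-current heat-exchanger band (dead-tissue
k = 0.531 W/m/K), the distal remainder live muscle (k = 0.622). The
original three-region labeling folds the distal flipper into the CHE's
surroundings; here it is a fourth region so the core summary statistics are
confined to the trunk core proper.

Physics: `∂(ρc_pT)/∂t = ∇·(k(T)∇T) + S` with core conductivity
piecewise-linear through (17 °C, 0.531), (28 °C, 0.622), (47 °C, 50) W/m/K,
clamped outside — the vasomotion surrogate. The source lives in the core:
RMR Boltzmann-scaled at the **local cell temperature** by default
(volume-mean mode available) plus the stroke's internal heat, distributed
uniformly per volume. Boundaries are Robin, `q = h(T_s − T_water)`, with
the film in series with the half-cell conduction resistance, using the
published per-run flipper/body coefficients.

Numerics: implicit Euler with Picard iteration on k(T) and S(T)
(tolerance 10⁻¹⁰ °C, ≤ 60 iterations per step); steady state by
pseudo-transient continuation (growing steps from 10 s) until
max |dT/dt| < 10⁻⁶ °C/s. A final consistent assembly after Picard
convergence makes the discrete energy ledger (stored + lost = generated)
close to solver precision, which the transient bookkeeping test checks at
0.1 %. Default resolution: 24 core + 6 blubber shells + 12 flipper cells
(42 cells); halving cell size moves the mean core temperature by < 0.5 %.
The solver is verified against the uniform-source sphere closed form
ΔT_center = S·R²/(6k) at ≤ 1 %.

The hot-anchor sensitivity run re-solves with the 47 °C anchor quadrupled
and reports `(T_base − T_quad)/T_base × 100` on the °C scale (as the
headline percentage is phrased); the Kelvin-scale figure is reported
alongside, and mean, max and innermost-point variants are all computed
since "core temperature" is ambiguous. The shipped configuration (29
beats/minute, 28 °C water — warm water maximizes the anchor's leverage)
yields ≈ 0.6 % on the mean, comfortably below the 4 % bound.

Water temperatures for the core-temperature maps span 16–31 °C, chosen to
bracket tropical/subtropical leatherback habitat; the original trial
temperatures were not printed, so no quantitative core-temperature
comparison is attempted (the direction — warmer water and faster strokes
both raise core temperature — is asserted instead).

## Limitations

- No blood-perfusion (Pennes) term: vasomotion enters only through k(T).
- Work heat deposits uniformly in the core; a muscle-weighted distribution
  would steepen local gradients.
- The synthetic flow cannot anchor absolute thrust/power/h values; only
  published values can.
- The 1-D shell + chain discretization cannot resolve azimuthal structure
  (e.g. shell channels vs. plastron).
- No behavioral thermoregulation, diving, or anaerobic metabolism.
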