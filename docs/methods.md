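# Methods

## Scope and model

`flashlysis` models the chemistry of pulsed electron irradiation of water
in two loosely coupled parts:

1. **Source geometry** — primary electrons characterized by a joint
   spectral–angular fluence distribution and entry positions on a spherical
   micro-target;
2. **Homogeneous kinetics** — the bulk evolution of radiolytic species
   described by mass-action ODEs over the pulse train.

The package deliberately contains **no track-structure chemistry**: the
inhomogeneous spur/track phase that follows each ionizing event (roughly
the first microseconds) is represented by *primary yields* — G values of
the species that escape intra-track recombination. Two first-class modes
bracket that phase:

- `per_pulse_injection` ("homogeneous from t₀"): the escape yields are
  injected continuously at the instantaneous dose rate while the pulse is
  on. This treats the system as well mixed from the start and is the mode
  used for all trend studies.
- `handoff_5us`: the solver starts at 5 µs from background water plus the
  full-pulse yields, mirroring a hand-off from a track-structure code.

Both label their output metadata. Neither reproduces intra-track kinetics;
consequences are listed under *Limitations*.

## Reaction network

Species carry elemental composition (H, O) and charge so every reaction can
be audited: the balance validator recomputes per-reaction atom and charge
deltas, and the packaged table passes with zero deltas for all 30
reactions. The hydrated electron is modelled as charge −1 with no atoms;
reactions written with it include explicit solvent molecules where needed
so the books balance (e.g. e⁻aq + e⁻aq + 2 H₂O → H₂ + 2 OH⁻).

**Rate-law convention.** The kinetic order of a reaction is fixed by the
unit tag of its rate constant (`M-1s-1` → 2, `s-1` → 1). Dynamic reactants
fill the order slots first; remaining slots are filled by
constant-concentration reactants at their fixed molarity. Thus
HO₂⁻ + H₂O → H₂O₂ + OH⁻ with a bimolecular constant proceeds at
k·[HO₂⁻]·55.3 (an effective 7.5·10⁷ s⁻¹ protonation by solvent, consistent
with the HO₂⁻/H₂O₂ acid-base equilibrium), while the solvent molecules in
the e⁻aq recombination reaction are bookkeeping only. Identical dynamic
reactants follow r = k[A]², with the species consumed at 2r through its
stoichiometric coefficient — the tabulation convention under which the
analytic law 1/[A](t) = 1/[A]₀ + 2kt holds.

**Composition of the default table.** The six-reaction
peroxide/superoxide core (labels 1a–2d) governs the late H₂O₂ and O₂•⁻
evolution. The rest is a standard room-temperature compilation set
(e⁻aq/H•/•OH/H₂/H₂O₂/O₂/HO₂•/O₂•⁻ interconversions) closed by the
acid-base equilibria of water (Kw = 10⁻¹⁴), HO₂• (pKa 4.8) and H₂O₂
(pKa 11.6); each forward/backward pair was checked for detailed-balance
consistency at 25 °C. Provenance is tagged per row in
`src/flashlysis/data/reactions_default.tsv`. H₃O⁺ and OH⁻ are dynamic by
default (the superoxide protonation consumes acid); `with_pinned` switches
any species to a fixed-concentration reservoir for buffered runs.

## Kinetics engine

- **Integrator**: SciPy `solve_ivp` with LSODA (automatic stiff/non-stiff
  switching), restarted at every pulse start/end so the discontinuous
  source never crosses a solver step. Instantaneous pulses are discrete
  concentration increments; grid points falling exactly on a kick time
  report the post-kick (right-limit) state.
- **Tolerances**: rtol 10⁻⁸, atol 10⁻¹⁴ M by default — the state spans
  ~10⁻¹² to 10⁻¹ M (solvent-free dynamic range 10⁻¹²–10⁻³), so a loose
  atol would silently zero the trace species. Output values in
  (−10⁻¹², 0) M are floored to zero; anything more negative aborts with
  the species and time named. The pure-recombination oracle
  (1/C law over 8 time decades) agrees to ~2·10⁻⁶ relative at these
  settings, and the answer is unchanged at rtol 10⁻¹⁰.
- **Unit bridge**: C = G·D/(100·e·N_A) = 1.0364·10⁻⁷·G·D mol/L per gray at
  unit density. G values reported during delivery divide by the *full*
  train dose, so a mid-pulse G is definitionally half of what a
  dose-so-far normalization would give at half delivery.
- **Injection granularity**: within a structured pulse the source is the
  continuous dose-rate profile. Bunch schedules (Δt between bunches) only
  shape the per-electron source-point list — once the mean rate is equal,
  a homogeneous ODE cannot see bunch granularity, so per-bunch injection
  would add cost without information.
- **Time grid**: logarithmic, 20 points per decade from 1 ns to 100 s by
  default, with 30-point linear refinement inside each pulse window.

## Study conditions

The packaged scenarios mirror the four single-pulse conditions of the
study design: 0.17, 1, 5 and 10 Gy per pulse, all 1.8 µs rectangular
(dose rates 9.4·10⁴–5.6·10⁶ Gy/s), with 1/10/50/500 electrons per bunch
and a second 5 Gy variant delivered instantaneously; multi-pulse trains
run at 100 Hz. Water is at neutral pH ([H₃O⁺] = [OH⁻] = 10⁻⁷ M, 25 °C)
with "1 % oxygen", interpreted as 1 % of O₂-saturated water:
[O₂] = 1.25·10⁻⁵ M (a gas-phase 1 % O₂ equilibration gives the same
number; both readings are supported by overriding `o2_M`). The target
sphere radius is 2 µm. Escape yields (per 100 eV): e⁻aq 2.7, •OH 2.8,
H• 0.6, H₂ 0.45, H₂O₂ 0.7, H₃O⁺ 2.7 (matching e⁻aq for
electroneutrality); secondary species start at zero. These are standard
low-LET literature values shipped as a clearly labelled synthetic
stand-in — no claim is made that they match any specific scored
track-structure output.

## Synthetic fixtures

The joint (E, cos θ) fixture reproduces the *structure* of a scored
in-sample electron field: a Gaussian beam component (default peak 3 MeV —
a nominal 5–6 MeV beam after ~3 MeV of collisional loss — spread 0.5 MeV)
concentrated toward cos θ = 1 with weight ∝ exp(κ(cos θ − 1)), κ = 40,
plus an isotropic exponential low-energy tail (scale 0.5 MeV) carrying 30 %
of the fluence, normalized to 32 µm⁻² Gy⁻¹ total. Weights are evaluated
analytically on the bin grid, so regeneration is byte-identical by
construction. The fixture preserves the qualitative energy–direction
correlation (exact grade correlation ≈ 0.6, matched by sampled draws
within Monte-Carlo error) but does not reproduce any measured spectrum;
tests built on it validate sampling machinery and trends, not absolute
source properties.

Within-bin values are drawn uniformly — binned scorings carry no
sub-bin information, and uniform is the unique assumption that adds none.

## Measurements

Trend metrics are computed per scenario on a grid extended to 10⁴ s: the
•OH half-fall time (first time after the peak at half the maximum,
log-time interpolated) and the O₂•⁻ lifetime proxy (time to 10 % of peak).
The long horizon is needed because at 0.17 Gy superoxide survives at nM
levels where its disproportionation (via the 9.7·10⁷ M⁻¹s⁻¹ HO₂•/O₂•⁻
channel at an HO₂• fraction of ~6·10⁻³ at pH 7) takes minutes. Both
metrics decrease strictly and monotonically with dose-per-pulse under the
default chemistry.

## Known limitations

- **Pulse-structure sensitivity is overstated.** Under
  homogeneous-from-t₀ injection, the 5 Gy structured and instantaneous
  deliveries differ by up to ~3 % at t ≥ 10 ms (worst in HO₂•; O₂•⁻ and
  the acid/base pair ~1.5 %). The effect is first order in pulse width:
  the e⁻aq lifetime against O₂ scavenging at 1.25·10⁻⁵ M is ~4 µs,
  comparable to the 1.8 µs pulse, so the branching between scavenging and
  radical–radical recombination during delivery genuinely depends on the
  temporal profile. In a full track-structure treatment the first
  microseconds are dominated by intra-track recombination common to both
  deliveries, which suppresses this difference; a homogeneous model cannot
  reproduce that suppression.
- Absolute concentration/G levels depend on the stand-in escape yields and
  the compilation reaction set; only trends and internal consistency are
  asserted by the test suite.
- No electron transport or energy deposition is modelled inside the
  sphere; the dose-threshold electron count requires a caller-supplied
  mean deposit per electron.
- No LET, temperature, or scavenger (cellular milieu) dependence; pure
  water with dissolved O₂ only.
- Pulse shapes other than rectangular (and Dirac) are not implemented.
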