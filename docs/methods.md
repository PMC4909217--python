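# Methods

## The model

`ifsim` simulates the elongation phase of intermediate-filament (IF)
assembly: pre-formed unit-length filaments (ULFs) diffuse in a periodic box
and irreversibly join end to end, so the filament count can only fall and
the total number of ULFs is conserved.  Lateral assembly (tetramer → ULF),
subunit exchange, breakage, and bundling are outside the model.

A filament is a chain of beads of diameter *d* = 11 nm; one ULF is four
consecutive beads.  The model is athermal: there are no potentials, and a
configuration is legal iff

* every bond length lies in [0.8, 1.2] *d*, and
* every angle between consecutive bond vectors is at most α
  (15° for vimentin/desmin, 25° for keratin K8/K18).

Torsions are free, and chains are ideal (no excluded volume): for the
stiffness and lengths simulated here, contour lengths stay far below
lp³/d², the regime in which self-avoidance does not alter chain statistics.

### Dynamics

One Monte Carlo *sweep* attempts exactly one trial move per bead, in a
fresh random permutation.  A trial move displaces one bead along a uniform
random direction by a magnitude uniform in [0, 0.1 *d*] and is accepted or
rejected by the geometric rules above.  A sweep corresponds to roughly
1 ns of real time (a constant imported from an external
Brownian-dynamics comparison, not recomputed here).

After every sweep an annealing pass runs: any two filament ends on
different filaments closer (minimum image) than the maximum bond length
1.2 *d* are candidates; candidates are processed in random order, each end
reacting at most once per pass, and a merge succeeds iff the new bond lies
in the bond window and both junction angles satisfy the reaction angle
(equal to α by default).  Merging never displaces beads — the gap vector
becomes the new bond — so the mechanical state of both partners is
preserved.  Ring closure (self-annealing) is forbidden.

### The angular measure

The stationary distribution of a hard-constraint Metropolis chain is
uniform over the legal configuration set, which makes cos θ (θ the bond
angle) uniform on [cos α, 1].  That measure yields an emergent persistence
length of ≈ 650 nm at α = 15° and ≈ 237 nm at α = 25° — *not* the
experimentally motivated 1000 nm / 333 nm this model family is calibrated
to.  The calibration is reproduced exactly when the scalar bond angle
itself is uniform on [0, α] ("the bond angle fluctuates freely within α"):
the freely-rotating-chain prediction is then
lp = −b̄ / ln(sin α / α) ≈ 986 nm (α = 15°) and ≈ 354 nm (α = 25°) with
b̄ = 1.026 *d*.

`ifsim` therefore defaults to the **uniform-angle measure**
(`angle_measure="uniform-angle"`), implemented as a purely geometric
Metropolis factor Π sin θ_old / sin θ_new over the (at most three) angles a
move changes; no energies or temperatures are introduced.  The flat
measure remains available as `angle_measure="uniform-cone"`.  Two
consequences are documented rather than hidden:

* the radial bond measure is r²-weighted either way, giving the mean bond
  length b̄ = 1.0264 *d* (the value the bond window was designed for);
* the move acceptance rate at α = 15° drops from ≈ 0.62 (flat measure,
  the canonical "about 2/3") to ≈ 0.55, because bending moves pay the
  sin-ratio factor.  The ~2/3 acceptance and the 1000 nm calibration are
  mutually exclusive properties of one ensemble; `ifsim` keeps the
  calibration, and its test suite asserts the ≈ 2/3 band only for the
  flat-measure variant.

The factor sin θ diverges as θ → 0; the ratio is regularised by flooring
sin θ at sin(0.5°) (`min_reg_angle`), which distorts only configurations
straighter than 0.5° and changes ⟨cos θ⟩ by O(10⁻⁶), but lets a perfectly
straight initial ULF start bending.

## Persistence-length calibration

An isolated chain's equilibrium ensemble factorises bond by bond (each
angle independent, torsion free, radius r²-weighted), so `ifsim` includes
an exact direct sampler (`sample_equilibrium_chain`).  The dynamic
estimator `simulate_single_filament_rg` runs `n_replicas` (default 32)
independent MC trajectories, each initialised from an exact draw, and
averages Rg² across them; the standard error comes from the spread of
replica means, which are independent by construction.  This replica design
is essential at desk scale: the slowest bending mode of a 64-ULF chain
relaxes in roughly L⁴/(D_bead · b · lp · π⁴) ≈ 10⁹ sweeps, so no
single-trajectory time average of affordable length is reliable there.
The direct and dynamic estimators are cross-checked against each other on
short chains, where plain time averaging does converge.

Fitting uses the closed-form worm-like-chain expression

    ⟨Rg²⟩ = lc·lp/3 − lp² + 2lp³/lc − (2lp⁴/lc²)(1 − e^(−lc/lp)),

evaluated by a series branch for lc/lp < 10⁻² (leading term lc²/12 with
corrections 1 − t/5 + t²/30 − t³/210) to avoid catastrophic cancellation.
The contour length entering the fit is the *effective* discrete contour
b̄·√(N² − 1) for an N-bead chain: a discrete rod has
Rg² = (N² − 1) b̄²/12, so using the naive (N − 1) b̄ would bias the shortest
grid point (2 ULFs) by +29% and, through its small error bar, drag the
whole fit.  The default grid is 2–64 ULFs (log-spaced), ~N²/2 sweeps per
replica per point; `fit_lp` is a standard-error-weighted least-squares fit
over lp with a coarse log-grid start.  With these defaults the fit
recovers lp = 990 ± 40 nm at α = 15° and 356 ± 15 nm at α = 25°
(asymptotically 991 / 356), against the nominal calibration values of
1000 and 333 nm.

## Assembly kinetics at desk scale

The published full-scale runs use 10³–10⁵ ULFs and 10⁶–10⁹ sweeps.  The
package reproduces the *intensive* kinetic quantities at reduced size,
exploiting the model's own validated scaling: the number of sweeps to
reach a given mean length ⟨l_n⟩ = n₀ / (filament count) scales as 1/c, so
the product c·sweeps is concentration-invariant, and length distributions
at fixed ⟨l_n⟩ are concentration-independent.  The test suite and the
acceptance script run n₀ = 100 ULFs at 17.5–70 g/l equivalent
concentration with 3–8 seeds per condition; these sizes were chosen so a
single-CPU battery finishes in minutes while keeping the sweep-count
estimators' seed-to-seed scatter (~8–14% per run) small against the
asserted tolerances.  At n₀ = 150 and 17.8 g/l the engine reaches
⟨l_n⟩ = 5 in 1.96×10⁶ sweeps, within 10% of the full-scale reference value
1.77×10⁶ — reassuring, since the absolute reaction-pass timing (once per
sweep) is a resolution choice, not a fitted quantity.

### Neighbour search

Reactive-end detection uses a periodic cell list (cell ≥ 1.2 *d*) wrapped
in a Verlet pair list: every 5 sweeps all end pairs within
1.2 *d* + 2·5·0.1 *d* are cached, and between rebuilds only cached pairs
are distance-checked.  Beads move at most 0.1 *d* per sweep and merges
never change wrapped coordinates, so no contact can appear undetected
between rebuilds; the public `detect_reactive_pairs` always computes the
exact set and is tested against an all-pairs oracle.  Boxes too small for
a 3×3×3 cell grid fall back to the all-pairs scan.

Coordinates are stored unwrapped (Rg and contour length are computed
directly); periodicity enters only through minimum-image distances.  When
two filaments merge across the boundary, the absorbed filament is
translated by the image offset so the new bond is contiguous in unwrapped
coordinates.

## Synthetic data

`make_traced_lengths` emulates traced filament-length tables by
constant-kernel stochastic coalescence — start from n·⟨l_n⟩ monomers,
repeatedly merge uniformly random pairs until n clusters remain — which
reproduces the merge-anybody statistics of length-independent annealing
and conserves the mean exactly.  It does *not* model tracing error,
surface-deposition bias, imaging noise, or the length-dependence of
diffusion, so tests passing on it validate the analytics, not the
microscopy.  `make_calibration_points` draws WLC curves with optional
multiplicative Gaussian noise; `make_reactive_pair` builds two-ULF
reaction fixtures with exact gap and junction angle.  All generators are
bit-reproducible from their seeds.

## Numerical choices and degenerate inputs

* All lengths are nm, concentrations g/l, volumes μm³, times s.  One ULF
  traces 60 nm; each annealing step adds the 42.7 nm axial repeat (ends
  interdigitate ~17 nm), giving the conversion i = (L − 60)/42.7 + 1,
  kept as a real number internally and rounded half-up only in reports.
* The ULF mass constant 2.85×10⁻¹⁸ g (≈ 32 monomers × 53.7 kDa) maps
  (n₀, box volume) to equivalent protein concentration; it reproduces all
  published (c, V, n₀) bookkeeping triples within 3%.
* Histogram bins are left-closed right-open with edges at integer
  multiples of the bin width in ULF units starting at i = 1;
  mass-weighted histograms weight by traced length in nm.
  Persistence-length binning (multiples of lp) is length-weighted.
* Angle tests compare squared cosines against cos²α with a positive-dot
  guard, restricting the engine to α < 90°; parameter validation enforces
  this at construction of the kernel inputs.
* The merge acceptance applies the geometric criteria only (no sin-ratio
  factor); the two junction angles it creates re-equilibrate within a few
  sweeps, and merge events are rare relative to moves.
* Targets such as ⟨l_n⟩ = 5 are integerised as a filament-count threshold
  ⌊n₀/⟨l_n⟩⌋; the run stops the first time the count reaches it.
* Empty length sets, targets above n₀, non-positive parameters, stale
  reaction pairs, and contradictory box specifications raise typed errors
  (`ValueError`, `StalePairError`, `ConfigError`).

## Known limitations

* The 1 ns/sweep time constant is taken as given; absolute times inherit
  its uncertainty (hydrodynamic interactions alone shift short-range
  dynamics by ~25%).
* Excluded volume, bending energetics, polarity, and filament–filament
  association are not modelled; conclusions are limited to dilute,
  annealing-dominated elongation.
* The uniform-angle measure is a reconstruction: the printed calibration
  (lp = 1000/333 nm at α = 15°/25°) and the printed algorithm (flat
  geometric acceptance) are mutually inconsistent, and this package
  resolves the conflict in favour of the calibration, documenting the
  acceptance-rate cost above.
* Reaction passes run once per sweep (`anneal_every` is configurable);
  absolute sweep counts to a given mean length depend weakly on this
  resolution choice, intensive ratios do not.
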