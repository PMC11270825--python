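# Methods

## The models

### 1D discrete-state chain

The chain is a list of N glycosidic linkages; linkage i carries a state
s_i ∈ {0, …, m−1} with relative energies E_0 = 0 ≤ E_k (kJ/mol). Sites are
equivalent and non-interacting, so the model isolates one question: how
does the conformer energy ladder of a *single* linkage shape the pattern
of conformational states along a chain? States are the conformers of the
linkage free-energy map — the *exo-syn* ground state plus the *anti*-φ
and *anti*-ψ minima — and systems whose maps lack a genuine *anti*-φ
minimum reduce to two states.

Dynamics are Metropolis: pick a site uniformly, propose a uniformly chosen
*different* state (the proposal excludes the current state; either
convention leaves the stationary distribution untouched, one had to be
fixed for reproducibility), accept with probability min(1, exp(−ΔE/k_BT)).
The chain starts with every site in state 0. Because sites are
independent, equilibrium is a product of single-site Boltzmann
distributions — the test suite verifies this by χ² against the exact
weights and by exact enumeration of all 3⁶ configurations of a 6-linkage
chain.

The observable is the run-length statistic L of one configuration: the
total number of ground-state sites divided by the number of maximal
ground-state runs (runs cut by the chain ends count as runs; a
configuration with no ground-state site scores 0). L is computed per
sampled configuration and then averaged. For an infinite chain the
equilibrium run lengths are geometric and E[L] = 1/(1 − p₀) with
p₀ = 1/Σ_k exp(−E_k/k_BT); this closed form is used as an internal oracle
throughout. For chains not much longer than 1/(1 − p₀) end truncation
biases the estimate *below* the infinite-chain value — visible in the
two-state 18.4 kJ/mol system, where a 5000-linkage chain yields L ≈ 1550
against an infinite-chain 1680.

### Coarse-grained 3D chain

Each residue contributes three backbone atoms (C_n, C_1, O); bond lengths,
bond angles and the through-ring dihedral O–C_n–C_1–O are frozen at their
MD-averaged values, leaving two torsions per linkage,
Φ = C_n–C_1–O–C_n and Ψ = C_1–O–C_n–C_1, as the only degrees of freedom.
The chain energy is the sum of per-linkage values read off a (Φ, Ψ)
free-energy map at the current bin — no bonded deformation terms, no
nonbonded attraction. The single interaction coupling distant parts of
the chain is a hard-sphere excluded volume: a move is rejected if any
atom pair separated by more than 3 backbone positions comes closer than
the clash cutoff (default 0.4 nm). The 3-position exemption covers the
pairs whose distances are fixed (or nearly fixed) by construction; the
source text of the model says only "non-neighboring atoms".

Moves: linkage uniform; proposal bin uniform over unmasked map bins; new
dihedrals are the proposal bin's center (the map *is* the energy model —
no sub-bin interpolation); Metropolis on the map-energy difference, then
the clash check, a clash counting as a rejected move. A uniform symmetric
proposal plus Metropolis guarantees that, with clash checking disabled,
the stationary per-linkage distribution is exactly the map's Boltzmann
distribution with independent linkages — the model's independence
assumption made literal, and verified by χ² and an adjacent-linkage
contingency test.

Implementation notes: draws are made in per-interval batches in the fixed
order (site array, proposal array, uniform array) from one seeded
generator, so runs are bit-reproducible; batched proposals are
pre-screened against pre-segment states, and any site that changes state
has its later in-segment moves re-enqueued and re-evaluated against the
live state, which makes the batched chain *identical* to the naive
sequential one. The total map energy is tracked incrementally and
re-derived from scratch at every sample; both series are stored and must
agree to 1e-9. With the clash check disabled the geometry does not
influence the dynamics, so coordinates are only rebuilt at sampling
times.

Chain building uses the standard internal-coordinate (NeRF) construction
with the IUPAC torsion sign convention; edits rotate the downstream part
rigidly about the C_1–O and O–C_n bonds. Conservation of every fixed
internal coordinate under arbitrary edit sequences is asserted to 1e-6.

## Free-energy maps

Maps are regular periodic grids over one 360° period per axis (no
duplicated endpoint), canonicalized to [−180, 180); both [−180, 180) and
[0, 360) input conventions are accepted. After normalization the global
unmasked minimum is exactly 0. Bins absent from the input file or
carrying a non-finite energy are masked: never proposed, treated as
infinitely high for minima finding, but counted in area denominators
(an unsampled region is an inaccessible one). Minima are bins not higher
than any of their eight periodic neighbours and strictly lower than at
least one; neighbouring equal-energy qualifiers (a well center falling
exactly between two bin centers) merge into a single record, and a flat
map has none. Minima above 45 kJ/mol (just above the largest tabulated
conformer energy, 39.6) are dropped as noise by default.

Conformer classification follows the map-geometric definition: the global
minimum is *exo-syn*; a secondary minimum whose ψ-like coordinate stays
within 45° (circular distance) of the main minimum while φ departs is
*anti*-φ, the converse *anti*-ψ, ties resolved toward the
better-conserved coordinate. The 45° default reflects that tabulated
anti minima sit within ~30° of the matched coordinate.

The φ→Φ axis calibration is a pure circular shift (slope 1): the mean
squared wrapped residual is scanned on a 1° then 0.1° grid and polished
by iterating the circular mean of the residuals, avoiding branch-cut
artifacts of naive regression on angles; residual spreads above 30° log
a warning that a shift alone may not describe the pair.

## Polymer statistics and persistence length

Bond vectors join consecutive glycosidic O atoms; b is the
trajectory-mean O–O distance and the contour length is l_c = b × n_bonds.
(The bond-count convention makes the bond subchain's rod limit exactly
l_c; the alternative residue-count convention differs by O(1/n).)
C(n) is the frame- and site-averaged cosine between bonds n apart.

Three estimators, one result type (`PersistenceEstimate`):

* `acf-fit`: unweighted least squares of log C(n) over the window of
  consecutive n ≥ 1 with C(n) ≥ 0.05 (points at or below the noise floor
  excluded); uncertainty from the slope covariance. The floor and window
  rule are the simplest defensible protocol and are exposed as an
  argument.
* `e2e-WLC` and `Rg-WLC`: bracketed root finding (Brent, on
  l_p ∈ (1e−4 l_c, 1e4 l_c)) of the Kratky–Porod and Benoit–Doty closed
  forms. Both forms are evaluated in cancellation-free factored shapes
  (2 l_p²(t + expm1(−t)) with t = l_c/l_p, and l_p² g(t) with a Taylor
  series for t < 0.05), which keeps the forward–inverse round trip below
  1e-6 relative error over l_p/l_c ∈ [0.01, 100]. Inputs at or beyond
  the rigid-rod limits (⟨e2e²⟩ ≥ l_c², ⟨R_g²⟩ ≥ l_c²/12) return an
  infinite-l_p sentinel with a warning.

`persistence_summary` measures everything on the bond-defining O-atom
subchain so that all three estimates describe the same polymer object,
and evaluates R_g along the interpolated contour (8 points per bond)
rather than on the bare points: the R_g of 10 discrete points differs
from the continuous-contour R_g that the Benoit–Doty expression describes
by ~10% (rod factor (N+1)/(N−1)), which would otherwise dominate the
error budget of short chains. The package-level `end_to_end` and
`radius_of_gyration` functions remain plain all-atom observables for
reporting. Uncertainties are standard deviations over 5 equal trajectory
blocks, propagated through the inversions by blockwise re-estimation.

Estimators consume true mean *squared* quantities; where the source
analysis equated e2e with ⟨e2e²⟩^1/2, this package computes the mean
squares directly.

## Synthetic data: what it emulates, what it does not

`make_gaussian_fem` builds maps as a flat plateau minus isotropic
Gaussian wells (toroidal distance), with analytically known well
positions and depths — emulating the multi-minimum topography of real
glycosidic maps, not their anharmonic shapes, basin asymmetries or
masked unsampled regions. Defaults: grid step 2°, plateau 45 kJ/mol,
well width 18° (the Gaussian width typical of the metadynamics bias that
produces real maps). The packaged conformer table supplies the nine
force-field × linkage ladders used by the 1D model, with the three
entries that are not genuine minima flagged as such.

`make_discrete_wlc` generates freely rotating bead chains with a *fixed*
bend angle per bond (cos θ equal to the requested mean, azimuth uniform),
so C(n) = ⟨cos θ⟩ⁿ exactly in expectation and the target
l_p = −b/ln⟨cos θ⟩ is known in closed form.

Passing tests on these generators shows the samplers converge to the
distributions the maps define and the estimators recover stiffness that
is genuinely there; it does not validate any particular force field's
map, nor chain behaviour dominated by features the generators lack
(solvent, attraction between residues, branched topologies, ring-pucker
heterogeneity beyond what a map already encodes).

## Study sizes and numerical choices

Run-length computations use 2000-linkage chains with 20 200 sweeps
(burn-in 200, sampling every 10) for the three-state systems and a
5000-linkage chain with 120 000 sweeps (burn-in 20 000, sampling every
200, ≥500 decorrelated samples) for the two-state system; relaxation of
the independent-site model is fast and verified by the equilibrium tests.
The chain-length scaling study samples a single-well map (depth
20 kJ/mol, width 18°, grid 4°) with extended zigzag geometry at chain
lengths 10–160; this places l_p ≈ 8 nm ≈ 17 bonds, so the scan spans the
rod-to-coil crossover where the worm-like-chain predictions are actually
informative. The default backbone geometry (0.29/0.141/0.143 nm,
116°/117°/111°) is a placeholder in the physically sensible range —
production use should supply per-force-field MD averages via the
geometry config.

Degenerate inputs are defined rather than left to chance: flat maps have
no minima; a single-state 1D model never moves (warning, not error); a
single-bin map freezes the CG chain; constant series have a δ-function
autocorrelation; negative area thresholds give 0.

## Known limitations

* Unbranched homopolymers only; one map for all linkages.
* No attractive interactions and no solvent — the hard sphere is the
  only excluded-volume physics, so dense-coil regimes are approximate.
* Nearest-bin energies mean the map's grid resolution bounds the
  torsional resolution of the sampler.
* L approximates a persistence scale only insofar as within-minimum
  flexibility is negligible; systems that are flexible inside the main
  basin can have short l_p despite long L.
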