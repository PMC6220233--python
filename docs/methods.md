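# Methods

## The multiscale Hamiltonian

The package samples a fine-grained model coupled to an accelerated
coarse-grained (CG) model of the same system.  The total potential is

    V(r_MM, r_CG) = V_MM(r_MM) + V_CG(r_CG) + k_MMCG |chi_MM(r_MM) - chi_CG(r_CG)|^2

where chi projects each model onto a shared K-dimensional collective-
variable space.  For protein complexes the CVs are the K inter-molecular
Cα-pair distances closer than 12 Å in the starting structure; for the
analytic toys chi is the coordinate itself.  The square bracket is read
as the squared Euclidean norm of the K-vector difference — pair distances
are the only functional form consistent with using atom pairs as the
variables, and the norm is the only reading that makes the exchange
criterion below a valid Metropolis rule.

At `k_MMCG = 0` the coupling vanishes identically, so the zero-coupling
replica samples the fine model's own Boltzmann distribution.  That is the
entire point of the construction: the CG model may be crude, hot and
heavy; none of its bias survives at rung 0.

## The CG force field

Built from a structure's Cα sites by `cgforge`:

| term | form | defaults |
|---|---|---|
| elastic network (intra-group) | (k/2)(r − r₀)² for pairs with r₀ < cutoff (strict) | k = 0.75 kcal/mol/Å², cutoff 12 Å |
| inter-group attraction | ε[(r_m/r)¹² − 2(r_m/r)⁶], r_m = reference distance, pairs with r₀ ≤ 15 Å (inclusive) | ε = 0.03 kcal/mol |
| soft boundary (per LJ pair) | (k_b/2)(r − onset)² for r > onset, onset = r_m + 12 Å | k_b = 5 kcal/mol/Å² |

CG bead mass defaults to 10⁴ amu and the CG thermostat to 1000 K
(adiabatic separation: heavy ⇒ slow, hot ⇒ barrier-free).  The ½ in the
harmonic forms is a convention choice, applied consistently in code and
tests.  Strictness at the cutoffs (ENM strict `<`, LJ selection inclusive
`≤`) is likewise a documented convention; boundary cases are tested.
At the reference coordinates every term is at its minimum, so the
reference is a stationary point of V_CG by construction.

## Dynamics and replica exchange

Both models are propagated by the BAOAB splitting of Langevin dynamics;
with zero friction the integrator reduces exactly to velocity Verlet
(energy-conservation test).  Units are kcal/mol, Å, fs, amu and K with
k_B = 0.0019872 kcal/mol/K; amu masses are converted once so that
acceleration = force/mass (1 kcal/mol/Å on 1 amu = 4.184·10⁻⁴ Å/fs²).
Analytic toys run in natural units (k_B = 1, mass 1).

A campaign holds one fine replica per rung of a coupling ladder.  The
shipped 16-value ladder (0 … 0.098 kcal/mol/Å²) is the default preset;
`scaled_ladder` reuses its shape for toy problems.  Every
`exchange_interval` steps, neighbouring rungs of alternating parity
attempt a swap with

    p_mn = min(1, exp(Δ_mn)),   Δ_mn = β (k_m − k_n)(B_m − B_n),

where B = |chi_MM − chi_CG|² is the k-free CV mismatch of the replica
currently at the rung.  Using the k-inclusive coupling energy here would
double-count k and violate detailed balance; with the k-free mismatch the
rule is the standard Metropolis criterion for swapping k assignments
(the energy change of a swap is −(k_m − k_n)(B_m − B_n)), which the
detailed-balance test verifies empirically on an enumerable toy.
Bookkeeping swaps k values, not configurations; the two are equivalent.

Two coupling topologies are implemented:

* **adiabatic** (default, the production scheme): a single CG trajectory,
  heavy and hot, feels no counterforce from the fine replicas; each fine
  replica is driven toward the time-matched CG configuration.  This is an
  approximation — its error is what the toy validations quantify.
* **symmetric** (validation only): one CG copy per replica, forces acting
  both ways, one temperature.  Sampling is then exactly canonical in the
  joint system, giving closed-form targets for k > 0 rungs.

Randomness: one seed per campaign, split into independent substreams per
replica, for the CG copy and for the exchange draws; identical seeds give
bit-identical logs.

## Analytic validation systems

* **Coupled harmonic** — V_MM = (a/2)x², V_CG = (c/2)y², coupling k(x−y)².
  Closed forms: Var(x) = 1/(βa) at rung 0; in symmetric mode at coupling
  k, Var(x) = β⁻¹(c+2k)/(ac+2k(a+c)).  Standard errors for variance
  comparisons use an autocorrelation-derived effective sample size.
* **Double well** — V = h(x²−1)², default h = 16 k_BT: large enough that
  plain dynamics essentially never crosses within the test budgets (the
  Kramers rate ≈ (8h/2πγ)e^(−βh) ≈ 10⁻⁶ per time unit), small enough
  that the hot CG copy (10× temperature) diffuses freely.  The reference
  density is computed by trapezoid quadrature of e^(−βV) with an explicit
  tail-convergence check.  The benchmark compares the rung-0 histogram
  with the reference via a reference-weighted RMS free-energy error over
  |x| ≤ 1.5 (weighting by reference mass keeps one-count edge bins from
  dominating an otherwise converged profile) and reports worse-well /
  better-well occupancy ratios for both the campaign and a plain run at
  the matched step budget.  The toy ladders scale the shipped 16-rung
  shape to a top value of k_max = 1·a (harmonic) and 8/β (double well) —
  chosen so the top rung's restoring force exceeds the maximum barrier
  force and the rung-to-rung Δ stays of order one.

## The synthetic two-domain/binder complex

`make_two_domain_complex` emulates a tandem two-domain protein whose
domains are joined by a flexible linker and bound bidentately by a third
small domain.  Domains are serpentine bead blocks on a 3.8 Å lattice with
0.25 Å seeded jitter; the binder block sits under the inter-domain seam
within native-contact range of both domains; the linker runs from an
anchor on the distal domain's top face to an attachment bead on the
proximal domain (selectable: native = far-top corner, far = binder-side
far corner, side, or an explicit index), ending in a side-chain-tip bead
whose anchor-to-anchor span d_linker can be pinned exactly.

The fine model is a bead-spring chain system: harmonic bonds (20
kcal/mol/Å²), soft angles on the linker only (2 kcal/mol/rad², θ₀ = 2.2
rad), Gō-like 6–12 native contacts read off the native pose (intra-domain
1.0 kcal/mol within 8 Å; binder–domain contacts within 10 Å at a shallower
depth, see below), r⁻¹² excluded volume (σ = 4 Å) and a soft spherical
confinement (reference extent + 12 Å, 1 kcal/mol/Å²) that mimics finite
concentration so unbinding is reversible.  Masses are 110 amu per bead
(Cα-scale); dynamics use 10 fs steps with 1 ps⁻¹ friction at 300 K.

The binder–domain contact depth required calibration.  At 1.0 kcal/mol
per contact the interface is effectively permanent on test timescales
(every design saturates at a bidentate fraction of 1), while much below
~0.5 kcal/mol the complex is transient rather than marginal.  The default
is 0.6 kcal/mol (≈1 k_BT per contact): the binder detaches and rebinds
several times per nanosecond, so the bidentate fraction is an equilibrium
property with enough dynamic range to resolve linker-design differences —
the stated purpose of the marginal-stability regime.  The scan classifies
frames with a 6.5 Å bead-contact criterion (≈1.6 bead diameters,
i.e. actual surface contact) rather than the looser 8 Å default of the
general classifier, which saturates for any nearby binder.

**Linkage variants.**  The force field (native contacts and rest lengths)
is always defined on the native bidentate pose; changing the linkage
changes the *initial state*, exactly as re-linked laboratory constructs
keep their binding surfaces but start from a remodelled geometry.  If the
requested linker cannot span its anchors (span > 0.98 × contour), the
proximal domain is rotated about its centroid until connection is
possible — displacing it from its bound orientation — and if even that
fails the build raises a construction error (the linkage cannot be
connected).  Linker bonds always rest at 3.8 Å; strain lives in the
configuration, never in the parameters.  The initial linker conformation
is a Brownian-bridge coil biased away from the binder.  `run_linkage_scan`
relaxes each start (L-BFGS) and measures mean bidentate fraction (binder
within 8 Å bead distance of both domains — the bead-resolution stand-in
for the atomistic 4 Å heavy-atom rule) and binder RMSD after fitting the
distal domain, over plain Langevin trajectories.

## Free-energy surfaces and observables

FES: 2D histogram, F = −k_BT ln(count/total), converted to kJ/mol,
min-shifted to 0; empty bins are unreachable (+inf), exported blank.
Default bin width 0.25 Å on RMSD axes.  Only rung-0 samples enter the
FES; no cross-rung reweighting is used (the zero-coupling replica *is*
the target ensemble, and reweighting across rungs is neither needed nor
defined by the method).  Binding modes: bidentate / monodentate-distal /
monodentate-proximal / unbound by contact counts against each domain.
Convergence: split-half Jensen–Shannon divergence of the CV histogram in
bits (0 identical, 1 disjoint; < 0.05 in practice for converged runs).

## Problem sizes used in tests and the acceptance script

Campaign validations run 16 rungs × 2000–5000 iterations × 20 steps
(harmonic / double well), the exchange-statistics checks use 10⁴ swap
attempts, and the linkage scan uses 12-bead domains, a 12-bead binder
and 5 seeds × 300 ps per variant.  These sizes give standard errors well
inside the asserted tolerances while keeping the whole suite at desk
scale.

## What the synthetic tests do and do not show

The toys verify the machinery exactly (criterion correctness, detailed
balance, unbiased rung-0 marginals, enhanced barrier crossing).  The bead
complex exercises the full pipeline on a protein-shaped problem, but its
energetics are schematic: no electrostatics, no solvent, sequence-free
interfaces.  Passing the linkage scan shows the *mechanistic* ordering —
native linkage preserves bidentate binding better than strained or
displaced linkages — not any quantitative affinity.  Results on real
complexes additionally depend on the all-atom force field and solvent
model, which are outside this package's scope.

Of the linkage-scan effects, the forced remodel (shortened linker), the
far-side attachment and the unconnectable-linkage error are robust; the
pure bead-count lengthening is the weakest comparator — a longer flexible
tether barely perturbs an otherwise marginal interface at equilibrium,
so its deficit relative to the native design sits at the edge of the
scan's statistical resolution.

## Known limitations

* The adiabatic scheme is an approximation; the symmetric mode exists to
  quantify it, and only toy-scale systems have been validated here.
* CG-resolution contact criteria (8 Å Cα–Cα) only approximate heavy-atom
  contact definitions.
* The PDB reader handles the common fixed-column dialect (ATOM/HETATM,
  MODEL/ENDMDL, altloc filtering); mmCIF and insertion-code semantics are
  out of scope.
* `Rotation`-grid superposition oracles and quadrature references are
  test-side tools, not optimised library code.
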