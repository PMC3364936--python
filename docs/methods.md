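# Methods

This note records the models implemented in `porefep`, the conventions
and defaults chosen where several were defensible, and what the
synthetic-data validation does and does not demonstrate.

## Thermodynamic bookkeeping (`porefep.thermo`)

Absolute binding free energies are assembled as

ΔG_bind,n = ΔG_FEP,n − ΔG_solv + ΔG_V + ΔG_sym

with ΔG_FEP,n the free energy of inserting the ligand from vacuum into
the (n−1)-fold occupied, restrained site, ΔG_solv the ligand's
solvation free energy (subtracted because binding proceeds from
solution, not vacuum), ΔG_V = −kT ln(V_site/V₀) the standard-state
restraint correction (V₀ = 1661 Å³ per molecule at 1 M), and
ΔG_sym = kT ln σ the symmetry penalty (σ = 1 for isoflurane, 2 for
propofol and ethanol; at 300 K, σ = 2 costs 0.41 kcal/mol, a factor of
two in affinity). The sign convention is fixed by the requirement that
the assembled totals map onto dissociation constants through
Kd = (1 M)·exp(ΔG_bind/kT); that total→Kd correspondence is the
validated contract (tested for all ten tabulated ligand/site totals at
2 significant figures). The individual component columns of the
packaged table are carried as annotations; their printed values do not
arithmetically sum to the printed totals (the ethanol row makes this
obvious), so no test asserts component sums.

Uncertainties: the correction terms carry no published errors and are
treated as exact; the standard error of a total equals that of its FEP
term. Temperature defaults to 300 K (the simulation thermostat value);
kB = 1.9872×10⁻³ kcal/(mol·K). Concentrations are stored in molar and
auto-scaled (M/mM/µM/nM) only for display.

Cooperativity labels use a relative dead band (default 50%):
Kd2 > Kd1(1+tol) is negative, Kd2 < Kd1/(1+tol) positive, otherwise
non-cooperative.

## FEP estimation (`porefep.fep`)

Window samples store ΔU = U(λ_high) − U(λ_low) for both the low-λ
("forward") and high-λ ("backward") ensembles, so both directions
estimate the same window ΔG; the backward exponential estimator is
+kT ln⟨e^{+ΔU/kT}⟩. BAR is solved on the log-ratio form of the implicit
acceptance-ratio equation by bisection (start bracket ±50 kcal/mol,
expanded if required; tolerance 10⁻⁸ kcal/mol), which is deterministic
for given inputs. The standard error is the standard BAR asymptotic
variance (delta method on the two Fermi-function averages at the
solution). Windows whose forward and backward sample ranges are
disjoint are flagged `poor_overlap` rather than rejected.

Window estimates are summed along the schedule with quadrature error
propagation; λ coverage is checked for gaps and overlaps. Stages run
once in each direction (decoupling and recoupling) are merged as the
mean with stderr = |difference|/2, matching the convention used when
each stage provides a single run. Repeated runs per direction are
pooled by sample concatenation before estimation.

The default λ schedule uses a 0.025 step inside [0, 0.25] and 0.05
elsewhere, giving 25 windows per stage (one 1-ns window per ns of a
25-ns stage). The placement of the fine region reproduces the window
count, but its exact bounds are a package choice; both the region and
the steps are configurable. Soft-core handling, equilibration discards
and unit conversion are the caller's responsibility: samples are
accepted pre-equilibrated, in kcal/mol.

## Pore-block dose-response model (`porefep.poreblock`)

Occupancies follow the two-site Adair scheme with macroscopic stepwise
constants Kd1, Kd2 (no per-site statistical factors are split out; the
ΔG↔Kd correspondence above supports the macroscopic reading).
Inhibition is I = α·p1 + p2. The exact IC50 solver brackets the root of
I = 1/2 by geometric growth (factor 10 from 10⁻¹²·Kd1) and polishes
with Brent's method; the α ∈ {0, 1} closed-form radicals serve as its
oracle and as the published-range endpoints. The exact root is primary
because the model's printed approximate IC50 expression is not
recoverable; the closed forms reproduce all eight tabulated range
bounds within the 5% slack implied by 2-s.f. inputs. The model is
scale-invariant in concentration units (tested), so Kd and dose axes
may be carried in any single unit.

Fitting (`PoreBlockModel`) minimizes unweighted squared residuals over
(log₁₀Kd1, log₁₀Kd2, α) with `scipy.optimize.least_squares` (TRF,
bounded), from a deterministic six-point multistart grid anchored at
the log-interpolated half-inhibition concentration; default Kd bounds
are six decades either side of that anchor. Uniform weights are used
because no error model accompanies typical published curves. Curves
that never leave [0, 0.05] or [0.95, 1] are rejected as degenerate.
Fitting all three parameters from 12-point curves with 0.02 absolute
noise recovers Kd1 with ~10% median error (50-seed study in the test
suite); Kd2 and α are less identifiable when α ≈ 1, which is expected —
the second site barely shapes the curve there.

## Pore geometry and density (`porefep.geometry`)

*Pore center*: unweighted centroid of the ten Cα atoms of Tyr226 and
Tyr244 over the five chains. *Pore axis*: principal axis of those ten
atoms, oriented so the Tyr244 (extracellular) ring projects positive —
the axis is not part of the published analysis conventions and had to
be fixed here. Axial coordinates are measured from the pore center.

*M2 pair distances*: geometric centers of Cα 232–245 per chain,
distances for the five non-adjacent pentagon pairs {1-3, 1-4, 2-4,
2-5, 3-5} with chains ordered by azimuth around the axis. (A printed
pair list containing an adjacent pair is normalized to this set, the
unique set of non-adjacent pairs of a pentagon.)

*Boltzmann profiles*: −kT ln of the histogram density, minimum shifted
to zero; empty bins are NaN (flagged, never zero-filled). Default bin
width 0.5 Å (configurable; restraint-design examples use 0.1 Å, fine
enough to resolve a ~1.5 Å basin separation).

*Flat-bottom restraint design*: the wall d₀ is placed at the largest
distance below the open-basin center where the profile rises a margin
(default 1 kT) above the basin minimum **and** descends again further
down — the second condition distinguishes a genuine barrier from the
flank of a single well, which raises a design error instead. The wall
is zero for d ≥ d₀ and (k/2)(d−d₀)² below, continuous with continuous
first derivative at d₀; default k = 10 kcal/mol/Å² (the printed order
of magnitude; configurable).

*Axial density*: ρ(z) = n_ligands·P(z)/Δz with P(z) pooled over ligands
when two are present (the per-ligand vs pooled choice is not dictated
by the figure convention being emulated; pooled is adopted). The
three-bin running average spreads each bin's mass equally over itself
and its neighbours; thirds that would leave the grid at the two edge
bins remain in the edge bin, so smoothing conserves the integral
exactly (a literal shrinking-window average does not, and conservation
to n_ligands is the stated invariant). Site occupancy integrates the
raw (unsmoothed) density, or counts sample fractions, over per-site
z-intervals derived from the prime-notation anchors (prime = residue −
223) projected on the axis of the structure at hand.

Coordinate precision: structures are held in the PDB container's
single-precision arrays, so geometric identities are asserted at
10⁻⁴–10⁻⁵ Å, well below the 10⁻³ Å precision of the PDB format itself.

## Synthetic generators (`porefep.synthetic`)

All generators draw from `numpy.random.default_rng(seed)` and are
bit-reproducible.

*FEP*: per window, forward work ~ N(ΔG + σ²/2kT, σ²) and backward
ΔU ~ N(ΔG − σ²/2kT, σ²) — the unique Gaussian pair satisfying the
Crooks relation for that ΔG, verified empirically (log-density-ratio
slope 1/kT, R² > 0.99). Defaults mirror the study conditions the
package targets: 25 windows, σ = 1 kcal/mol, 5000 samples per direction
per window, totals at the tabulated −7.6 kcal/mol scale.

*Toy pore*: Metropolis sampling of a sum-of-Gaussian-wells potential
between hard walls, with 20% global uniform proposals for fast
inter-well mixing and a local step auto-tuned to 30–50% acceptance
during a discarded burn-in (10% of the trajectory length). Two ligands
may repel through a soft Gaussian core. Because Metropolis samples are
autocorrelated, occupancy recovery is tested against a 3σ band with σ
from the chain's effective sample size, not the raw frame count.

*Distance series*: two-component Gaussian mixture, defaults 30% open at
20 Å / 70% collapsed at 18.5 Å, σ = 0.3 Å — chosen to emulate the
described bimodal statistics (metastable open basin near 20 Å, larger
collapsed population below 19 Å).

*Dose curves*: exact model inhibition on a log-spaced grid spanning two
decades either side of the model IC50 (12 points by default), plus
Gaussian noise clipped to [0, 1].

What passing these tests shows: the estimators are correct on data that
match their assumptions (independent samples, Gaussian work
distributions, exact model curves, rigid geometry). What they do not
show: robustness to the pathologies of real MD output — autocorrelated
and non-Gaussian work values, slow conformational drift, anharmonic
basins, force-field error. The generators make no attempt at atomistic
realism.

## Numerical choices and limitations

- BAR bisection tolerance 10⁻⁸ kcal/mol; IC50 root relative tolerance
  10⁻¹²; Kd↔ΔG round trips hold to 10⁻¹² relative.
- The acceptance script's IC50 targets are fully deterministic; its
  `--seed` flag exists for interface uniformity and seeds nothing that
  affects those outputs.
- Double occupancy is capped at two ligands (higher aggregates are
  outside the model); α is a free parameter bounded in [0, 1], not
  derived from structure.
- The ethanol affinity entry in the packaged table is a narrative value
  (510 mM) carried as an annotation; it is excluded from validation.
- Allosteric-site modulation (potentiation) is deliberately not
  modelled: the package predicts pore-block inhibition only, which is
  why a pure pore-block prediction can overestimate inhibition for
  ligands that also occupy an allosteric site.
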