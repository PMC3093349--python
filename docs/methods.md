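# Methods

## Model and assumptions

Circuits are mass-action reaction networks over transcription-factor
genes and their proteins. The modeling assumptions, fixed throughout:

- **Elementary reactions only.** No Michaelis–Menten or Hill terms;
  every regulatory effect is unpacked into binding, unbinding,
  production and degradation steps so that mass-action theory (and in
  particular CRNT) applies without approximation.
- **Exclusive promoter occupancy.** Each gene is free or bound by
  exactly one monomer or dimer; bound states are distinct species and
  no doubly-bound species exists.
- **No dimer proteolysis.** Monomers degrade; dimers do not (dimerization
  commonly protects against degradation). A dimer-breakdown reaction
  would in any case be a subspace-preserving addition — its reaction
  vector is a combination of un-dimerization and two monomer
  degradations — so omitting it does not change which topologies can be
  bistable (tested in `test_ancestry.py`).
- **Dimensionless concentrations.** Each gene's total DNA is one; all
  concentrations are relative to it. Rate constants are in arbitrary
  units on that scale.
- **Production from a bound gene is non-zero but unconstrained**: it may
  exceed or undercut the basal rate, so a binding reaction alone encodes
  "regulation of unknown sign", and binding plus bound-production can
  realize activation.

Reversible reactions are stored as two irreversible records sharing a
label; circuit *size* counts labels (so the canonical seven-reaction
switches `ckn` and `kqw` have size 7 even though their compiled
networks contain 9 directed reactions).

## Enumeration and symmetry

Dependencies make the optional-label poset a disjoint union of small
chains (a binding with its production; a dimerization with its two
binding/production chains). Dependency-closed subsets are Cartesian
products of per-chain valid states, which is how `enumerate_family`
iterates all 81,000 raw circuits in under a second. The gene-swap
involution (`a↔d, b↔c, e↔h, f↔g, i↔k, j↔j, l↔q, m↔p, n↔o, r↔w, s↔v,
t↔u`) identifies mirror circuits; the canonical orbit representative is
the lexicographically smaller sorted label tuple. Note that the
literature names some circuits by the other representative (e.g. `kqw`,
whose mirror `ilr` is lexicographically smaller; or `bcdh`, canonically
`abce`), so name comparisons should canonicalize both sides — all
counts are representative-invariant. The tests check the enumeration
against an independent Burnside orbit count with per-chain closed
forms: (81,000 + 360)/2 = 40,680 for the family, (144 + 12)/2 = 78
decoupled, (81 + 9)/2 = 45 cooperativity-free.

## Exact structural computations

Rank, stoichiometric-subspace bases and conservation laws are computed
over the rationals (integer fraction-free elimination for rank; sympy
RREF for bases). The canonical subspace basis is the reduced
row-echelon form of the reaction-vector matrix over a fixed species
ordering: RREF is unique per row space, so *subspace equality is
entrywise equality of canonical bases* — no tolerances. Networks over
different species universes are aligned by species name, padding
missing species with zero coordinates; this is exactly what the
ancestry test needs when a child circuit adds a species.

The deficiency screen implements the conclusion-forcing conditions of
the deficiency-zero theorem (δ = 0: weakly reversible ⇒ unique positive
steady state per class; otherwise ⇒ none) and of the deficiency-one
theorem (δ = 1, each linkage class with deficiency ≤ 1 summing to δ,
and one terminal strong-linkage class per linkage class ⇒ at most one
positive steady state per class). Every member of the two-gene family
has δ ≥ 2, so the screen always returns "inconclusive" there; it is
still exercised on small hand-built networks.

## Network ancestry

Adding a reaction whose vector already lies in the parent's
stoichiometric subspace cannot change the surfaces confining the
dynamics, and with an arbitrarily small rate constant it perturbs the
vector field arbitrarily weakly, so two hyperbolic stable equilibria
persist: bistability is inherited. Production-from-bound additions are
always such: their vector equals the basal-production vector, already
in the span via degradation. The closure operator works on raw
(uncanonicalized) label sets — trivial parent/child species alignment —
and collapses orbits only for membership bookkeeping; it is monotone
and idempotent (property-tested). Minimality is assessed against *all*
dependency-closed proper subsets up to symmetry, not just one-reaction
deletions, matching the subnetwork definition of a minimal bistable
network.

## The numerical oracle

**Reduced steady-state system.** For every circuit in this grammar, a
bound-gene species changes only through binding/unbinding (bound
production leaves it untouched), so its net flux is zero at any steady
state; dimer species then also reduce to dimerization equilibrium. All
equilibria therefore satisfy, per gene *g* with monomer concentration
*p_g*,

    (basal_g + Σ_B prod_B·K_B·C_B) / (1 + Σ_B K_B·C_B) = deg_g · p_g,

where the sum runs over that gene's binders, `K_B` is the effective
association constant (including the dimerization constant for dimer
binders) and `C_B` the binder concentration expressed through the
monomers. Two genes → two equations. `circuit_equilibria` solves them
by damped Newton iteration from a dense log-spaced grid of starts
(10 per axis over 10⁻⁵–10³·⁵, plus the basal/degradation point),
vectorized over starts, so no equilibrium is missed in practice; roots
are lifted to the full species space, Newton-polished *within the
stoichiometric subspace* (preserving conserved totals exactly), and
classified by the eigenvalues of the subspace-restricted Jacobian. A
generic multistart least-squares solver (`find_equilibria`) covers
arbitrary networks outside the grammar and cross-checks the reduced
solver on linear cases.

**Numerical conventions.** Stability threshold ±10⁻⁶ on eigenvalue
real parts, with the band in between labeled "marginal"; equilibria
deduplicated at relative L∞ distance 10⁻⁴; strict positivity above
10⁻¹⁰; candidate equilibria are discarded unless the polished residual
max|dx/dt| is below 10⁻⁸. Draws whose scales are too extreme to polish
below that residual are simply rejected and cost one draw.

**Rate sampling.** The default scheme is log-uniform on [10⁻³, 10³] per
rate symbol. The `guided` scheme (used by `is_bistable` by default)
draws each rate log-uniformly within a role-specific window — weak
basal production (10⁻²–10⁰·⁵), degradation near unity (10⁻¹–10¹),
fast/tight binding and dimerization on-rates (10⁰–10²·⁵), slow
off-rates (10⁻²–10¹), bound-production up to 10² — because switches
need tight binding and bound production that can dominate basal
production; this raises the fraction of bistable draws by orders of
magnitude while staying inside the global range. Draw *d* of a search
seeded with *s* uses the deterministic child seed `SeedSequence([s, d])`,
so identical (circuit, budget, seed) always reproduce the same outcome.

**Certificates and validation.** A certificate stores the rates, the
conserved totals (the class with one unit of free DNA per gene and no
protein), the two stable equilibria (lowest and highest total
concentration if more than two are found) and one unstable equilibrium
when present. `validate_certificate` is an independent check: it
perturbs each stable state by ~1% *within its compatibility class*
(shrinking, never clipping, so the class is preserved), integrates the
stiff ODEs (LSODA, rtol 10⁻⁹) for 200 relaxation times of the leading
eigenvalue, and requires return to the same state and conserved-total
drift below 10⁻⁶; unstable states must show a positive reduced
eigenvalue. `grow_certificate` continues a certificate onto a
one-reaction descendant by carrying the rates over and initializing new
rates at 10⁻⁴ times the parent's median rate (off-rates at 1 so new
bound states stay sparse); it re-solves globally and revalidates, so it
also works — without any guarantee — across additions that enlarge the
subspace.

**Bifurcation scans** re-run the global equilibrium solve on a grid of
one rate constant and bracket folds wherever the equilibrium count
changes by two between adjacent grid points. For a `bcdh` certificate,
sweeping the P2 degradation rate shows the expected fold-bounded window
with two stable and one unstable branch.

**Verdict semantics.** Absence of a certificate is always "unknown":
a failed random search proves nothing. "Monostable" is assigned only
from closed-form reasoning — in the survey, the rudimentary circuit,
whose dynamics are linear with a unique globally attracting
equilibrium. "Multiple steady states, stability unconfirmed" records
draws with several equilibria but never two stable ones.

## Interaction-table mining

The translation from elementary-reaction circuits to minable patterns
is a declared convention (the original mapping is not published in an
accessible form): each monomer binding becomes a protein→gene edge;
each dimer binding becomes a protein→gene edge per dimer constituent
plus the dimerization edge; binding *with* the matching bound-production
reaction constrains the edge sign to activation-or-unknown, binding
without it to repression-or-unknown; missing sign annotations are
compatible with everything, since curated sign data is sparse and was
only ever supplementary evidence. Matching enumerates ordered distinct
gene pairs.

The fixture generator emulates the *structure* of curated TF
interaction extracts (a TF list, undirected protein-protein pairs with
self-pairs as homodimers, protein-DNA pairs, optional sign
annotations): it plants the exact edges of requested motifs and then
adds decoy edges one at a time, rejecting any decoy that would create a
new match for a planted pattern. It does not emulate measurement noise,
missing true edges, promoter-region geometry, or database-version
variance — passing the recovery tests therefore demonstrates the
correctness of the matching logic, not any claim about real yeast
counts, which depend on the database snapshot.

## Problem sizes in the test suite

The exhaustive structural sweep covers all 40,680 compiled networks
(~15 s). Oracle acceptance uses budget 2,000 draws with search seed 1
for the eleven minimal bistable networks (all certify in a few minutes,
most within a handful of draws); the survey test restricts to the
45-member cooperativity-free family with 300 draws for the seed
circuit. Property tests that are quadratic or worse in the family size
(subspace-preservation of production additions, equivalence-relation
checks) run on seeded samples of the family rather than exhaustively.

## Known limitations

- The oracle is a sampler: it can certify bistability but never refute
  it, and its success probability depends on the sampling scheme. The
  published fraction of the family that is bistable cannot be
  reproduced here, since it rests on an advanced-deficiency-theory
  implementation that is not publicly available; this package's closure
  and growth machinery propagates only from seeds the user certifies.
- Exhaustive enumeration is implemented for one and two genes; the
  grammar generalizes to any gene count (60 optional reactions for
  three genes) but three-gene enumeration is out of scope.
- The reduced equilibrium solver is specific to the grammar's
  structure; for arbitrary networks the generic multistart solver has
  no completeness guarantee.
- Certificate growth across subspace-*changing* additions is heuristic
  continuation; only subspace-preserving growth carries a structural
  guarantee.
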