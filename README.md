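# grnswitch

Tools for surveying the bistability of small gene-regulatory networks
(GRNs) built from elementary mass-action biochemistry, aimed at people
studying genetic switches: systems/synthetic biologists who want to
know which two-gene circuit topologies *can* behave as a bistable
switch for some choice of rate constants, without committing to any
particular parameter values.

## The model family

A circuit over two transcription-factor genes `X1`, `X2` with proteins
`P1`, `P2` always contains basal production (`Xi → Xi + Pi`) and
monomer degradation (`Pi → 0`). It may add, subject to logical
dependencies, any of 23 optional elementary reactions: monomer-promoter
binding (`Xi + Pj ⇌ XiPj`), production from a monomer-bound gene,
dimerization (`Pi + Pj ⇌ PiPj`), dimer-promoter binding, and production
from a dimer-bound gene (labels `a`–`w`; a circuit is named by its
sorted labels, e.g. `bcdh`). Each promoter holds at most one binder,
dimers are not degraded, and the heterodimer `P1P2` is a single
species. Enumerating all dependency-closed label subsets gives 81,000
circuits; identifying mirror images under exchange of the gene indices
leaves **40,680** distinct two-gene networks — among them 78 decoupled
circuits (no cross-gene reaction) and 45 cooperativity-free ones (no
dimerization).

Three layers of analysis sit on top of the enumeration:

- **Chemical reaction network theory (CRNT).** For any mass-action
  network the package computes, in exact rational arithmetic, the
  number of complexes *n*, linkage classes *l*, rank *s*, deficiency
  *δ = n − l − s*, a canonical basis of the stoichiometric subspace,
  and the conservation laws; a deficiency-zero/one screen rules out
  multistationarity where those theorems apply (they never do in this
  family — every member has *δ ≥ 2*).
- **Network ancestry.** If adding one reaction leaves the
  stoichiometric subspace identical, a bistable parent circuit passes
  its bistability to the descendant (the new rate constant can be made
  arbitrarily small). The package builds the one-reaction extension
  lattice, tests subspace preservation exactly, closes seed sets under
  it, and identifies minimal bistable networks — bistable circuits
  containing no smaller bistable sub-circuit.
- **A numerical bistability oracle.** For a given circuit it samples
  rate constants, finds *all* equilibria in the compatibility class
  with one unit of DNA per gene (exploiting the fact that bound genes
  and dimers are at binding equilibrium at any steady state, which
  reduces the problem to one balance equation per monomer), classifies
  stability from the Jacobian restricted to the stoichiometric
  subspace, and emits a certificate — rates plus two asymptotically
  stable positive equilibria — that is independently re-checked by
  perturbation and forward ODE integration. One-parameter bifurcation
  scans trace the fold-bounded bistable window of a certificate.

A fourth module translates circuits into coarse interaction patterns
(who binds whose promoter, with what dimerization and regulatory sign)
and mines protein-protein / protein-DNA interaction tables for gene
pairs matching them, with a seeded fixture generator standing in for
curated database extracts.

## Worked example

```
$ grnswitch crnt --circuit kqw
species            6
reactions          9
complexes (n)      12
linkage classes (l) 5
rank (s)           4
deficiency (d)     3
conservation laws  2
  X1 = const
  X2 + X2P2P2 = const
subspace dimension 4
deficiency screen  inconclusive
```

The seven-reaction self-activation circuit `kqw` (P2 homodimerizes, the
dimer binds the `X2` promoter, and the bound gene produces P2) has
deficiency 3, so the classical deficiency theorems say nothing — its
bistability has to be established another way:

```
$ grnswitch oracle --circuit kqw --budget 400 --seed 1 --out kqw.json
certificate with 2 stable equilibria written to kqw.json
```

The certificate records sampled rate constants and two stable positive
steady states (a low-P2 and a high-P2 state) sharing the same conserved
totals. Growing a certificate and sweeping a parameter:

```
$ grnswitch grow --cert kqw.json --add a --out kqwa.json
$ grnswitch survey --filter coop-free --seeds bcdh --budget 300 --seed 1 --out report
{"family_size": 45, "min_deficiency": 2, "n_bistable_confirmed": 11,
 "n_coop_free": 45, "n_decoupled": 6, "n_monostable": 1,
 "n_multiple_unconfirmed": 0, "n_unknown": 33}
```

The survey certifies the dimer-free switch `bcdh` (P2 activates its own
gene and represses `X1`, P1 represses `X2`) and then continues its
certificate along the extension lattice: exactly the 11
cooperativity-free circuits containing `bcdh` up to symmetry come out
bistable; the only monostable verdict is the rudimentary circuit, whose
linear dynamics have a unique equilibrium in closed form.

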