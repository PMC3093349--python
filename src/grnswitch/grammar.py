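"""The two-gene reaction grammar and exhaustive circuit enumeration.

A gene circuit over ``N`` transcription-factor genes is built from a fixed
menu of elementary mass-action reactions: per gene, basal protein
production and monomer degradation are always present (the *essential*
reactions); optionally a circuit may add monomer-promoter binding,
production from a monomer-bound gene, TF dimerization, dimer-promoter
binding, and production from a dimer-bound gene.  Additions are subject
to logical dependencies — production from a bound gene requires the
binding, dimer binding requires the dimerization, and production from a
dimer-bound gene requires both.

For two genes the optional menu has 23 members, labeled ``a`` through
``w``.  Enumerating every dependency-closed subset gives 81,000 raw
circuits; identifying each circuit with its mirror image under exchange
of the gene indices (heterodimers P1P2 and P2P1 are one species) leaves
40,680 distinct two-gene circuits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx

from .crn import Complex, Reaction, ReactionNetwork, Role, Species

_KINDS = ("bind_monomer", "prod_monomer_bound", "dimerize",
          "bind_dimer", "prod_dimer_bound")

TWO_GENE_LETTERS = "abcdefghijklmnopqrstuvw"

#: Coupling reactions: any circuit containing one of these links the two genes.
COUPLING_LABELS = frozenset("bcjno")

#: Dimerization reactions; their absence defines the cooperativity-free family.
DIMERIZATION_LABELS = frozenset("ijk")


@dataclass(frozen=True)
class ReactionTemplate:
    """One row of the reaction menu.

    ``gene`` is the promoter (or producing) gene index, 1-based;
    ``partners`` holds the protein indices involved (one for monomer
    binding/production, the sorted pair for anything dimeric).
    """

    label: str
    kind: str
    gene: int
    partners: tuple[int, ...]
    dependencies: frozenset[str]
    essential: bool = False


def _dimer_pairs(n_genes: int) -> list[tuple[int, int]]:
    return [(p, q) for p in range(1, n_genes + 1) for q in range(p, n_genes + 1)]


@lru_cache(maxsize=None)
def reaction_table(n_genes: int = 2) -> tuple[ReactionTemplate, ...]:
    """The full reaction menu (essential + optional) for ``n_genes`` genes.

    Optional template counts: N^2 monomer bindings, N^2 productions from
    monomer-bound genes, N(N+1)/2 dimerizations, N*N(N+1)/2 dimer
    bindings and as many productions from dimer-bound genes — 23 for two
    genes, 5 for one, 60 for three.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    rows: list[ReactionTemplate] = []
    for g in range(1, n_genes + 1):
        rows.append(ReactionTemplate(f"B{g}", "basal", g, (g,), frozenset(), True))
    for g in range(1, n_genes + 1):
        rows.append(ReactionTemplate(f"D{g}", "degrade", g, (g,), frozenset(), True))

    optional: list[tuple[str, int, tuple[int, ...], tuple]] = []
    genes = range(1, n_genes + 1)
    binds = [(g, p) for g in genes for p in genes]
    for g, p in binds:
        optional.append(("bind_monomer", g, (p,), ()))
    for g, p in binds:
        optional.append(("prod_monomer_bound", g, (p,), (("bind_monomer", g, (p,)),)))
    dimers = _dimer_pairs(n_genes)
    for pq in dimers:
        optional.append(("dimerize", 0, pq, ()))
    dbinds = [(g, pq) for g in genes for pq in dimers]
    for g, pq in dbinds:
        optional.append(("bind_dimer", g, pq, (("dimerize", 0, pq),)))
    for g, pq in dbinds:
        optional.append(("prod_dimer_bound", g, pq,
                         (("dimerize", 0, pq), ("bind_dimer", g, pq))))

    # label assignment: letters a..w for the two-gene menu, structured
    # identifiers otherwise
    key_to_label: dict[tuple, str] = {}
    for idx, (kind, g, partners, _) in enumerate(optional):
        if n_genes == 2:
            label = TWO_GENE_LETTERS[idx]
        else:
            tag = {"bind_monomer": "mb", "prod_monomer_bound": "pm",
                   "dimerize": "dz", "bind_dimer": "db",
                   "prod_dimer_bound": "pd"}[kind]
            suffix = "".join(str(i) for i in partners)
            label = f"{tag}{g}.{suffix}" if g else f"{tag}.{suffix}"
        key_to_label[(kind, g, partners)] = label
    for kind, g, partners, deps in optional:
        rows.append(ReactionTemplate(
            key_to_label[(kind, g, partners)], kind, g, partners,
            frozenset(key_to_label[d] for d in deps)))
    return tuple(rows)


def optional_templates(n_genes: int = 2) -> tuple[ReactionTemplate, ...]:
    return tuple(t for t in reaction_table(n_genes) if not t.essential)


@lru_cache(maxsize=None)
def _template_index(n_genes: int) -> dict[str, ReactionTemplate]:
    return {t.label: t for t in reaction_table(n_genes)}


@lru_cache(maxsize=None)
def _swap_map(n_genes: int) -> dict[str, str]:
    """Label involution induced by exchanging the gene indices 1 and 2."""
    if n_genes < 2:
        return {t.label: t.label for t in optional_templates(n_genes)}
    perm = {1: 2, 2: 1}
    perm.update({g: g for g in range(3, n_genes + 1)})
    by_key = {(t.kind, t.gene, t.partners): t.label
              for t in optional_templates(n_genes)}
    out = {}
    for t in optional_templates(n_genes):
        g = perm.get(t.gene, t.gene) if t.gene else 0
        partners = tuple(sorted(perm[p] for p in t.partners))
        out[t.label] = by_key[(t.kind, g, partners)]
    return out


def gene_swap(labels: Iterable[str], n_genes: int = 2) -> frozenset[str]:
    """Image of a label set under the gene-exchange involution."""
    m = _swap_map(n_genes)
    out = set()
    for lab in labels:
        if lab not in m:
            raise KeyError(f"unknown optional reaction label {lab!r}")
        out.add(m[lab])
    return frozenset(out)


@dataclass(frozen=True)
class GeneCircuit:
    """A dependency-closed set of optional reaction labels.

    The essential basal production and degradation reactions are
    implicit.  The circuit *name* is the sorted concatenation of its
    optional labels ("" for the rudimentary circuit).
    """

    labels: frozenset[str]
    n_genes: int = 2

    def __post_init__(self):
        idx = _template_index(self.n_genes)
        unknown = [l for l in self.labels if l not in idx or idx[l].essential]
        if unknown:
            raise ValueError(f"unknown optional labels {unknown}")

    @property
    def name(self) -> str:
        if self.n_genes == 2:
            return "".join(sorted(self.labels))
        return "+".join(sorted(self.labels))

    @property
    def size(self) -> int:
        """Reaction count: optional labels plus the essential reactions."""
        return len(self.labels) + 2 * self.n_genes

    def is_closed(self) -> bool:
        idx = _template_index(self.n_genes)
        return all(idx[l].dependencies <= self.labels for l in self.labels)

    def closure(self) -> "GeneCircuit":
        """Smallest dependency-closed superset (idempotent)."""
        idx = _template_index(self.n_genes)
        labels = set(self.labels)
        frontier = list(labels)
        while frontier:
            lab = frontier.pop()
            for dep in idx[lab].dependencies:
                if dep not in labels:
                    labels.add(dep)
                    frontier.append(dep)
        return GeneCircuit(frozenset(labels), self.n_genes)

    def swapped(self) -> "GeneCircuit":
        return GeneCircuit(gene_swap(self.labels, self.n_genes), self.n_genes)

    def canonical(self) -> "GeneCircuit":
        """Orbit representative: lexicographically smaller label tuple of
        the circuit and its gene-swapped mirror."""
        mine = tuple(sorted(self.labels))
        other = tuple(sorted(gene_swap(self.labels, self.n_genes)))
        return self if mine <= other else self.swapped()

    def is_canonical(self) -> bool:
        return tuple(sorted(self.labels)) <= tuple(
            sorted(gene_swap(self.labels, self.n_genes)))


def circuit(name: str, n_genes: int = 2) -> GeneCircuit:
    """Parse a circuit string such as ``"bcdh"`` (two-gene letters)."""
    if n_genes == 2:
        labels = frozenset(name)
    else:
        labels = frozenset(p for p in name.split("+") if p)
    c = GeneCircuit(labels, n_genes)
    if not c.is_closed():
        raise ValueError(f"circuit {name!r} is not dependency-closed")
    return c


# ---------------------------------------------------------------------------
# enumeration


@lru_cache(maxsize=None)
def _component_subsets(n_genes: int) -> tuple[tuple[frozenset[str], ...], ...]:
    """Valid (dependency-closed) label subsets per dependency component.

    The optional-label dependency graph splits into small connected
    components; dependency-closed subsets of the whole menu are exactly
    Cartesian products of dependency-closed subsets per component.
    """
    idx = _template_index(n_genes)
    g = nx.Graph()
    for t in optional_templates(n_genes):
        g.add_node(t.label)
        for dep in t.dependencies:
            g.add_edge(t.label, dep)
    components = sorted((sorted(c) for c in nx.connected_components(g)),
                        key=lambda c: c[0])
    out = []
    for comp in components:
        valid = []
        for r in range(len(comp) + 1):
            for sub in itertools.combinations(comp, r):
                sset = frozenset(sub)
                if all(idx[l].dependencies <= sset for l in sset):
                    valid.append(sset)
        out.append(tuple(valid))
    return tuple(out)


def iter_raw_family(n_genes: int = 2) -> Iterable[frozenset[str]]:
    """All dependency-closed optional-label subsets (no symmetry folding)."""
    for combo in itertools.product(*_component_subsets(n_genes)):
        yield frozenset().union(*combo) if combo else frozenset()


def enumerate_family(n_genes: int = 2) -> list[GeneCircuit]:
    """All circuits, one representative per gene-swap orbit, sorted by
    (size, name)."""
    if n_genes not in (1, 2):
        raise ValueError("exhaustive enumeration is supported for 1 or 2 genes")
    swap = _swap_map(n_genes)
    out = []
    for labels in iter_raw_family(n_genes):
        mirrored = frozenset(swap[l] for l in labels)
        if tuple(sorted(labels)) <= tuple(sorted(mirrored)):
            out.append(GeneCircuit(labels, n_genes))
    out.sort(key=lambda c: (c.size, c.name))
    return out


def is_decoupled(circ: GeneCircuit) -> bool:
    """True iff the circuit contains no cross-gene coupling reaction."""
    if circ.n_genes != 2:
        raise ValueError("decoupling is defined for two-gene circuits")
    return not (circ.labels & COUPLING_LABELS)


def is_cooperativity_free(circ: GeneCircuit) -> bool:
    """True iff the circuit contains no dimerization (hence nothing dimeric)."""
    if circ.n_genes != 2:
        raise ValueError("cooperativity-freeness is defined for two-gene circuits")
    return not (circ.labels & DIMERIZATION_LABELS)


#: two-gene labels acting purely within gene 1 / gene 2
GENE1_LOCAL = frozenset("aeilr")
GENE2_LOCAL = frozenset("dhkqw")

# map a decoupled two-gene side onto the one-gene menu
_SIDE1_TO_ONE_GENE = {"a": "mb1.1", "e": "pm1.1", "i": "dz.11",
                      "l": "db1.11", "r": "pd1.11"}
_SIDE2_TO_ONE_GENE = {"d": "mb1.1", "h": "pm1.1", "k": "dz.11",
                      "q": "db1.11", "w": "pd1.11"}


def decoupled_components(circ: GeneCircuit) -> tuple[GeneCircuit, GeneCircuit]:
    """Factor a decoupled two-gene circuit into its two one-gene circuits."""
    if not is_decoupled(circ):
        raise ValueError("circuit couples the two genes")
    side1 = frozenset(_SIDE1_TO_ONE_GENE[l] for l in circ.labels & GENE1_LOCAL)
    side2 = frozenset(_SIDE2_TO_ONE_GENE[l] for l in circ.labels & GENE2_LOCAL)
    return GeneCircuit(side1, 1), GeneCircuit(side2, 1)


# ---------------------------------------------------------------------------
# compilation to a reaction network


def _dimer_name(partners: Sequence[int]) -> str:
    return "".join(f"P{i}" for i in sorted(partners))


def circuit_to_crn(circ: GeneCircuit) -> ReactionNetwork:
    """Compile a circuit into its mass-action reaction network.

    Species: genes ``Xg``, monomers ``Pg``, dimers ``PiPj`` (i <= j;
    the heterodimer is a single species), bound genes ``Xg<binder>``.
    Promoter occupancy is exclusive by construction: each bound state is
    a distinct species and no doubly-bound species exists.
    """
    if not circ.is_closed():
        raise ValueError("circuit is not dependency-closed")
    idx = _template_index(circ.n_genes)
    genes = range(1, circ.n_genes + 1)

    monomers = {g: f"P{g}" for g in genes}
    gene_sp = {g: f"X{g}" for g in genes}
    dimers: dict[tuple[int, ...], str] = {}
    bound: dict[tuple[int, tuple[int, ...]], str] = {}

    templates = [idx[l] for l in sorted(circ.labels)]
    for t in templates:
        if t.kind == "dimerize":
            dimers[tuple(sorted(t.partners))] = _dimer_name(t.partners)
        elif t.kind in ("bind_monomer", "prod_monomer_bound"):
            key = (t.gene, tuple(t.partners))
            bound[key] = f"X{t.gene}P{t.partners[0]}"
        elif t.kind in ("bind_dimer", "prod_dimer_bound"):
            key = (t.gene, tuple(sorted(t.partners)))
            bound[key] = f"X{t.gene}{_dimer_name(t.partners)}"

    species = [Species(gene_sp[g], Role.GENE) for g in genes]
    species += [Species(monomers[g], Role.MONOMER) for g in genes]
    species += [Species(n, Role.DIMER) for _, n in sorted(dimers.items())]
    species += [Species(n, Role.BOUND_GENE) for _, n in sorted(bound.items())]

    reactions: list[Reaction] = []
    for g in genes:
        reactions.append(Reaction(Complex({gene_sp[g]: 1}),
                                  Complex({gene_sp[g]: 1, monomers[g]: 1}),
                                  f"k_B{g}", f"B{g}"))
    for g in genes:
        reactions.append(Reaction(Complex({monomers[g]: 1}), Complex(),
                                  f"k_D{g}", f"D{g}"))

    for t in templates:
        lab = t.label
        if t.kind == "bind_monomer":
            free = Complex({gene_sp[t.gene]: 1, monomers[t.partners[0]]: 1})
            bnd = Complex({bound[(t.gene, tuple(t.partners))]: 1})
            reactions.append(Reaction(free, bnd, f"k_{lab}_on", lab))
            reactions.append(Reaction(bnd, free, f"k_{lab}_off", lab))
        elif t.kind == "prod_monomer_bound":
            b = bound[(t.gene, tuple(t.partners))]
            reactions.append(Reaction(Complex({b: 1}),
                                      Complex({b: 1, monomers[t.gene]: 1}),
                                      f"k_{lab}", lab))
        elif t.kind == "dimerize":
            pq = tuple(sorted(t.partners))
            if pq[0] == pq[1]:
                free = Complex({monomers[pq[0]]: 2})
            else:
                free = Complex({monomers[pq[0]]: 1, monomers[pq[1]]: 1})
            dim = Complex({dimers[pq]: 1})
            reactions.append(Reaction(free, dim, f"k_{lab}_on", lab))
            reactions.append(Reaction(dim, free, f"k_{lab}_off", lab))
        elif t.kind == "bind_dimer":
            pq = tuple(sorted(t.partners))
            free = Complex({gene_sp[t.gene]: 1, dimers[pq]: 1})
            bnd = Complex({bound[(t.gene, pq)]: 1})
            reactions.append(Reaction(free, bnd, f"k_{lab}_on", lab))
            reactions.append(Reaction(bnd, free, f"k_{lab}_off", lab))
        elif t.kind == "prod_dimer_bound":
            pq = tuple(sorted(t.partners))
            b = bound[(t.gene, pq)]
            reactions.append(Reaction(Complex({b: 1}),
                                      Complex({b: 1, monomers[t.gene]: 1}),
                                      f"k_{lab}", lab))
    return ReactionNetwork(species, reactions)


def rate_symbols(circ: GeneCircuit) -> tuple[str, ...]:
    """All rate symbols of the compiled circuit, in network order."""
    return tuple(r.rate_symbol for r in circuit_to_crn(circ).reactions)
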