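"""Mass-action reaction networks and their structural (CRNT) analysis.

A chemical reaction network is a set of species together with reactions
between *complexes* (non-negative integer combinations of species).  From
the network structure alone one can compute the number of complexes ``n``,
the number of linkage classes ``l`` (connected components of the complex
graph), the rank ``s`` of the set of reaction vectors, and the deficiency
``delta = n - l - s``.  These quantities drive the classical deficiency
theorems, which can rule out multistationarity for some networks without
any knowledge of rate constants.

All structural computations here (rank, stoichiometric-subspace basis,
conservation laws) are carried out in exact rational arithmetic, so that
two networks have the same stoichiometric subspace if and only if their
canonical bases compare equal entrywise.  The numerical side — the
mass-action ODE right-hand side and its Jacobian — is plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import sympy


class Role(str, Enum):
    """Biological role of a species in a gene-circuit model."""

    GENE = "gene"
    MONOMER = "monomer"
    DIMER = "dimer"
    BOUND_GENE = "bound_gene"
    OTHER = "other"


@dataclass(frozen=True)
class Species:
    name: str
    role: Role = Role.OTHER


class Complex:
    """A non-negative integer combination of species (possibly empty).

    The empty complex (the "zero complex") is the source of a synthesis
    reaction or the sink of a degradation reaction.  Complexes are
    hashable and compare by their coefficient maps.
    """

    __slots__ = ("_coeffs",)

    def __init__(self, coefficients: Mapping[str, int] | None = None):
        coeffs = {}
        for name, count in (coefficients or {}).items():
            if count < 0:
                raise ValueError(f"negative stoichiometric count for {name}")
            if count > 0:
                coeffs[name] = int(count)
        object.__setattr__(self, "_coeffs", frozenset(coeffs.items()))

    @property
    def coefficients(self) -> dict[str, int]:
        return dict(self._coeffs)

    def species_names(self) -> set[str]:
        return {name for name, _ in self._coeffs}

    def is_empty(self) -> bool:
        return not self._coeffs

    def __eq__(self, other) -> bool:
        return isinstance(other, Complex) and self._coeffs == other._coeffs

    def __hash__(self) -> int:
        return hash(self._coeffs)

    def __repr__(self) -> str:
        return f"Complex({format_complex(self)!r})"


def format_complex(cx: Complex) -> str:
    if cx.is_empty():
        return "0"
    parts = []
    for name, count in sorted(cx.coefficients.items()):
        parts.append(name if count == 1 else f"{count}{name}")
    return " + ".join(parts)


@dataclass(frozen=True)
class Reaction:
    """A single irreversible reaction reactant -> product.

    Reversible reactions are represented as two ``Reaction`` records
    sharing a ``label``; each direction carries its own rate symbol.
    """

    reactant: Complex
    product: Complex
    rate_symbol: str
    label: str | None = None

    def __post_init__(self):
        if self.reactant == self.product:
            raise ValueError("reactant and product complexes must differ")

    def vector(self, species_order: Sequence[str]) -> tuple[int, ...]:
        """Net stoichiometry (product minus reactant) over an ordering."""
        r = self.reactant.coefficients
        p = self.product.coefficients
        return tuple(p.get(s, 0) - r.get(s, 0) for s in species_order)


class ReactionNetwork:
    """An ordered species list plus a sequence of reactions."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        declared = set(names)
        seen: set[tuple[Complex, Complex]] = set()
        for rxn in self.reactions:
            used = rxn.reactant.species_names() | rxn.product.species_names()
            if not used <= declared:
                raise ValueError(f"undeclared species in reaction: {used - declared}")
            key = (rxn.reactant, rxn.product)
            if key in seen:
                raise ValueError(f"duplicate reaction {format_complex(rxn.reactant)} -> "
                                 f"{format_complex(rxn.product)}")
            seen.add(key)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer matrix, species x reactions, of net stoichiometries."""
        order = self.species_names
        cols = [rxn.vector(order) for rxn in self.reactions]
        return np.array(cols, dtype=np.int64).T

    def reactant_matrix(self) -> np.ndarray:
        """Integer matrix, species x reactions, of reactant orders."""
        out = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        index = {name: i for i, name in enumerate(self.species_names)}
        for j, rxn in enumerate(self.reactions):
            for name, count in rxn.reactant.coefficients.items():
                out[index[name], j] = count
        return out

    def __repr__(self) -> str:
        return (f"ReactionNetwork({len(self.species)} species, "
                f"{len(self.reactions)} reactions)")


@dataclass(frozen=True)
class CRNTSummary:
    n_complexes: int
    n_linkage_classes: int
    rank: int
    deficiency: int

    def __post_init__(self):
        expected = self.n_complexes - self.n_linkage_classes - self.rank
        if self.deficiency != expected:
            raise ValueError("inconsistent deficiency")
        if self.deficiency < 0:
            raise ValueError("deficiency must be non-negative")


@dataclass(frozen=True)
class SubspaceBasis:
    """Canonical exact basis of the stoichiometric subspace.

    The basis is the reduced row-echelon form of the matrix of reaction
    vectors over a given species ordering: the RREF is unique for a row
    space, so two networks span the same subspace over the same ordering
    iff their bases compare equal entrywise.
    """

    species_order: tuple[str, ...]
    basis: tuple[tuple[Fraction, ...], ...]

    @property
    def dimension(self) -> int:
        return len(self.basis)


@dataclass(frozen=True)
class ConservationLaws:
    """Canonical exact basis of the left null space of the stoichiometry."""

    species_order: tuple[str, ...]
    laws: tuple[tuple[Fraction, ...], ...]

    def totals(self, state: Sequence[float]) -> np.ndarray:
        mat = np.array([[float(v) for v in row] for row in self.laws])
        if mat.size == 0:
            return np.zeros(0)
        return mat @ np.asarray(state, dtype=float)

    def matrix(self) -> np.ndarray:
        if not self.laws:
            return np.zeros((0, len(self.species_order)))
        return np.array([[float(v) for v in row] for row in self.laws])


# ---------------------------------------------------------------------------
# structural quantities


def complexes(net: ReactionNetwork) -> set[Complex]:
    """All distinct reactant and product complexes of the network."""
    out: set[Complex] = set()
    for rxn in net.reactions:
        out.add(rxn.reactant)
        out.add(rxn.product)
    return out


def linkage_classes(net: ReactionNetwork) -> list[set[Complex]]:
    """Connected components of the (undirected) complex graph."""
    graph = nx.Graph()
    graph.add_nodes_from(complexes(net))
    for rxn in net.reactions:
        graph.add_edge(rxn.reactant, rxn.product)
    return [set(c) for c in nx.connected_components(graph)]


def _int_rank(rows: list[tuple[int, ...]]) -> int:
    """Exact rank of an integer matrix by fraction-free elimination."""
    rows = [list(r) for r in rows if any(r)]
    if not rows:
        return 0
    ncols = len(rows[0])
    rank = 0
    col = 0
    while col < ncols and rank < len(rows):
        pivot = None
        for i in range(rank, len(rows)):
            if rows[i][col] != 0:
                pivot = i
                break
        if pivot is None:
            col += 1
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        pr = rows[rank]
        pv = pr[col]
        for i in range(rank + 1, len(rows)):
            ri = rows[i]
            if ri[col] != 0:
                f = ri[col]
                for j in range(col, ncols):
                    ri[j] = ri[j] * pv - pr[j] * f
        rank += 1
        col += 1
    return rank


def network_rank(net: ReactionNetwork) -> int:
    """Rank of the set of reaction vectors, exact over the rationals."""
    order = net.species_names
    return _int_rank([rxn.vector(order) for rxn in net.reactions])


def deficiency(net: ReactionNetwork) -> CRNTSummary:
    n = len(complexes(net))
    l = len(linkage_classes(net))
    s = network_rank(net)
    return CRNTSummary(n, l, s, n - l - s)


def _rref_rows(rows: list[tuple[int, ...]] | list[list[Fraction]],
               ncols: int) -> tuple[tuple[Fraction, ...], ...]:
    """Canonical RREF rows (nonzero only) of a rational matrix."""
    if not rows:
        return ()
    mat = sympy.Matrix([[sympy.Rational(v) for v in row] for row in rows])
    rref, _ = mat.rref()
    out = []
    for i in range(rref.rows):
        row = tuple(Fraction(int(v.p), int(v.q)) for v in rref.row(i))
        if any(row):
            out.append(row)
    return tuple(out)


def stoich_subspace(net: ReactionNetwork,
                    species_order: Sequence[str] | None = None) -> SubspaceBasis:
    """Canonical exact basis (RREF) of the span of the reaction vectors.

    ``species_order`` may extend the network's own species (extra names
    contribute zero coordinates); it must contain every network species.
    """
    if species_order is None:
        species_order = net.species_names
    else:
        missing = set(net.species_names) - set(species_order)
        if missing:
            raise ValueError(f"species order misses network species {missing}")
    order = tuple(species_order)
    rows = [rxn.vector(order) for rxn in net.reactions]
    return SubspaceBasis(order, _rref_rows(rows, len(order)))


def same_subspace(a: ReactionNetwork, b: ReactionNetwork) -> bool:
    """Whether two networks have identical stoichiometric subspaces.

    The species universes are aligned by name: the comparison is over the
    sorted union of species names, missing species padding with zeros.
    """
    union = tuple(sorted(set(a.species_names) | set(b.species_names)))
    return stoich_subspace(a, union).basis == stoich_subspace(b, union).basis


def conservation_laws(net: ReactionNetwork) -> ConservationLaws:
    """Exact basis of left null vectors of the stoichiometry matrix.

    Each row dotted with every reaction vector is zero; the row count is
    ``n_species - rank``.  Rows are returned in canonical RREF form.
    """
    order = net.species_names
    smat = sympy.Matrix([[int(v) for v in row]
                         for row in net.stoichiometry_matrix().tolist()])
    if smat.cols == 0 or smat.rows == 0:
        basis = [[Fraction(1 if i == j else 0) for j in range(len(order))]
                 for i in range(len(order))]
        return ConservationLaws(order, _rref_rows(basis, len(order)))
    null = smat.T.nullspace()
    rows = [[Fraction(int(v.p), int(v.q)) for v in vec] for vec in null]
    return ConservationLaws(order, _rref_rows(rows, len(order)))


# ---------------------------------------------------------------------------
# mass-action dynamics


def mass_action_system(
    net: ReactionNetwork, rates: Mapping[str, float]
) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Build the mass-action ODE right-hand side and its Jacobian.

    The derivative of each species is the sum over reactions of
    ``rate * prod(concentration ** reactant order) * net stoichiometry``.
    Raises on a missing or non-positive rate.
    """
    kvec = np.empty(len(net.reactions))
    for j, rxn in enumerate(net.reactions):
        if rxn.rate_symbol not in rates:
            raise ValueError(f"missing rate for symbol {rxn.rate_symbol!r}")
        k = float(rates[rxn.rate_symbol])
        if not k > 0:
            raise ValueError(f"rate {rxn.rate_symbol!r} must be positive, got {k}")
        kvec[j] = k

    nmat = net.stoichiometry_matrix().astype(float)          # species x reactions
    ymat = net.reactant_matrix().astype(float)               # species x reactions
    n_species, n_rxn = nmat.shape

    def fluxes(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            # x**0 == 1 even at x == 0; only positive orders touch x
            terms = np.where(ymat > 0, x[:, None] ** ymat, 1.0)
        return kvec * terms.prod(axis=0)

    def f(x: np.ndarray) -> np.ndarray:
        return nmat @ fluxes(x)

    def jac(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        v = fluxes(x)
        out = np.zeros((n_species, n_species))
        for s in range(n_species):
            orders = ymat[s]
            mask = orders > 0
            if not mask.any():
                continue
            dv = np.zeros(n_rxn)
            xs = x[s]
            if xs != 0.0:
                dv[mask] = v[mask] * orders[mask] / xs
            else:
                # d(x^m)/dx at 0 is nonzero only for m == 1
                lin = mask & (orders == 1.0)
                if lin.any():
                    others = np.where(ymat > 0, x[:, None] ** ymat, 1.0)
                    others[s, :] = 1.0
                    dv[lin] = kvec[lin] * others[:, lin].prod(axis=0)
            out[:, s] = nmat @ dv
        return out

    return f, jac


# ---------------------------------------------------------------------------
# deficiency-theorem screen


class ScreenVerdict(str, Enum):
    NO_MULTISTATIONARITY = "no_multistationarity"
    INCONCLUSIVE = "inconclusive"


def _directed_complex_graph(net: ReactionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(complexes(net))
    for rxn in net.reactions:
        g.add_edge(rxn.reactant, rxn.product)
    return g


def is_weakly_reversible(net: ReactionNetwork) -> bool:
    """True iff every linkage class is strongly connected."""
    g = _directed_complex_graph(net)
    strong = {frozenset(c) for c in nx.strongly_connected_components(g)}
    weak = {frozenset(c) for c in nx.weakly_connected_components(g)}
    return strong == weak


def structural_screen(net: ReactionNetwork) -> ScreenVerdict:
    """Parameter-free screen based on the deficiency zero/one theorems.

    Deficiency zero: a weakly reversible network admits exactly one
    positive steady state per compatibility class; a non-weakly-reversible
    one admits none.  Either way multistationarity is excluded.

    Deficiency one: if every linkage class has deficiency at most one,
    the class deficiencies sum to the network deficiency, and each
    linkage class contains exactly one terminal strong-linkage class,
    then the network admits at most one positive steady state per
    compatibility class.  Anything else is inconclusive — in particular
    every member of the two-gene family (deficiency >= 2).
    """
    summary = deficiency(net)
    if summary.deficiency == 0:
        return ScreenVerdict.NO_MULTISTATIONARITY
    if summary.deficiency == 1:
        g = _directed_complex_graph(net)
        condensation = nx.condensation(g)
        order = net.species_names
        total_class_def = 0
        ok = True
        for cls in nx.weakly_connected_components(g):
            sub_rxns = [r for r in net.reactions
                        if r.reactant in cls and r.product in cls]
            s_theta = _int_rank([r.vector(order) for r in sub_rxns])
            d_theta = len(cls) - 1 - s_theta
            if d_theta > 1:
                ok = False
                break
            total_class_def += d_theta
            # terminal strong components within this linkage class
            members = {n for n, data in condensation.nodes(data=True)
                       if set(data["members"]) <= cls}
            terminal = [n for n in members if condensation.out_degree(n) == 0]
            if len(terminal) != 1:
                ok = False
                break
        if ok and total_class_def == summary.deficiency:
            return ScreenVerdict.NO_MULTISTATIONARITY
    return ScreenVerdict.INCONCLUSIVE


# ---------------------------------------------------------------------------
# text format


def _parse_complex(text: str) -> dict[str, int]:
    text = text.strip()
    if text == "0":
        return {}
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ValueError("empty term in complex")
        i = 0
        while i < len(term) and term[i].isdigit():
            i += 1
        count = int(term[:i]) if i else 1
        name = term[i:].strip()
        if not name:
            raise ValueError(f"malformed term {term!r}")
        coeffs[name] = coeffs.get(name, 0) + count
    return coeffs


def read_network(text: str, roles: Mapping[str, Role] | None = None) -> ReactionNetwork:
    """Parse the one-reaction-per-line text format.

    Lines look like ``2A + B -> C`` or ``A <-> B``; ``0`` is the empty
    complex; ``#`` starts a comment.  Rate symbols are ``k1, k1r, k2, ...``
    in line order (the ``r`` suffix marks the reverse direction).
    """
    roles = roles or {}
    reactions: list[Reaction] = []
    names: list[str] = []
    seen: set[str] = set()

    def register(coeffs: Mapping[str, int]):
        for n in coeffs:
            if n not in seen:
                seen.add(n)
                names.append(n)

    idx = 0
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        idx += 1
        reversible = "<->" in line
        lhs, rhs = line.split("<->" if reversible else "->")
        rc, pc = _parse_complex(lhs), _parse_complex(rhs)
        register(rc)
        register(pc)
        label = f"r{idx}"
        reactions.append(Reaction(Complex(rc), Complex(pc), f"k{idx}", label))
        if reversible:
            reactions.append(Reaction(Complex(pc), Complex(rc), f"k{idx}r", label))
    species = [Species(n, roles.get(n, Role.OTHER)) for n in names]
    return ReactionNetwork(species, reactions)


def write_network(net: ReactionNetwork) -> str:
    """Serialize to the text format; reversible pairs fold into ``<->``."""
    lines = []
    skip: set[int] = set()
    rxns = net.reactions
    for i, rxn in enumerate(rxns):
        if i in skip:
            continue
        arrow = "->"
        for j in range(i + 1, len(rxns)):
            other = rxns[j]
            if (j not in skip and other.label == rxn.label
                    and other.reactant == rxn.product
                    and other.product == rxn.reactant):
                arrow = "<->"
                skip.add(j)
                break
        lines.append(f"{format_complex(rxn.reactant)} {arrow} "
                     f"{format_complex(rxn.product)}")
    return "\n".join(lines) + "\n"
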