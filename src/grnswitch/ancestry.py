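"""Network ancestry: propagating bistability through the circuit lattice.

Circuits are partially ordered by label-set inclusion; a *descendant* is
obtained from a *parent* by adding one dependency-valid reaction.  If
the addition leaves the stoichiometric subspace identical (after
aligning species by name and padding missing ones with zeros), then the
descendant inherits the parent's capacity for bistability: the new
reaction can be given an arbitrarily small rate constant without
changing the surfaces that confine the dynamics, so the parent's two
stable equilibria persist.

This module builds the one-reaction extension lattice, tests subspace
preservation, closes a seed set of bistable circuits under
subspace-preserving extension, and identifies minimal bistable networks
(bistable circuits with no dependency-closed proper sub-circuit, up to
gene-swap symmetry, that is also bistable).
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from .crn import same_subspace
from .grammar import (GeneCircuit, _template_index, circuit_to_crn,
                      optional_templates)


@dataclass(frozen=True)
class AncestryEdge:
    parent: GeneCircuit
    child: GeneCircuit
    added_label: str
    subspace_preserving: bool


def one_reaction_extensions(circ: GeneCircuit) -> list[tuple[str, GeneCircuit]]:
    """All dependency-valid single-label additions.

    Children are returned as raw (uncanonicalized) label sets so that
    parent/child species alignment stays trivial along the lattice.
    """
    out = []
    for t in optional_templates(circ.n_genes):
        if t.label in circ.labels:
            continue
        if t.dependencies <= circ.labels:
            child = GeneCircuit(circ.labels | {t.label}, circ.n_genes)
            out.append((t.label, child))
    return out


def subspace_preserving(parent: GeneCircuit, added_label: str) -> bool:
    """Whether adding ``added_label`` leaves the stoichiometric subspace
    of the compiled network identical to the parent's."""
    idx = _template_index(parent.n_genes)
    if added_label not in idx or idx[added_label].essential:
        raise KeyError(f"unknown optional label {added_label!r}")
    if not idx[added_label].dependencies <= parent.labels:
        raise ValueError(
            f"adding {added_label!r} violates its dependencies")
    child = GeneCircuit(parent.labels | {added_label}, parent.n_genes)
    return same_subspace(circuit_to_crn(parent), circuit_to_crn(child))


def ancestry_closure(
    seeds: Iterable[GeneCircuit],
    family: Sequence[GeneCircuit] | None = None,
) -> set[GeneCircuit]:
    """Close a seed set under subspace-preserving one-reaction extension.

    Membership is tracked on canonical representatives; the returned set
    is canonical.  ``family``, when given, restricts which children are
    admitted (e.g. the cooperativity-free subfamily); by default any
    dependency-valid child is in play.
    """
    allowed = None
    if family is not None:
        allowed = {c.canonical().labels for c in family}
    closed: dict[frozenset[str], GeneCircuit] = {}
    queue: deque[GeneCircuit] = deque()
    for seed in seeds:
        canon = seed.canonical()
        if canon.labels not in closed:
            closed[canon.labels] = canon
            queue.append(seed)
    while queue:
        parent = queue.popleft()
        for label, child in one_reaction_extensions(parent):
            canon = child.canonical()
            if canon.labels in closed:
                continue
            if allowed is not None and canon.labels not in allowed:
                continue
            if subspace_preserving(parent, label):
                closed[canon.labels] = canon
                queue.append(child)
    return set(closed.values())


def contains_subnetwork(big: GeneCircuit, small: GeneCircuit,
                        up_to_symmetry: bool = True) -> bool:
    """Whether ``small`` (or, optionally, its mirror) is a label subset
    of ``big``."""
    if small.labels <= big.labels:
        return True
    if up_to_symmetry and small.swapped().labels <= big.labels:
        return True
    return False


def closed_subsets(circ: GeneCircuit,
                   proper: bool = True) -> list[GeneCircuit]:
    """All dependency-closed (optionally proper) sub-circuits."""
    idx = _template_index(circ.n_genes)
    labels = sorted(circ.labels)
    out = []
    for r in range(len(labels) + (0 if proper else 1)):
        for sub in itertools.combinations(labels, r):
            sset = frozenset(sub)
            if all(idx[l].dependencies <= sset for l in sset):
                out.append(GeneCircuit(sset, circ.n_genes))
    return out


def minimal_networks(bistable: Iterable[GeneCircuit]) -> set[GeneCircuit]:
    """Members of a bistable set with no proper dependency-closed
    sub-circuit (up to gene-swap symmetry) also in the set.

    Minimality is assessed against all dependency-closed proper subsets,
    not just one-reaction deletions: a bistable sub-circuit several
    reactions smaller equally disqualifies its supersets.
    """
    canon = {c.canonical().labels: c.canonical() for c in bistable}
    out = set()
    for labels, circ in canon.items():
        minimal = True
        for sub in closed_subsets(circ, proper=True):
            if sub.canonical().labels in canon:
                minimal = False
                break
        if minimal:
            out.add(circ)
    return out
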