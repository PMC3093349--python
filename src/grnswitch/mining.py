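"""Mining interaction tables for two-gene circuit topologies.

Elementary-reaction circuit models are translated into coarse
interaction patterns — who binds whose promoter, with what dimerization
and what regulatory sign — and those patterns are searched for in
protein-protein / protein-DNA interaction tables of the kind curated
for yeast.  Translation convention: a promoter-binding reaction with
the matching production-from-bound reaction present is an activating
(or sign-unknown) edge; binding without production is repressing (or
sign-unknown); a dimer binding requires its dimerization edge and
protein-DNA edges from every dimer constituent.  A missing sign
annotation is compatible with any constraint.

No database access happens here: a seeded fixture generator produces
tables with planted motifs and guaranteed-inert decoy edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grammar import GeneCircuit, _template_index


class Effect(str, Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    UNKNOWN = "unknown"


class EdgeConstraint(str, Enum):
    ACTIVATION_OR_UNKNOWN = "activation-or-unknown"
    REPRESSION_OR_UNKNOWN = "repression-or-unknown"
    ANY = "any"

    def admits(self, effect: Effect | None) -> bool:
        if effect is None or effect is Effect.UNKNOWN or self is EdgeConstraint.ANY:
            return True
        if self is EdgeConstraint.ACTIVATION_OR_UNKNOWN:
            return effect is Effect.ACTIVATION
        return effect is Effect.REPRESSION


@dataclass
class InteractionTables:
    """Transcription-factor interaction data.

    ``ppi`` holds unordered protein pairs (a self-pair is a homodimer);
    ``pdi`` holds (protein, target gene) promoter-binding pairs;
    ``effects`` optionally annotates pdi pairs with a regulatory sign.
    """

    tf_genes: set[str]
    ppi: set[frozenset[str]] = field(default_factory=set)
    pdi: set[tuple[str, str]] = field(default_factory=set)
    effects: dict[tuple[str, str], Effect] = field(default_factory=dict)

    def __post_init__(self):
        for pair in self.ppi:
            if not pair <= self.tf_genes:
                raise ValueError(f"ppi pair {set(pair)} outside declared TFs")
        for prot, gene in self.pdi:
            if prot not in self.tf_genes or gene not in self.tf_genes:
                raise ValueError(f"pdi ({prot}, {gene}) outside declared TFs")
        extra = set(self.effects) - self.pdi
        if extra:
            raise ValueError(f"effect annotations without pdi edge: {extra}")

    def has_dimer(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.ppi


@dataclass(frozen=True)
class PatternEdge:
    """A required promoter-binding edge of a motif pattern.

    ``binder`` is one protein slot (monomer) or two (dimer constituents,
    gene slots 1-based); ``target`` is the bound gene slot.
    """

    binder: tuple[int, ...]
    target: int
    constraint: EdgeConstraint


@dataclass(frozen=True)
class MotifPattern:
    circuit: str
    edges: tuple[PatternEdge, ...]
    dimerizations: tuple[tuple[int, ...], ...]


def circuit_to_pattern(circ: GeneCircuit) -> MotifPattern:
    """Translate a two-gene circuit into its interaction pattern."""
    if circ.n_genes != 2:
        raise ValueError("pattern translation is defined for two-gene circuits")
    idx = _template_index(circ.n_genes)
    present = {(t.kind, t.gene, tuple(sorted(t.partners)))
               for t in (idx[l] for l in circ.labels)}
    edges = []
    dimerizations = set()
    for kind, gene, pq in sorted(present):
        if kind == "dimerize":
            dimerizations.add(pq)
        elif kind in ("bind_monomer", "bind_dimer"):
            prod_kind = ("prod_monomer_bound" if kind == "bind_monomer"
                         else "prod_dimer_bound")
            has_prod = (prod_kind, gene, pq) in present
            constraint = (EdgeConstraint.ACTIVATION_OR_UNKNOWN if has_prod
                          else EdgeConstraint.REPRESSION_OR_UNKNOWN)
            edges.append(PatternEdge(pq, gene, constraint))
    return MotifPattern(circ.name, tuple(edges), tuple(sorted(dimerizations)))


def _assignment_matches(tables: InteractionTables, pattern: MotifPattern,
                        genes: tuple[str, str]) -> bool:
    slot = {1: genes[0], 2: genes[1]}
    for pq in pattern.dimerizations:
        if not tables.has_dimer(slot[pq[0]], slot[pq[-1]]):
            return False
    for edge in pattern.edges:
        target = slot[edge.target]
        for p in set(edge.binder):
            prot = slot[p]
            if (prot, target) not in tables.pdi:
                return False
            if not edge.constraint.admits(tables.effects.get((prot, target))):
                return False
    return True


def match_motifs(tables: InteractionTables,
                 patterns: Sequence[MotifPattern]
                 ) -> list[tuple[MotifPattern, tuple[str, str]]]:
    """All ordered assignments of distinct gene pairs matching each pattern.

    The assignment maps pattern gene slot 1 to the first gene of the
    returned pair and slot 2 to the second.
    """
    out = []
    genes = sorted(tables.tf_genes)
    for pattern in patterns:
        for pair in itertools.permutations(genes, 2):
            if _assignment_matches(tables, pattern, pair):
                out.append((pattern, pair))
    return out


# ---------------------------------------------------------------------------
# fixture generation


def generate_fixture(rng_seed: int, n_genes: int, n_decoy_edges: int,
                     planted: Sequence[tuple[GeneCircuit, tuple[str, str]]]
                     ) -> InteractionTables:
    """Synthetic interaction tables with planted motifs and inert decoys.

    Gene identifiers are ``G001 .. G<n>`` plus any planted names.  The
    planted circuits' pattern edges are inserted exactly (with their
    sign annotations); decoy edges are then added one at a time,
    rejecting any edge that would create a new match for any planted
    pattern.  Deterministic given the seed.
    """
    names = {f"G{i:03d}" for i in range(1, n_genes + 1)}
    for _, pair in planted:
        names.update(pair)
    pairs = [pair for _, pair in planted]
    if len(set(pairs)) != len(pairs):
        raise ValueError("planted gene pairs must be distinct")
    tables = InteractionTables(tf_genes=set(names))
    patterns = []
    for circ, pair in planted:
        pattern = circuit_to_pattern(circ)
        patterns.append(pattern)
        slot = {1: pair[0], 2: pair[1]}
        for pq in pattern.dimerizations:
            tables.ppi.add(frozenset((slot[pq[0]], slot[pq[-1]])))
        for edge in pattern.edges:
            target = slot[edge.target]
            for p in set(edge.binder):
                key = (slot[p], target)
                tables.pdi.add(key)
                if edge.constraint is EdgeConstraint.ACTIVATION_OR_UNKNOWN:
                    tables.effects[key] = Effect.ACTIVATION
                elif edge.constraint is EdgeConstraint.REPRESSION_OR_UNKNOWN:
                    tables.effects[key] = Effect.REPRESSION

    baseline = {(p.circuit, pair) for p, pair in match_motifs(tables, patterns)}
    rng = np.random.default_rng(rng_seed)
    gene_list = sorted(names)
    placed = 0
    attempts = 0
    max_attempts = 200 * max(1, n_decoy_edges)
    while placed < n_decoy_edges:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"infeasible decoy budget: placed {placed} of {n_decoy_edges}")
        kind = rng.choice(("pdi", "ppi"))
        a, b = rng.choice(gene_list, size=2, replace=True)
        if kind == "pdi":
            if a == b or (a, b) in tables.pdi:
                continue
            tables.pdi.add((a, b))
            now = {(p.circuit, pair) for p, pair in match_motifs(tables, patterns)}
            if now != baseline:
                tables.pdi.discard((a, b))
                continue
        else:
            pair = frozenset((a, b))
            if pair in tables.ppi:
                continue
            tables.ppi.add(pair)
            now = {(p.circuit, pr) for p, pr in match_motifs(tables, patterns)}
            if now != baseline:
                tables.ppi.discard(pair)
                continue
        placed += 1
    return tables


# ---------------------------------------------------------------------------
# TSV input/output


def read_tables(tf_path: str | Path, ppi_path: str | Path | None = None,
                pdi_path: str | Path | None = None,
                effects_path: str | Path | None = None) -> InteractionTables:
    """Read interaction tables from headerless TSV files.

    ``tf`` has one gene identifier per line; ``ppi`` two protein
    columns; ``pdi`` protein and target-gene columns; ``effects``
    protein, gene and effect columns.  Malformed rows are reported with
    their line numbers.
    """
    tfs = {line.strip() for line in Path(tf_path).read_text().splitlines()
           if line.strip()}

    def load(path, n_cols, what):
        rows = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}: line {i}: expected {n_cols} {what} columns, "
                    f"got {len(parts)}")
            rows.append(tuple(p.strip() for p in parts))
        return rows

    ppi = set()
    if ppi_path is not None:
        for a, b in load(ppi_path, 2, "ppi"):
            ppi.add(frozenset((a, b)))
    pdi = set()
    if pdi_path is not None:
        pdi = {(a, b) for a, b in load(pdi_path, 2, "pdi")}
    effects = {}
    if effects_path is not None:
        for a, b, eff in load(effects_path, 3, "effects"):
            effects[(a, b)] = Effect(eff)
    return InteractionTables(tfs, ppi, pdi, effects)


def write_tables(tables: InteractionTables, directory: str | Path) -> dict[str, Path]:
    """Write the four TSVs into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["tf"] = directory / "tf_genes.tsv"
    paths["tf"].write_text("\n".join(sorted(tables.tf_genes)) + "\n")
    paths["ppi"] = directory / "ppi.tsv"
    rows = ["\t".join(sorted(p) if len(p) == 2 else list(p) * 2)
            for p in sorted(tables.ppi, key=sorted)]
    paths["ppi"].write_text("\n".join(rows) + ("\n" if rows else ""))
    paths["pdi"] = directory / "pdi.tsv"
    rows = ["\t".join(p) for p in sorted(tables.pdi)]
    paths["pdi"].write_text("\n".join(rows) + ("\n" if rows else ""))
    paths["effects"] = directory / "effects.tsv"
    rows = [f"{a}\t{b}\t{e.value}" for (a, b), e in sorted(tables.effects.items())]
    paths["effects"].write_text("\n".join(rows) + ("\n" if rows else ""))
    return paths


def matches_to_frame(matches: Sequence[tuple[MotifPattern, tuple[str, str]]]
                     ) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.circuit, g1, g2) for p, (g1, g2) in matches],
        columns=["circuit", "X1", "X2"])
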