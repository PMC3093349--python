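"""End-to-end survey: enumerate, screen, certify, grow, and report.

The pipeline mirrors a parameter-free bistability survey of the
two-gene family: enumerate the (possibly filtered) circuit family,
compute the structural CRNT quantities per circuit, certify seed
circuits numerically, propagate certificates outward along the
one-reaction extension lattice (numerical continuation, with the
subspace-preservation test recorded for each edge), and emit a
per-circuit TSV plus an aggregate JSON summary.

Verdicts: ``bistable_confirmed`` requires a validated certificate;
``multiple_unconfirmed`` records that several equilibria were seen in
one compatibility class but never two stable ones; ``monostable`` is
only assigned from closed-form reasoning (the rudimentary circuit's
linear dynamics), never from a failed numerical search, which yields
``unknown``.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import oracle as orc
from .crn import deficiency
from .grammar import (GeneCircuit, circuit, circuit_to_crn, enumerate_family,
                      is_cooperativity_free, is_decoupled)

VERDICTS = ("bistable_confirmed", "multiple_unconfirmed", "monostable",
            "unknown")

DEFAULT_CONFIG: dict = {
    "genes": 2,
    "filter": "all",          # all | decoupled | coop-free
    "seeds": (),              # circuit names to certify first
    "budget": 200,            # oracle draws per seed
    "rng_seed": 0,
    "grow": True,             # continue certificates along the lattice
    "scheme": "guided",
    "output_dir": None,
}


def closed_form_monostable(circ: GeneCircuit) -> bool:
    """True when uniqueness of the equilibrium is provable in closed form.

    The rudimentary circuit (no optional reactions) has linear
    mass-action dynamics with a unique globally attracting equilibrium;
    any optional reaction introduces a bimolecular term.
    """
    return not circ.labels


def oracle_scan(circ: GeneCircuit, budget: int, rng_seed: int,
                scheme: str = "guided"
                ) -> tuple[orc.BistabilityCertificate | None, bool]:
    """Certificate search that also reports whether any draw showed
    multiple equilibria in one compatibility class."""
    saw_multiple = False
    for draw in range(budget):
        seed = np.random.SeedSequence([rng_seed, draw]).generate_state(1)[0]
        rates = orc.sample_rates(circ, int(seed), scheme=scheme)
        eqs = orc.circuit_equilibria(circ, rates)
        if len(eqs) >= 2:
            saw_multiple = True
        cert = orc._certificate_from(circ, rates, eqs, rng_seed)
        if cert is not None:
            return cert, True
    return None, saw_multiple


@dataclass
class SurveyReport:
    rows: pd.DataFrame
    certificates: dict[str, orc.BistabilityCertificate]
    summary: dict

    def to_files(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "survey.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=1,
                                                     sort_keys=True) + "\n")
        certdir = out / "certs"
        certdir.mkdir(exist_ok=True)
        for name, cert in sorted(self.certificates.items()):
            fname = name if name else "rudimentary"
            (certdir / f"{fname}.json").write_text(cert.to_json())


def run_survey(config: Mapping | None = None) -> SurveyReport:
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    unknown_keys = set(cfg) - set(DEFAULT_CONFIG)
    if unknown_keys:
        raise ValueError(f"unknown config keys: {sorted(unknown_keys)}")

    family = enumerate_family(cfg["genes"])
    if cfg["genes"] == 2:
        if cfg["filter"] == "decoupled":
            family = [c for c in family if is_decoupled(c)]
        elif cfg["filter"] == "coop-free":
            family = [c for c in family if is_cooperativity_free(c)]
        elif cfg["filter"] != "all":
            raise ValueError(f"unknown filter {cfg['filter']!r}")
    members = {c.labels: c for c in family}

    verdict: dict[frozenset, str] = {}
    provenance: dict[frozenset, str] = {}
    certs: dict[frozenset, orc.BistabilityCertificate] = {}
    for c in family:
        verdict[c.labels] = ("monostable" if closed_form_monostable(c)
                             else "unknown")
        provenance[c.labels] = ""

    # certify seeds
    queue: deque[GeneCircuit] = deque()
    for name in cfg["seeds"]:
        seed_circ = circuit(name, cfg["genes"]).canonical()
        if seed_circ.labels not in members:
            raise ValueError(f"seed {name!r} not in the surveyed family")
        cert, saw_multiple = oracle_scan(seed_circ, cfg["budget"],
                                         cfg["rng_seed"], cfg["scheme"])
        if cert is not None:
            verdict[seed_circ.labels] = "bistable_confirmed"
            provenance[seed_circ.labels] = "seed"
            certs[seed_circ.labels] = cert
            queue.append(seed_circ)
        elif saw_multiple:
            verdict[seed_circ.labels] = "multiple_unconfirmed"

    # grow certificates outward along the one-reaction extension lattice
    if cfg["grow"]:
        while queue:
            parent = queue.popleft()
            parent_cert = certs[parent.canonical().labels]
            for label, child in anc.one_reaction_extensions(parent):
                canon = child.canonical()
                if canon.labels not in members:
                    continue
                if verdict[canon.labels] == "bistable_confirmed":
                    continue
                grown = orc.grow_certificate(parent_cert, child, label)
                if grown is not None and orc.validate_certificate(grown):
                    preserved = anc.subspace_preserving(parent, label)
                    verdict[canon.labels] = "bistable_confirmed"
                    provenance[canon.labels] = (
                        f"growth:{parent.name}+{label}"
                        + (":subspace-preserved" if preserved else ""))
                    certs[canon.labels] = grown
                    queue.append(child)

    rows = []
    for c in family:
        summary = deficiency(circuit_to_crn(c))
        rows.append({
            "circuit": c.name,
            "size": c.size,
            "n_species": len(circuit_to_crn(c).species),
            "n_complexes": summary.n_complexes,
            "n_linkage_classes": summary.n_linkage_classes,
            "rank": summary.rank,
            "deficiency": summary.deficiency,
            "decoupled": is_decoupled(c) if cfg["genes"] == 2 else True,
            "coop_free": (is_cooperativity_free(c)
                          if cfg["genes"] == 2 else None),
            "verdict": verdict[c.labels],
            "certificate": c.name if c.labels in certs else "",
            "provenance": provenance[c.labels],
        })
    frame = pd.DataFrame(rows)

    descendants = {
        name: sorted(c.name for c in family
                     if anc.contains_subnetwork(
                         c, circuit(name, cfg["genes"]), up_to_symmetry=True))
        for name in cfg["seeds"]}
    agg = {
        "family_size": int(len(frame)),
        "n_decoupled": int(frame["decoupled"].sum()),
        "n_coop_free": (int(frame["coop_free"].sum())
                        if cfg["genes"] == 2 else None),
        "min_deficiency": int(frame["deficiency"].min()),
        "n_bistable_confirmed": int(
            (frame["verdict"] == "bistable_confirmed").sum()),
        "n_multiple_unconfirmed": int(
            (frame["verdict"] == "multiple_unconfirmed").sum()),
        "n_monostable": int((frame["verdict"] == "monostable").sum()),
        "n_unknown": int((frame["verdict"] == "unknown").sum()),
        "seed_descendants": descendants,
    }
    report = SurveyReport(frame,
                          {members[k].name: v for k, v in certs.items()},
                          agg)
    if cfg["output_dir"]:
        report.to_files(cfg["output_dir"])
    return report


def read_config(path: str | Path) -> dict:
    """Flat key=value config file; '#' comments; seeds comma-separated."""
    cfg: dict = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i}: expected key=value")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in ("genes", "budget", "rng_seed"):
            cfg[key] = int(value)
        elif key == "seeds":
            cfg[key] = tuple(s.strip() for s in value.split(",") if s.strip())
        elif key == "grow":
            cfg[key] = value.lower() in ("1", "true", "yes")
        else:
            cfg[key] = value
    return cfg
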