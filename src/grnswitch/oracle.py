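"""Numerical bistability certification for gene circuits.

A circuit is *bistable* if for some choice of mass-action rate constants
it admits two distinct asymptotically stable positive equilibria within
a single stoichiometric compatibility class.  This module searches for
such rate constants by repeated sampling, locates all equilibria for
each draw, classifies their stability from the Jacobian restricted to
the stoichiometric subspace, and packages a successful draw as a
:class:`BistabilityCertificate`.  Absence of a certificate is never a
proof of monostability — the verdict for a circuit without one stays
"unknown".

Equilibrium finding exploits a structural property of the grammar: at
any steady state every bound-gene species is in binding equilibrium
(production from a bound gene does not consume the bound state), and
consequently every dimer is in dimerization equilibrium too.  All
equilibria therefore lie on a manifold parameterized by the free
monomer concentrations alone, and the steady-state problem reduces to
one balance equation per gene.  Roots of the reduced system are located
by dense multistart Newton iteration, lifted to the full species space,
polished on the full network, and classified there.

Concentrations are dimensionless, scaled so that each gene's total DNA
equals one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.integrate import solve_ivp

from .crn import ReactionNetwork, conservation_laws, mass_action_system
from .grammar import GeneCircuit, _template_index, circuit, circuit_to_crn

#: asymptotic stability requires all reduced eigenvalues below -STABILITY_TOL;
#: within +/-STABILITY_TOL of zero the verdict is "marginal"
STABILITY_TOL = 1e-6
#: equilibria closer than this relative L-infinity distance are one point
DEDUP_TOL = 1e-4
#: strict positivity threshold for certificate equilibria
POSITIVITY_TOL = 1e-10
#: accepted max |dx/dt| at an equilibrium
RESIDUAL_TOL = 1e-8


class Stability(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    MARGINAL = "marginal"


@dataclass
class Equilibrium:
    state: np.ndarray
    residual: float
    stability: Stability
    leading_real: float

    def to_dict(self) -> dict:
        return {"state": [float(v) for v in self.state],
                "residual": self.residual,
                "stability": self.stability.value,
                "leading_real": self.leading_real}

    @classmethod
    def from_dict(cls, d: dict) -> "Equilibrium":
        return cls(np.array(d["state"], dtype=float), d["residual"],
                   Stability(d["stability"]), d["leading_real"])


@dataclass
class BistabilityCertificate:
    """Rate constants and a pair of stable equilibria proving bistability."""

    circuit: str
    n_genes: int
    rates: dict[str, float]
    totals: tuple[float, ...]
    equilibria: list[Equilibrium]
    seed: int

    @property
    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability is Stability.STABLE]

    @property
    def unstable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability is Stability.UNSTABLE]

    def to_json(self) -> str:
        return json.dumps({
            "circuit": self.circuit, "n_genes": self.n_genes,
            "rates": self.rates, "totals": list(self.totals),
            "equilibria": [e.to_dict() for e in self.equilibria],
            "seed": self.seed}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BistabilityCertificate":
        d = json.loads(text)
        return cls(d["circuit"], d["n_genes"], dict(d["rates"]),
                   tuple(d["totals"]),
                   [Equilibrium.from_dict(e) for e in d["equilibria"]],
                   d["seed"])


# ---------------------------------------------------------------------------
# rate sampling


def _symbol_kinds(circ: GeneCircuit) -> dict[str, str]:
    """Classify each rate symbol of a circuit by its biochemical role."""
    idx = _template_index(circ.n_genes)
    out: dict[str, str] = {}
    for rxn in circuit_to_crn(circ).reactions:
        t = idx[rxn.label]
        sym = rxn.rate_symbol
        if t.kind == "basal":
            out[sym] = "basal"
        elif t.kind == "degrade":
            out[sym] = "degrade"
        elif t.kind in ("prod_monomer_bound", "prod_dimer_bound"):
            out[sym] = "production_bound"
        elif sym.endswith("_on"):
            out[sym] = "bind_on" if t.kind.startswith("bind") else "dimer_on"
        else:
            out[sym] = "off"
    return out


#: log10 sampling windows of the guided scheme, by biochemical role.
#: Switch-like behavior favors tight, fast promoter/dimer binding, weak
#: basal expression, and bound-state production that can exceed basal.
GUIDED_WINDOWS = {
    "basal": (-2.0, 0.5),
    "degrade": (-1.0, 1.0),
    "production_bound": (-1.0, 2.0),
    "bind_on": (0.0, 2.5),
    "dimer_on": (0.0, 2.0),
    "off": (-2.0, 1.0),
}


def sample_rates(circ: GeneCircuit, rng_seed: int,
                 low: float = 1e-3, high: float = 1e3,
                 scheme: str = "log-uniform") -> dict[str, float]:
    """Draw one positive rate constant per rate symbol.

    ``scheme="log-uniform"`` draws every rate log-uniformly on
    ``[low, high]``.  ``scheme="guided"`` draws each rate log-uniformly
    within a role-specific window (still inside ``[low, high]``) chosen
    to make switch-supporting regimes common.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(rng_seed)
    kinds = _symbol_kinds(circ)
    out: dict[str, float] = {}
    for rxn in circuit_to_crn(circ).reactions:
        sym = rxn.rate_symbol
        if sym in out:
            continue
        if scheme == "log-uniform":
            lo, hi = math.log10(low), math.log10(high)
        elif scheme == "guided":
            lo, hi = GUIDED_WINDOWS[kinds[sym]]
            lo = max(lo, math.log10(low))
            hi = min(hi, math.log10(high))
        else:
            raise ValueError(f"unknown sampling scheme {scheme!r}")
        out[sym] = float(10.0 ** rng.uniform(lo, hi))
    return out


# ---------------------------------------------------------------------------
# reduced (per-monomer) steady-state equations


@dataclass
class _GeneBalance:
    basal: float
    degrade: float
    # each binder: (protein indices 0-based, effective K, bound production rate)
    binders: list[tuple[tuple[int, ...], float, float]] = field(default_factory=list)


def _reduced_structure(circ: GeneCircuit,
                       rates: Mapping[str, float]) -> list[_GeneBalance]:
    idx = _template_index(circ.n_genes)
    templates = {(t.kind, t.gene, tuple(sorted(t.partners))): t
                 for t in (idx[l] for l in circ.labels)}
    dimer_k: dict[tuple[int, ...], float] = {}
    for (kind, _, pq), t in templates.items():
        if kind == "dimerize":
            dimer_k[pq] = rates[f"k_{t.label}_on"] / rates[f"k_{t.label}_off"]
    balances = []
    for g in range(1, circ.n_genes + 1):
        bal = _GeneBalance(rates[f"k_B{g}"], rates[f"k_D{g}"])
        for (kind, gg, pq), t in templates.items():
            if gg != g or kind not in ("bind_monomer", "bind_dimer"):
                continue
            k_eff = rates[f"k_{t.label}_on"] / rates[f"k_{t.label}_off"]
            if kind == "bind_dimer":
                k_eff *= dimer_k[pq]
            prod_kind = ("prod_monomer_bound" if kind == "bind_monomer"
                         else "prod_dimer_bound")
            prod_t = templates.get((prod_kind, g, pq))
            prod = rates[f"k_{prod_t.label}"] if prod_t is not None else 0.0
            # for a homodimer binder, C = K_dimer * p^2 enters via pq=(p,p)
            bal.binders.append((tuple(i - 1 for i in pq), k_eff, prod))
        balances.append(bal)
    return balances


def _reduced_f(balances: Sequence[_GeneBalance], P: np.ndarray) -> np.ndarray:
    """Net monomer balance per gene; ``P`` has shape (m, n_genes)."""
    out = np.empty_like(P)
    for g, bal in enumerate(balances):
        num = np.full(P.shape[0], bal.basal)
        den = np.ones(P.shape[0])
        for pidx, k_eff, prod in bal.binders:
            c = k_eff * np.prod(P[:, list(pidx)], axis=1)
            num += prod * c
            den += c
        out[:, g] = num / den - bal.degrade * P[:, g]
    return out


def _lift(circ: GeneCircuit, rates: Mapping[str, float],
          p: np.ndarray) -> np.ndarray:
    """Full species state on the binding-equilibrium manifold at monomer
    concentrations ``p`` (gene totals equal one)."""
    idx = _template_index(circ.n_genes)
    net = circuit_to_crn(circ)
    templates = {(t.kind, t.gene, tuple(sorted(t.partners))): t
                 for t in (idx[l] for l in circ.labels)}
    dimer_k = {}
    for (kind, _, pq), t in templates.items():
        if kind == "dimerize":
            dimer_k[pq] = rates[f"k_{t.label}_on"] / rates[f"k_{t.label}_off"]
    conc: dict[str, float] = {}
    for g in range(1, circ.n_genes + 1):
        conc[f"P{g}"] = float(p[g - 1])
    for pq, kd in dimer_k.items():
        name = "".join(f"P{i}" for i in pq)
        conc[name] = kd * float(np.prod([p[i - 1] for i in pq]))
    for g in range(1, circ.n_genes + 1):
        occ = []
        for (kind, gg, pq), t in templates.items():
            if gg != g or kind not in ("bind_monomer", "bind_dimer"):
                continue
            k_eff = rates[f"k_{t.label}_on"] / rates[f"k_{t.label}_off"]
            c = float(np.prod([p[i - 1] for i in pq]))
            if kind == "bind_dimer":
                k_eff *= dimer_k[pq]
            bound_name = (f"X{g}P{pq[0]}" if kind == "bind_monomer"
                          else f"X{g}" + "".join(f"P{i}" for i in pq))
            occ.append((bound_name, k_eff * c))
        den = 1.0 + sum(v for _, v in occ)
        conc[f"X{g}"] = 1.0 / den
        for name, v in occ:
            conc[name] = v / den
    return np.array([conc[s] for s in net.species_names])


def _subspace_orth(net: ReactionNetwork) -> np.ndarray:
    """Orthonormal basis (columns) of the stoichiometric subspace."""
    smat = net.stoichiometry_matrix().astype(float)
    return scipy.linalg.orth(smat)


def _classify(jac_x: np.ndarray, basis: np.ndarray) -> tuple[Stability, float]:
    reduced = basis.T @ jac_x @ basis
    lead = float(np.max(np.linalg.eigvals(reduced).real)) if reduced.size else -np.inf
    if lead < -STABILITY_TOL:
        return Stability.STABLE, lead
    if lead > STABILITY_TOL:
        return Stability.UNSTABLE, lead
    return Stability.MARGINAL, lead


def _polish_and_classify(net: ReactionNetwork, rates: Mapping[str, float],
                         states: list[np.ndarray],
                         residual_tol: float = RESIDUAL_TOL
                         ) -> list[Equilibrium]:
    """Newton-polish candidate states on the full network and classify.

    Polishing moves only within the stoichiometric subspace, so the
    conserved totals of each candidate are preserved exactly.
    """
    if not states:
        return []
    f, jac = mass_action_system(net, rates)
    basis = _subspace_orth(net)
    out: list[Equilibrium] = []
    for x in states:
        x = np.array(x, dtype=float)
        for _ in range(6):
            r = f(x)
            if np.max(np.abs(r)) < 1e-13:
                break
            red = basis.T @ jac(x) @ basis
            try:
                y = np.linalg.solve(red, basis.T @ r)
            except np.linalg.LinAlgError:
                y, *_ = np.linalg.lstsq(red, basis.T @ r, rcond=None)
            step = basis @ y
            nrm = np.max(np.abs(step))
            if nrm > 1.0:          # keep polish local
                step = step / nrm
            x = x - step
        if np.min(x) < -1e-9:
            continue
        x = np.clip(x, 0.0, None)
        residual = float(np.max(np.abs(f(x))))
        if residual > residual_tol:
            continue
        stab, lead = _classify(jac(x), basis)
        out.append(Equilibrium(x, residual, stab, lead))
    # deduplicate at relative L-infinity distance
    dedup: list[Equilibrium] = []
    for eq in out:
        scale = max(1e-30, float(np.max(np.abs(eq.state))))
        if all(np.max(np.abs(eq.state - other.state)) > DEDUP_TOL * max(
                scale, float(np.max(np.abs(other.state)))) for other in dedup):
            dedup.append(eq)
    return dedup


def circuit_equilibria(circ: GeneCircuit, rates: Mapping[str, float],
                       n_grid: int = 10,
                       residual_tol: float = RESIDUAL_TOL) -> list[Equilibrium]:
    """All equilibria of a circuit (gene totals one) for given rates.

    Solves the reduced per-monomer balance by dense multistart Newton in
    log-concentration space, lifts the roots onto the full species
    space, polishes them there, and classifies stability on the
    subspace-restricted Jacobian.
    """
    balances = _reduced_structure(circ, rates)
    n = circ.n_genes
    axes = [np.linspace(-5.0, 3.5, n_grid)] * n
    mesh = np.meshgrid(*axes, indexing="ij")
    U = np.stack([m.ravel() for m in mesh], axis=1) * math.log(10.0)
    # include the closed-form basal/degradation point
    u0 = np.array([[math.log(max(b.basal / b.degrade, 1e-12))
                    for b in balances]])
    U = np.vstack([U, u0])

    h = 1e-7
    for _ in range(80):
        P = np.exp(U)
        F = _reduced_f(balances, P)
        J = np.empty((U.shape[0], n, n))
        for j in range(n):
            up = U.copy(); up[:, j] += h
            dn = U.copy(); dn[:, j] -= h
            J[:, :, j] = (_reduced_f(balances, np.exp(up))
                          - _reduced_f(balances, np.exp(dn))) / (2 * h)
        try:
            du = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            du = np.stack([np.linalg.lstsq(J[i], F[i], rcond=None)[0]
                           for i in range(U.shape[0])])
        du = np.clip(du, -2.0, 2.0)
        U = U - du
        U = np.clip(U, -60.0, 25.0)
    P = np.exp(U)
    F = _reduced_f(balances, P)
    scale = np.array([max(1.0, b.basal) for b in balances])
    ok = np.all(np.abs(F) < 1e-9 * scale, axis=1)
    roots: list[np.ndarray] = []
    for p in P[ok]:
        if any(np.max(np.abs(np.log(p) - np.log(r))) < 1e-5 for r in roots):
            continue
        roots.append(p)
    net = circuit_to_crn(circ)
    states = [_lift(circ, rates, p) for p in roots]
    return _polish_and_classify(net, rates, states, residual_tol)


# ---------------------------------------------------------------------------
# general-network equilibrium search


def find_equilibria(net: ReactionNetwork, rates: Mapping[str, float],
                    totals: Sequence[float], n_starts: int = 40,
                    rng_seed: int = 0,
                    residual_tol: float = RESIDUAL_TOL) -> list[Equilibrium]:
    """Multistart equilibrium search on an arbitrary reaction network.

    ``totals`` fixes the stoichiometric compatibility class: one value
    per conservation law, in the row order of
    :func:`grnswitch.crn.conservation_laws`.  Starts are a log-spread
    cloud around a non-negative reference state satisfying the totals.
    Non-convergent starts are skipped.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    laws = conservation_laws(net)
    cmat = laws.matrix()
    totals = np.asarray(totals, dtype=float)
    if totals.shape[0] != cmat.shape[0]:
        raise ValueError(
            f"expected {cmat.shape[0]} conserved totals, got {totals.shape[0]}")
    f, jac = mass_action_system(net, rates)
    nsp = len(net.species)
    if cmat.shape[0]:
        x_ref, _ = scipy.optimize.nnls(cmat, totals)
    else:
        x_ref = np.ones(nsp)
    scale = max(1.0, float(np.max(x_ref)) if x_ref.size else 1.0)

    def residuals(x):
        parts = [f(x)]
        if cmat.shape[0]:
            parts.append((cmat @ x - totals) * max(1.0, 1.0 / scale))
        return np.concatenate(parts)

    rng = np.random.default_rng(rng_seed)
    starts = [np.maximum(x_ref, 1e-6 * scale)]
    for _ in range(n_starts - 1):
        jitter = 10.0 ** rng.uniform(-4, 1, size=nsp)
        starts.append(np.maximum(x_ref, 1e-6 * scale) * jitter)
    candidates = []
    for x0 in starts:
        sol = scipy.optimize.least_squares(
            residuals, x0, bounds=(np.zeros(nsp), np.full(nsp, np.inf)),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
        if np.max(np.abs(sol.fun)) < 1e-6 * scale:
            candidates.append(sol.x)
    eqs = _polish_and_classify(net, rates, candidates, residual_tol)
    # keep only the requested compatibility class (polish preserves it)
    if cmat.shape[0]:
        eqs = [e for e in eqs
               if np.max(np.abs(cmat @ e.state - totals)) < 1e-6 * scale]
    return eqs


# ---------------------------------------------------------------------------
# bistability search


def default_totals(circ: GeneCircuit) -> tuple[float, ...]:
    """Conserved totals of the compatibility class with all DNA free and
    no protein (each gene's total DNA equal to one)."""
    net = circuit_to_crn(circ)
    laws = conservation_laws(net)
    ref = np.array([1.0 if sp.role.value == "gene" else 0.0
                    for sp in net.species])
    return tuple(float(v) for v in laws.totals(ref))


def _certificate_from(circ: GeneCircuit, rates: Mapping[str, float],
                      eqs: list[Equilibrium], seed: int
                      ) -> BistabilityCertificate | None:
    stable = [e for e in eqs if e.stability is Stability.STABLE
              and np.min(e.state) > POSITIVITY_TOL]
    if len(stable) < 2:
        return None
    stable.sort(key=lambda e: float(e.state.sum()))
    unstable = [e for e in eqs if e.stability is Stability.UNSTABLE]
    chosen = [stable[0], stable[-1]] + unstable[:1]
    return BistabilityCertificate(
        circuit=circ.name, n_genes=circ.n_genes,
        rates={k: float(v) for k, v in rates.items()},
        totals=default_totals(circ), equilibria=chosen, seed=seed)


def is_bistable(circ: GeneCircuit, budget: int = 400, rng_seed: int = 0,
                warm_start: BistabilityCertificate | None = None,
                scheme: str = "guided") -> BistabilityCertificate | None:
    """Search for a bistability certificate; ``None`` means *unknown*.

    Per draw, rate constants are sampled (seeded deterministically from
    ``rng_seed`` and the draw index) and all equilibria are located; the
    search stops at the first draw with two distinct strictly positive
    asymptotically stable equilibria.  A ``warm_start`` certificate from
    a sub-circuit is tried first, with any newly introduced rates set
    small.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if warm_start is not None:
        parent = circuit(warm_start.circuit, warm_start.n_genes)
        grown = grow_certificate(warm_start, circ,
                                 added=circ.labels - parent.labels)
        if grown is not None:
            return grown
    for draw in range(budget):
        seed = np.random.SeedSequence([rng_seed, draw]).generate_state(1)[0]
        rates = sample_rates(circ, int(seed), scheme=scheme)
        eqs = circuit_equilibria(circ, rates)
        cert = _certificate_from(circ, rates, eqs, rng_seed)
        if cert is not None:
            return cert
    return None


def grow_certificate(parent_cert: BistabilityCertificate,
                     child: GeneCircuit,
                     added: str | set[str] | None = None,
                     rate_scales: Sequence[float] = (1e-4, 1e-6, 1e-8)
                     ) -> BistabilityCertificate | None:
    """Continue a parent certificate onto a larger circuit.

    The parent's rates carry over; rates of newly added reactions are
    initialized at a small multiple of the median parent rate, so the
    perturbation to the parent's phase portrait is weak.  The
    persistence argument only holds for *sufficiently* small new rates
    — a parent equilibrium close to a fold tolerates less — so the
    scales in ``rate_scales`` are tried in order.  Equilibria are
    re-located and re-classified on the child; returns ``None`` if two
    stable equilibria are never recovered.
    """
    parent = circuit(parent_cert.circuit, parent_cert.n_genes)
    if added is None:
        added = child.labels - parent.labels
    elif isinstance(added, str):
        added = {added}
    if not (parent.labels | set(added)) == child.labels:
        raise ValueError("child must equal parent plus the added labels")
    if not added:
        return parent_cert
    median = float(np.median(list(parent_cert.rates.values())))
    for scale in rate_scales:
        rates = dict(parent_cert.rates)
        for rxn in circuit_to_crn(child).reactions:
            if rxn.rate_symbol not in rates:
                # keep unbinding at unit rate so new complexes stay sparse
                rates[rxn.rate_symbol] = (
                    1.0 if rxn.rate_symbol.endswith("_off")
                    else scale * median)
        eqs = circuit_equilibria(child, rates)
        cert = _certificate_from(child, rates, eqs, parent_cert.seed)
        if cert is not None:
            return cert
    return None


# ---------------------------------------------------------------------------
# certificate validation by forward integration


def validate_certificate(cert: BistabilityCertificate,
                         rel_perturbation: float = 0.01,
                         rng_seed: int = 0) -> bool:
    """Independently re-check a certificate by simulation.

    For each stable equilibrium, the state is perturbed within its
    stoichiometric compatibility class and the mass-action ODEs are
    integrated forward; the trajectory must return to the same
    equilibrium.  Any unstable equilibrium must show a reduced-Jacobian
    eigenvalue with positive real part.  Conserved totals must stay
    constant along the integrations.
    """
    circ = circuit(cert.circuit, cert.n_genes)
    net = circuit_to_crn(circ)
    rates = cert.rates
    f, jac = mass_action_system(net, rates)
    basis = _subspace_orth(net)
    laws = conservation_laws(net)
    cmat = laws.matrix()
    rng = np.random.default_rng(rng_seed)

    stable = cert.stable
    if len(stable) < 2:
        return False
    for eq in stable:
        if eq.stability is not Stability.STABLE or np.min(eq.state) <= 0:
            return False
        tau = 1.0 / max(abs(eq.leading_real), 1e-12)
        t_final = min(1e8, 200.0 * tau)
        for _ in range(2):
            dx = rel_perturbation * eq.state * rng.uniform(-1, 1, eq.state.size)
            dx = basis @ (basis.T @ dx)      # stay inside the class
            # shrink the step rather than clip: clipping would change the
            # conserved totals and hence the compatibility class
            neg = dx < 0
            alpha = 1.0
            if neg.any():
                alpha = min(1.0, 0.5 * float(np.min(eq.state[neg]
                                                    / -dx[neg])))
            x0 = eq.state + alpha * dx
            displacement = float(np.max(np.abs(alpha * dx)))
            sol = solve_ivp(lambda t, x: f(x), (0.0, t_final), x0,
                            method="LSODA", jac=lambda t, x: jac(x),
                            rtol=1e-9, atol=1e-12)
            if not sol.success:
                return False
            x_end = sol.y[:, -1]
            scale = max(1.0, float(np.max(np.abs(eq.state))))
            if np.max(np.abs(x_end - eq.state)) > max(0.05 * displacement,
                                                      1e-9 * scale):
                return False
            if cmat.shape[0]:
                drift = np.max(np.abs(cmat @ x_end - cmat @ x0))
                if drift > 1e-6 * scale:
                    return False
    for eq in cert.unstable:
        if eq.leading_real <= STABILITY_TOL:
            return False
    return True


# ---------------------------------------------------------------------------
# one-parameter bifurcation scan


@dataclass
class BifurcationBranch:
    parameter: str
    grid: tuple[float, ...]
    points: list[list[Equilibrium]]
    folds: list[tuple[float, float]]

    def stable_counts(self) -> list[int]:
        return [sum(e.stability is Stability.STABLE for e in eqs)
                for eqs in self.points]


def bifurcation_scan(circ: GeneCircuit | ReactionNetwork,
                     rates: Mapping[str, float], parameter: str,
                     grid: Sequence[float],
                     totals: Sequence[float] | None = None
                     ) -> BifurcationBranch:
    """Equilibria and their stability along a one-parameter sweep.

    Fold (saddle-node) points are bracketed wherever the number of
    equilibria changes by two between adjacent grid values.
    """
    if isinstance(circ, GeneCircuit):
        symbols = {r.rate_symbol for r in circuit_to_crn(circ).reactions}
    else:
        symbols = {r.rate_symbol for r in circ.reactions}
    if parameter not in symbols:
        raise KeyError(f"{parameter!r} is not a rate symbol of this network")
    points: list[list[Equilibrium]] = []
    for value in grid:
        r = dict(rates)
        r[parameter] = float(value)
        if isinstance(circ, GeneCircuit):
            points.append(circuit_equilibria(circ, r))
        else:
            if totals is None:
                raise ValueError("totals required for a bare ReactionNetwork")
            points.append(find_equilibria(circ, r, totals))
    folds = []
    for i in range(len(grid) - 1):
        if abs(len(points[i + 1]) - len(points[i])) == 2:
            folds.append((float(grid[i]), float(grid[i + 1])))
    return BifurcationBranch(parameter, tuple(float(v) for v in grid),
                             points, folds)
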