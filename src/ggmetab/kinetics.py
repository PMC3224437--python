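"""Steady-state simulation of small reaction systems under enzymatic variability.

A :class:`ReactionNetwork` couples a stoichiometry matrix with per-reaction
rate laws (mass action, reversible Michaelis-Menten, or Michaelis-Menten with
mixed inhibition).  Population-like variability is introduced by perturbing
every kinetic constant with multiplicative log-normal noise; for each draw the
system is brought to its steady state and the log-concentrations are collected
into a :class:`ConcentrationEnsemble`, the input expected by
:mod:`ggmetab.ggm`.

Purely zeroth/first-order mass-action systems have a closed-form steady state
(the flux-balance equations are linear in the concentrations); anything else
is integrated to equilibrium with a stiff ODE solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "MMParams",
    "Reaction",
    "ReactionNetwork",
    "ParameterDraw",
    "ConcentrationEnsemble",
    "MonostabilityReport",
    "KineticsError",
    "SolverError",
    "mass_action_rate",
    "reversible_mm_rate",
    "mixed_inhibition_rate",
    "reaction_rates",
    "sample_parameters",
    "linear_steady_state",
    "numerical_steady_state",
    "verify_monostability",
    "simulate_ensemble",
    "pathway_distances",
    "read_network",
    "write_network",
]

MASS_ACTION = "mass_action"
REVERSIBLE_MM = "reversible_mm"
MIXED_INHIBITION = "mixed_inhibition"


class KineticsError(ValueError):
    """Invalid network, parameters, or concentrations."""


class SolverError(RuntimeError):
    """Steady state could not be obtained (singular, unstable, or no convergence)."""


@dataclass(frozen=True)
class MMParams:
    """Constants of a reversible Michaelis-Menten reaction.

    ``vmax_fwd``/``vmax_bwd`` are the maximal forward/backward rates,
    ``km_s``/``km_p`` the Michaelis constants of substrate and product.  If
    ``inhibitor_id`` is set the rate law is extended to mixed inhibition with
    binding constants ``ki`` (free enzyme) and ``kii`` (enzyme-substrate
    complex); ``ki == kii`` gives the non-competitive special case.
    """

    vmax_fwd: float
    vmax_bwd: float
    km_s: float
    km_p: float
    inhibitor_id: str | None = None
    ki: float | None = None
    kii: float | None = None

    def __post_init__(self) -> None:
        for name in ("vmax_fwd", "vmax_bwd", "km_s", "km_p"):
            if getattr(self, name) <= 0:
                raise KineticsError(f"MM constant {name} must be strictly positive")
        if self.inhibitor_id is not None:
            if self.ki is None or self.kii is None:
                raise KineticsError(
                    "inhibited reaction requires both ki and kii constants"
                )
            if self.ki <= 0 or self.kii <= 0:
                raise KineticsError("inhibition constants must be strictly positive")

    def constants(self) -> dict[str, float]:
        out = {
            "vmax_fwd": self.vmax_fwd,
            "vmax_bwd": self.vmax_bwd,
            "km_s": self.km_s,
            "km_p": self.km_p,
        }
        if self.inhibitor_id is not None:
            out["ki"] = self.ki
            out["kii"] = self.kii
        return out


@dataclass(frozen=True)
class Reaction:
    """One reaction: educt/product stoichiometries plus a rate law."""

    name: str
    educts: Mapping[str, int]
    products: Mapping[str, int]
    law: str = MASS_ACTION
    k: float | None = None
    mm: MMParams | None = None

    def __post_init__(self) -> None:
        if self.law not in (MASS_ACTION, REVERSIBLE_MM, MIXED_INHIBITION):
            raise KineticsError(f"unknown rate law {self.law!r} in {self.name}")
        if not self.educts and not self.products:
            raise KineticsError(f"reaction {self.name} has empty stoichiometry")
        if any(s <= 0 for s in (*self.educts.values(), *self.products.values())):
            raise KineticsError(f"stoichiometric coefficients must be positive in {self.name}")
        if self.law == MASS_ACTION:
            if self.k is None or self.k <= 0:
                raise KineticsError(f"mass-action reaction {self.name} needs k > 0")
        else:
            if self.mm is None:
                raise KineticsError(f"enzymatic reaction {self.name} needs MM constants")
            if len(self.educts) != 1 or len(self.products) != 1:
                raise KineticsError(
                    f"MM reaction {self.name} must have one substrate and one product"
                )
            if self.law == MIXED_INHIBITION and self.mm.inhibitor_id is None:
                raise KineticsError(
                    f"mixed-inhibition reaction {self.name} needs an inhibitor_id"
                )


class ReactionNetwork:
    """Stoichiometry, rate laws and nominal constants of a reaction system.

    Parameters
    ----------
    metabolite_ids : sequence of str
        Names of the ``m`` metabolites (columns of ensembles, rows of ``S``).
    reactions : sequence of Reaction
        The ``r`` reactions.  Educts enter the stoichiometry matrix ``S`` with
        negative sign, products with positive sign; ``S_e`` keeps only the
        negative part of ``S``.
    """

    def __init__(self, metabolite_ids: Sequence[str], reactions: Sequence[Reaction]):
        self.metabolite_ids = list(metabolite_ids)
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise KineticsError("duplicate metabolite ids")
        self.reactions = list(reactions)
        if not self.reactions:
            raise KineticsError("network has no reactions")
        self._index = {mid: i for i, mid in enumerate(self.metabolite_ids)}

        m, r = len(self.metabolite_ids), len(self.reactions)
        S = np.zeros((m, r), dtype=int)
        for j, rx in enumerate(self.reactions):
            for mid, s in rx.educts.items():
                if mid not in self._index:
                    raise KineticsError(f"reaction {rx.name} references unknown {mid!r}")
                S[self._index[mid], j] -= s
            for mid, s in rx.products.items():
                if mid not in self._index:
                    raise KineticsError(f"reaction {rx.name} references unknown {mid!r}")
                S[self._index[mid], j] += s
            if rx.law == MIXED_INHIBITION and rx.mm.inhibitor_id not in self._index:
                raise KineticsError(
                    f"inhibitor {rx.mm.inhibitor_id!r} of {rx.name} is not declared"
                )
            if not S[:, j].any():
                raise KineticsError(f"reaction {rx.name} has a zero stoichiometry column")
        self.S = S
        # S_e holds the educt stoichiometries only (cannot be recovered from S
        # when a species is both educt and product of the same reaction).
        S_e = np.zeros((m, r), dtype=int)
        for j, rx in enumerate(self.reactions):
            for mid, s in rx.educts.items():
                S_e[self._index[mid], j] -= s
        self.S_e = S_e

    # -- basic properties ---------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def r(self) -> int:
        return len(self.reactions)

    def index(self, metabolite_id: str) -> int:
        return self._index[metabolite_id]

    def is_linear(self) -> bool:
        """True if every reaction is zeroth- or first-order mass action."""
        for rx in self.reactions:
            if rx.law != MASS_ACTION:
                return False
            if sum(rx.educts.values()) > 1:
                return False
        return True

    # -- parameter bookkeeping ---------------------------------------------
    def constant_names(self) -> list[str]:
        """Flat, ordered names of every kinetic constant (``reaction.constant``)."""
        names: list[str] = []
        for rx in self.reactions:
            if rx.law == MASS_ACTION:
                names.append(f"{rx.name}.k")
            else:
                names.extend(f"{rx.name}.{c}" for c in rx.mm.constants())
        return names

    def nominal_constants(self) -> np.ndarray:
        vals: list[float] = []
        for rx in self.reactions:
            if rx.law == MASS_ACTION:
                vals.append(rx.k)
            else:
                vals.extend(rx.mm.constants().values())
        return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled set of kinetic constants for a network."""

    names: tuple[str, ...]
    values: np.ndarray
    sigma: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) <= 0):
            raise KineticsError("sampled kinetic constants must be strictly positive")

    def value(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class ConcentrationEnsemble:
    """n x m matrix of natural-log steady-state concentrations.

    ``data`` columns are metabolite ids; ``classes`` optionally maps each id
    to a metabolite-class label used by the graph/modularity tools.
    """

    data: pd.DataFrame
    classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise KineticsError("ensemble contains missing values")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    def zero_variance_columns(self) -> list[str]:
        sd = self.data.std(ddof=1)
        return list(sd.index[sd.values == 0.0])


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def mass_action_rate(x: np.ndarray, k_j: float, network: ReactionNetwork, j: int) -> float:
    """Mass-action rate ``k_j * prod_i x_i**(-s^e_ij)`` of reaction ``j``.

    Zeroth-order (input) reactions have an empty educt set and return ``k_j``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise KineticsError("negative concentration in mass_action_rate")
    if k_j <= 0:
        raise KineticsError("rate constant must be positive")
    exponents = -network.S_e[:, j]
    return float(k_j * np.prod(x[: network.m] ** exponents))


def reversible_mm_rate(s_conc: float, p_conc: float, params: MMParams) -> float:
    """Reversible Michaelis-Menten rate.

    v = (Vmax+/KMs * S - Vmax-/KMp * P) / (1 + S/KMs + P/KMp).
    """
    if s_conc < 0 or p_conc < 0:
        raise KineticsError("negative concentration in reversible_mm_rate")
    num = params.vmax_fwd / params.km_s * s_conc - params.vmax_bwd / params.km_p * p_conc
    den = 1.0 + s_conc / params.km_s + p_conc / params.km_p
    return num / den


def mixed_inhibition_rate(
    s_conc: float, p_conc: float, i_conc: float, params: MMParams
) -> float:
    """Reversible MM rate under mixed inhibition.

    The denominator becomes ``1 + I/Ki + (S/KMs + P/KMp) * (1 + I/Kii)``;
    with ``Ki == Kii`` this is non-competitive inhibition and the rate at
    ``I == Ki`` is exactly half the uninhibited rate.
    """
    if params.ki is None or params.kii is None:
        raise KineticsError("mixed inhibition requires ki and kii")
    if s_conc < 0 or p_conc < 0 or i_conc < 0:
        raise KineticsError("negative concentration in mixed_inhibition_rate")
    num = params.vmax_fwd / params.km_s * s_conc - params.vmax_bwd / params.km_p * p_conc
    den = (
        1.0
        + i_conc / params.ki
        + (s_conc / params.km_s + p_conc / params.km_p) * (1.0 + i_conc / params.kii)
    )
    return num / den


def _draw_mm(rx: Reaction, draw: ParameterDraw) -> MMParams:
    consts = {c: draw.value(f"{rx.name}.{c}") for c in rx.mm.constants()}
    return replace(rx.mm, **consts)


def reaction_rates(network: ReactionNetwork, x: np.ndarray, draw: ParameterDraw) -> np.ndarray:
    """Rate vector v(x, k) for all reactions under a parameter draw."""
    v = np.empty(network.r)
    for j, rx in enumerate(network.reactions):
        if rx.law == MASS_ACTION:
            v[j] = mass_action_rate(x, draw.value(f"{rx.name}.k"), network, j)
        else:
            params = _draw_mm(rx, draw)
            (s_id,) = rx.educts
            (p_id,) = rx.products
            s_c = x[network.index(s_id)]
            p_c = x[network.index(p_id)]
            if rx.law == REVERSIBLE_MM:
                v[j] = reversible_mm_rate(s_c, p_c, params)
            else:
                i_c = x[network.index(params.inhibitor_id)]
                v[j] = mixed_inhibition_rate(s_c, p_c, i_c, params)
    return v


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def sample_parameters(
    network: ReactionNetwork,
    sigma: float | Mapping[str, float] = 0.2,
    seed: int | np.random.Generator | None = None,
    lognormal_mode: str = "median",
) -> ParameterDraw:
    """Draw one log-normally perturbed set of kinetic constants.

    Each constant is multiplied by ``exp(eps)`` with ``eps ~ N(mu, sigma^2)``
    drawn independently per constant.  ``lognormal_mode="median"`` (default)
    uses ``mu = 0`` so the nominal value is the median of the perturbed
    constant; ``"mean"`` uses ``mu = -sigma^2/2`` so the nominal value is its
    mean.  ``sigma`` may be a single value or a per-constant/per-reaction map
    (keys match ``constant_names()`` entries or reaction names).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = network.constant_names()
    nominal = network.nominal_constants()
    if isinstance(sigma, Mapping):
        sig = np.array(
            [sigma.get(n, sigma.get(n.split(".")[0], 0.0)) for n in names], dtype=float
        )
    else:
        sig = np.full(len(names), float(sigma))
    if np.any(sig < 0):
        raise KineticsError("sigma must be non-negative")
    if lognormal_mode == "median":
        mu = np.zeros_like(sig)
    elif lognormal_mode == "mean":
        mu = -sig**2 / 2.0
    else:
        raise KineticsError(f"unknown lognormal_mode {lognormal_mode!r}")
    eps = rng.normal(mu, sig)
    values = nominal * np.exp(eps)
    return ParameterDraw(
        names=tuple(names),
        values=values,
        sigma=float(np.max(sig)),
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def nominal_draw(network: ReactionNetwork) -> ParameterDraw:
    """The unperturbed parameter set (sigma = 0)."""
    return ParameterDraw(
        names=tuple(network.constant_names()),
        values=network.nominal_constants(),
        sigma=0.0,
    )


# ---------------------------------------------------------------------------
# steady-state solvers
# ---------------------------------------------------------------------------

def linear_steady_state(network: ReactionNetwork, draw: ParameterDraw) -> np.ndarray:
    """Closed-form steady state of a zeroth/first-order mass-action system.

    For such systems ``S v(x, k) = A x + b`` with constant ``A`` and ``b``;
    the steady state solves ``A x = -b``.  Raises :class:`SolverError` if the
    flux-balance system is singular or the solution is not strictly positive.
    """
    if not network.is_linear():
        raise KineticsError("linear_steady_state requires zeroth/first-order mass action")
    m = network.m
    A = np.zeros((m, m))
    b = np.zeros(m)
    for j, rx in enumerate(network.reactions):
        k = draw.value(f"{rx.name}.k")
        col = network.S[:, j].astype(float)
        if rx.educts:
            (educt,) = rx.educts
            A[:, network.index(educt)] += k * col
        else:
            b += k * col
    if np.linalg.matrix_rank(A) < m:
        raise SolverError("flux-balance system is singular: no unique steady state")
    x = np.linalg.solve(A, -b)
    if np.any(x <= 0):
        raise SolverError("steady state has non-positive concentrations")
    return x


def numerical_steady_state(
    network: ReactionNetwork,
    draw: ParameterDraw,
    x0: np.ndarray | None = None,
    tol: float = 1e-9,
    t_horizon: float = 100.0,
    max_doublings: int = 14,
    polish: bool = True,
) -> np.ndarray:
    """Integrate dx/dt = S v(x, k) to equilibrium with a stiff solver.

    Convergence is declared when ``||dx/dt|| < tol * (1 + ||x||)``; the
    integration horizon doubles until convergence or ``max_doublings`` is
    exhausted.  With ``polish=True`` the integrated endpoint is refined by a
    Newton-type root solve of the flux balance, which typically saturates the
    tolerance after a short transient integration.
    """
    x = np.ones(network.m) if x0 is None else np.asarray(x0, dtype=float).copy()
    if np.any(x <= 0):
        raise KineticsError("initial state must be strictly positive")

    S = network.S.astype(float)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return S @ reaction_rates(network, np.maximum(y, 0.0), draw)

    def converged(y: np.ndarray) -> bool:
        return float(np.linalg.norm(rhs(0.0, y))) < tol * (1.0 + float(np.linalg.norm(y)))

    horizon = t_horizon
    for _ in range(max_doublings + 1):
        sol = solve_ivp(rhs, (0.0, horizon), x, method="LSODA", rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise SolverError(f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        if np.any(x < -tol):
            raise SolverError("trajectory left the positive orthant")
        x = np.maximum(x, 1e-300)
        if polish:
            res = root(lambda y: S @ reaction_rates(network, np.maximum(y, 0.0), draw), x)
            if res.success and np.all(res.x > 0) and converged(res.x):
                return res.x
        if converged(x):
            return x
        horizon *= 2.0
    raise SolverError("no convergence to steady state within the configured horizon")


def steady_state(
    network: ReactionNetwork, draw: ParameterDraw, x0: np.ndarray | None = None, tol: float = 1e-9
) -> np.ndarray:
    """Dispatch to the analytic solver for linear systems, else integrate."""
    if network.is_linear():
        return linear_steady_state(network, draw)
    return numerical_steady_state(network, draw, x0=x0, tol=tol)


@dataclass
class MonostabilityReport:
    passed: bool
    worst_divergence: float
    n_param_draws: int
    n_init_draws: int
    failures: list[str] = field(default_factory=list)


def verify_monostability(
    network: ReactionNetwork,
    n_param_draws: int = 10,
    n_init_draws: int = 5,
    seed: int | None = None,
    sigma: float = 0.2,
    tol: float = 1e-6,
) -> MonostabilityReport:
    """Empirically check that sampled parameters give a unique steady state.

    For each parameter draw the steady state is computed from several random
    strictly positive initial states (log-uniform over two decades); the draw
    passes if all agree within ``tol`` relative divergence.  Solver failures
    are recorded, not raised.
    """
    if n_param_draws < 1 or n_init_draws < 1:
        raise KineticsError("draw counts must be >= 1")
    rng = np.random.default_rng(seed)
    worst = 0.0
    failures: list[str] = []
    for p in range(n_param_draws):
        draw = sample_parameters(network, sigma=sigma, seed=rng)
        states = []
        for i in range(n_init_draws):
            x0 = 10.0 ** rng.uniform(-1, 1, size=network.m)
            try:
                if network.is_linear():
                    states.append(linear_steady_state(network, draw))
                else:
                    states.append(numerical_steady_state(network, draw, x0=x0))
            except SolverError as exc:
                failures.append(f"draw {p}, init {i}: {exc}")
        if len(states) >= 2:
            ref = states[0]
            for s in states[1:]:
                div = float(np.max(np.abs(s - ref) / (1.0 + np.abs(ref))))
                worst = max(worst, div)
    passed = not failures and worst <= tol
    return MonostabilityReport(
        passed=passed,
        worst_divergence=worst,
        n_param_draws=n_param_draws,
        n_init_draws=n_init_draws,
        failures=failures,
    )


def simulate_ensemble(
    network: ReactionNetwork,
    sigma: float | Mapping[str, float] = 0.2,
    n_samples: int = 1000,
    seed: int | None = None,
    lognormal_mode: str = "median",
    tol: float = 1e-9,
    classes: dict[str, str] | None = None,
) -> ConcentrationEnsemble:
    """Simulate ``n_samples`` steady states under parameter variability.

    Each sample is an independent log-normal parameter draw; the resulting
    steady-state concentrations are natural-logarithmized.  Linear networks
    use the analytic solver, others the stiff integrator (warm-started at the
    previous steady state, since nearby parameter draws have nearby fixed
    points).  Solver errors propagate with the draw index attached.
    """
    if n_samples < 2:
        raise KineticsError("need at least two samples")
    rng = np.random.default_rng(seed)
    linear = network.is_linear()
    X = np.empty((n_samples, network.m))
    x_prev: np.ndarray | None = None
    for i in range(n_samples):
        draw = sample_parameters(network, sigma=sigma, seed=rng, lognormal_mode=lognormal_mode)
        try:
            if linear:
                x = linear_steady_state(network, draw)
            else:
                # continuation fast path: Newton from the previous steady
                # state (nearby draws have nearby fixed points), verified
                # against the same residual tolerance; integrate on failure
                x = None
                if x_prev is not None:
                    S = network.S.astype(float)
                    res = root(lambda y: S @ reaction_rates(network, np.maximum(y, 0.0), draw), x_prev)
                    if res.success and np.all(res.x > 0):
                        resid = float(np.linalg.norm(S @ reaction_rates(network, res.x, draw)))
                        if resid < tol * (1.0 + float(np.linalg.norm(res.x))):
                            x = res.x
                if x is None:
                    x = numerical_steady_state(network, draw, x0=x_prev, tol=tol)
                x_prev = x
        except SolverError as exc:
            raise SolverError(f"draw {i}: {exc}") from exc
        X[i] = np.log(x)
    ens = ConcentrationEnsemble(
        data=pd.DataFrame(X, columns=network.metabolite_ids), classes=classes
    )
    return ens


def pathway_distances(network: ReactionNetwork, exchange_free: bool = True) -> pd.DataFrame:
    """Reaction-step distances between metabolites of a network.

    Builds an undirected graph with an edge between every educt-product pair
    of each internal reaction (exchange reactions, i.e. reactions with an
    empty educt or product set, contribute no edges) and returns all-pairs
    shortest path lengths; unreachable pairs get ``inf``.  This is the ground
    truth used when evaluating reconstructed networks against the generating
    topology.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.metabolite_ids)
    for rx in network.reactions:
        if not rx.educts or not rx.products:
            continue
        for e in rx.educts:
            for p in rx.products:
                if e != p:
                    g.add_edge(e, p)
    ids = network.metabolite_ids
    D = pd.DataFrame(np.inf, index=ids, columns=ids)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            D.loc[src, dst] = float(d)
    np.fill_diagonal(D.values, 0.0)
    return D


# ---------------------------------------------------------------------------
# network file I/O (YAML)
# ---------------------------------------------------------------------------

def _reaction_to_dict(rx: Reaction) -> dict:
    d: dict = {
        "name": rx.name,
        "educts": dict(rx.educts),
        "products": dict(rx.products),
        "law": rx.law,
    }
    if rx.law == MASS_ACTION:
        d["k"] = rx.k
    else:
        d["params"] = {k: v for k, v in rx.mm.constants().items()}
        if rx.mm.inhibitor_id is not None:
            d["params"]["inhibitor_id"] = rx.mm.inhibitor_id
    return d


def write_network(network: ReactionNetwork, path) -> None:
    doc = {
        "metabolites": network.metabolite_ids,
        "reactions": [_reaction_to_dict(rx) for rx in network.reactions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_network(path) -> ReactionNetwork:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    reactions = []
    for rd in doc["reactions"]:
        law = rd.get("law", MASS_ACTION)
        mm = None
        if law != MASS_ACTION:
            params = dict(rd["params"])
            mm = MMParams(**params)
        reactions.append(
            Reaction(
                name=rd["name"],
                educts=rd.get("educts", {}) or {},
                products=rd.get("products", {}) or {},
                law=law,
                k=rd.get("k"),
                mm=mm,
            )
        )
    return ReactionNetwork(doc["metabolites"], reactions)
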