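"""Constraint-based propagation of root perturbations through logic networks.

Each node carries a continuous activity in [0.01, 100] with 1.0 meaning
normal.  A node with AND fan-in takes the product of its (edge-transformed)
input activities; inhibitory edges contribute the reciprocal of the input;
OR fan-in takes the arithmetic average of the edge-transformed inputs.
Every node has a pair of values: the input-side value x-bar actually fed
into downstream equations, and the output-side value x its own equation
produces.  Fixing perturbed roots and minimizing the total per-node
disagreement |x-bar - x| yields a solution even when the equation system is
inconsistent (feedback loops, conflicting inputs, saturation at the bounds).

Internally everything is solved in log10 space, where products and
reciprocals are linear.  With ``or_mode='geometric_log'`` the OR average is
taken in log space too and the whole problem is a linear program; the
default ``'arithmetic_raw'`` averages raw activities, which adds one smooth
nonlinear equation per multi-input OR node.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, minimize

from .logic_network import (
    Direction,
    Logic,
    LogicNetwork,
    NodeRole,
    TestCase,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["SolverConfig", "Perturbation", "SolverStatus", "SolverSolution",
           "Model", "ModelError", "build_model", "solve", "predict_outputs",
           "perturbation_for_case"]


class ModelError(ValueError):
    """Raised when a model cannot be assembled from its inputs."""


class OrMode(str, enum.Enum):
    ARITHMETIC_RAW = "arithmetic_raw"
    GEOMETRIC_LOG = "geometric_log"


class Objective(str, enum.Enum):
    L1 = "L1"
    L2 = "L2"


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    FEASIBLE = "feasible"
    FAILED = "failed"


@dataclass(frozen=True)
class SolverConfig:
    lower_bound: float = 0.01
    upper_bound: float = 100.0
    baseline: float = 1.0
    up_value: float = 100.0
    down_value: float = 0.01
    or_mode: OrMode = OrMode.ARITHMETIC_RAW
    objective: Objective = Objective.L1
    tol: float = 1e-9
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.lower_bound < self.baseline < self.upper_bound):
            raise ValidationError(
                "bounds must satisfy 0 < lower < baseline < upper")
        for v in (self.up_value, self.down_value):
            if not (self.lower_bound <= v <= self.upper_bound):
                raise ValidationError(
                    f"perturbation value {v} outside bounds")
        object.__setattr__(self, "or_mode",
                           OrMode(str(self.or_mode.value
                                      if isinstance(self.or_mode, OrMode)
                                      else self.or_mode).lower()))
        object.__setattr__(self, "objective",
                           Objective(str(self.objective.value
                                         if isinstance(self.objective, Objective)
                                         else self.objective).upper()))


@dataclass(frozen=True)
class Perturbation:
    node: str
    value: float


@dataclass
class SolverSolution:
    """Per-node paired activities (raw scale) plus the minimized objective
    (total log10-space disagreement) and a status flag."""

    x_in: dict[str, float]   # x-bar, the value fed into downstream equations
    x_out: dict[str, float]  # x, the value each node's own equation produces
    objective: float
    status: SolverStatus
    message: str = ""


@dataclass
class Model:
    net: LogicNetwork
    cfg: SolverConfig
    node_order: list[str]
    fixed_log: dict[str, float]          # node -> fixed log10 activity
    equations: dict[str, tuple[Logic, list[tuple[str, int]]]]
    # equations: target -> (logic, [(source, sign)]), sign +1/-1

    @property
    def log_lb(self) -> float:
        return math.log10(self.cfg.lower_bound)

    @property
    def log_ub(self) -> float:
        return math.log10(self.cfg.upper_bound)

    def nonlinear_or_nodes(self) -> list[str]:
        if self.cfg.or_mode is OrMode.GEOMETRIC_LOG:
            return []
        return [n for n, (logic, terms) in self.equations.items()
                if logic is Logic.OR and len(terms) >= 2]


def build_model(net: LogicNetwork,
                perturbations: list[Perturbation],
                cfg: SolverConfig = SolverConfig(),
                roles: list[NodeRole] | None = None,
                allow_non_root: bool = False) -> Model:
    """Assemble the optimization problem.

    Nodes with in-degree 0 are roots: perturbed ones are fixed at their
    assigned value, the rest at the baseline.  Every other node gets one
    equation combining its inputs per its fan-in logic.  Mixed AND/OR
    fan-ins are normalized away first.
    """
    if not net.is_normalized():
        logger.info("normalizing mixed fan-in before model build")
        net = net.normalized()
    net.validate()

    in_deg: dict[str, int] = {n: 0 for n in net.nodes}
    for e in net.edges:
        in_deg[e.target] += 1
    root_set = {n for n, d in in_deg.items() if d == 0}
    if roles is not None:
        declared = {r.node_id for r in roles if r.is_root_input}
        dangling = sorted(root_set - declared)
        if dangling:
            raise ModelError(
                "nodes with no incoming edges are not declared root inputs: "
                + ", ".join(dangling))

    fixed_log: dict[str, float] = {
        n: math.log10(cfg.baseline) for n in root_set}
    for p in perturbations:
        if p.node not in net.nodes:
            raise ModelError(f"perturbed node {p.node!r} not in network")
        if p.node not in root_set and not allow_non_root:
            raise ModelError(
                f"perturbed node {p.node!r} is not a root input "
                "(pass allow_non_root=True to override)")
        if not (cfg.lower_bound <= p.value <= cfg.upper_bound):
            raise ValidationError(
                f"perturbation value {p.value} outside bounds")
        fixed_log[p.node] = math.log10(p.value)

    equations: dict[str, tuple[Logic, list[tuple[str, int]]]] = {}
    by_target: dict[str, list[tuple[str, int, Logic]]] = {}
    for e in net.edges:
        by_target.setdefault(e.target, []).append(
            (e.source, -1 if e.is_negative else 1, e.logic))
    for target, terms in by_target.items():
        logics = {t[2] for t in terms}
        assert len(logics) == 1  # guaranteed by normalization
        equations[target] = (logics.pop(),
                             sorted((s, sign) for s, sign, _ in terms))

    node_order = sorted(net.nodes)
    return Model(net=net, cfg=cfg, node_order=node_order,
                 fixed_log=fixed_log, equations=equations)


def _eq_value_log(model: Model, node: str, xbar: dict[str, float]) -> float:
    """Log10 output of *node*'s equation given log10 input-side values."""
    logic, terms = model.equations[node]
    contribs = [sign * xbar[src] for src, sign in terms]
    if logic is Logic.AND:
        return float(sum(contribs))
    if len(contribs) == 1:
        return float(contribs[0])
    if model.cfg.or_mode is OrMode.GEOMETRIC_LOG:
        return float(np.mean(contribs))
    return float(np.log10(np.mean([10.0 ** c for c in contribs])))


def solve(model: Model) -> SolverSolution:
    """Minimize total per-node disagreement subject to the logic equations.

    Linear instances (no multi-input OR under arithmetic averaging, L1
    objective) go through an LP with split slack variables; nonlinear ones
    are warm-started from the corresponding LP and polished with SLSQP.
    Fully deterministic: initialization is fixed and no randomness is used.
    """
    cfg = model.cfg
    L, U = model.log_lb, model.log_ub
    order = model.node_order
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    eq_nodes = [m for m in order if m in model.equations]
    eq_idx = {m: j for j, m in enumerate(eq_nodes)}
    m = len(eq_nodes)

    nonlin = set(model.nonlinear_or_nodes())
    use_lp = not nonlin and cfg.objective is Objective.L1

    def finish(xbar_vec: np.ndarray, status: SolverStatus,
               message: str = "") -> SolverSolution:
        xbar = {node: float(xbar_vec[idx[node]]) for node in order}
        x_out_log = {}
        for node in order:
            if node in model.equations:
                x_out_log[node] = min(max(_eq_value_log(model, node, xbar),
                                          L), U)
            else:
                x_out_log[node] = xbar[node]
        if cfg.objective is Objective.L1:
            obj = sum(abs(xbar[v] - _eq_value_log(model, v, xbar))
                      for v in eq_nodes)
        else:
            obj = sum((xbar[v] - _eq_value_log(model, v, xbar)) ** 2
                      for v in eq_nodes)
        return SolverSolution(
            x_in={v: 10.0 ** xbar[v] for v in order},
            x_out={v: 10.0 ** x_out_log[v] for v in order},
            objective=float(obj), status=status, message=message)

    # variable bounds for x-bar (fixed nodes pinned)
    xbar_bounds = []
    for node in order:
        if node in model.fixed_log:
            v = model.fixed_log[node]
            xbar_bounds.append((v, v))
        else:
            xbar_bounds.append((L, U))

    # linear coefficients of each equation where applicable:
    # f_v = sum_e c_e * xbar_src
    def linear_coeffs(node: str) -> list[tuple[int, float]]:
        logic, terms = model.equations[node]
        k = len(terms)
        div = k if (logic is Logic.OR and k > 1) else 1
        out: dict[int, float] = {}
        for src, sign in terms:
            out[idx[src]] = out.get(idx[src], 0.0) + sign / div
        return list(out.items())

    if use_lp:
        # variables: [xbar (n), t (m)]; minimize sum t
        # t_v >= xbar_v - f_v  and  t_v >= f_v - xbar_v
        c = np.concatenate([np.zeros(n), np.ones(m)])
        rows, cols, vals, b_ub = [], [], [], []
        r = 0
        for v in eq_nodes:
            coeffs = linear_coeffs(v)
            for sgn in (+1.0, -1.0):
                rows.append(r); cols.append(idx[v]); vals.append(sgn)
                for j, cj in coeffs:
                    rows.append(r); cols.append(j); vals.append(-sgn * cj)
                rows.append(r); cols.append(n + eq_idx[v]); vals.append(-1.0)
                b_ub.append(0.0)
                r += 1
        from scipy.sparse import coo_matrix
        a_ub = coo_matrix((vals, (rows, cols)), shape=(r, n + m))
        bounds = xbar_bounds + [(0.0, None)] * m
        res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not res.success:
            return SolverSolution({}, {}, math.inf, SolverStatus.FAILED,
                                  message=res.message)
        return finish(res.x[:n], SolverStatus.OPTIMAL, res.message)

    # nonlinear route: warm start from the geometric-log LP
    lp_model = Model(net=model.net,
                     cfg=SolverConfig(
                         lower_bound=cfg.lower_bound,
                         upper_bound=cfg.upper_bound,
                         baseline=cfg.baseline,
                         up_value=cfg.up_value,
                         down_value=cfg.down_value,
                         or_mode=OrMode.GEOMETRIC_LOG,
                         objective=Objective.L1,
                         tol=cfg.tol, max_iter=cfg.max_iter),
                     node_order=model.node_order,
                     fixed_log=model.fixed_log,
                     equations=model.equations)
    warm = solve(lp_model)
    if warm.status is SolverStatus.FAILED:
        x0_bar = np.array([model.fixed_log.get(v, 0.0) for v in order])
    else:
        x0_bar = np.array([math.log10(warm.x_in[v]) for v in order])

    def fvals(xbar_vec: np.ndarray) -> np.ndarray:
        xbar = {node: float(xbar_vec[idx[node]]) for node in order}
        return np.array([_eq_value_log(model, v, xbar) for v in eq_nodes])

    if cfg.objective is Objective.L1:
        # variables [xbar, t]; min sum t s.t. t_v >= |xbar_v - f_v|
        def objective(z: np.ndarray) -> float:
            return float(np.sum(z[n:]))

        def obj_grad(z: np.ndarray) -> np.ndarray:
            g = np.zeros(n + m)
            g[n:] = 1.0
            return g

        def cons_fun(z: np.ndarray) -> np.ndarray:
            resid = z[:n][[idx[v] for v in eq_nodes]] - fvals(z[:n])
            t = z[n:]
            return np.concatenate([t - resid, t + resid])

        t0 = np.abs(x0_bar[[idx[v] for v in eq_nodes]] - fvals(x0_bar))
        z0 = np.concatenate([x0_bar, t0 + 1e-9])
        bounds = xbar_bounds + [(0.0, None)] * m
        res = minimize(objective, z0, jac=obj_grad, method="SLSQP",
                       bounds=bounds,
                       constraints=[{"type": "ineq", "fun": cons_fun}],
                       options={"maxiter": cfg.max_iter, "ftol": max(cfg.tol, 1e-12)})
        if not res.success and warm.status is not SolverStatus.FAILED:
            # keep the LP warm start as a feasible fallback
            return finish(x0_bar, SolverStatus.FEASIBLE,
                          message=f"SLSQP: {res.message}; using LP warm start")
        if not res.success:
            return SolverSolution({}, {}, math.inf, SolverStatus.FAILED,
                                  message=str(res.message))
        sol = finish(res.x[:n], SolverStatus.OPTIMAL, str(res.message))
        if (warm.status is not SolverStatus.FAILED
                and warm.objective < sol.objective - 1e-9):
            # the nonlinear polish never has to be worse than the warm start
            return finish(x0_bar, SolverStatus.FEASIBLE,
                          message="LP warm start beat SLSQP polish")
        return sol

    # L2: smooth unconstrained-in-t formulation
    def objective2(z: np.ndarray) -> float:
        resid = z[[idx[v] for v in eq_nodes]] - fvals(z)
        return float(np.dot(resid, resid))

    res = minimize(objective2, x0_bar, method="SLSQP", bounds=xbar_bounds,
                   options={"maxiter": cfg.max_iter, "ftol": max(cfg.tol, 1e-12)})
    if not res.success:
        return SolverSolution({}, {}, math.inf, SolverStatus.FAILED,
                              message=str(res.message))
    return finish(res.x, SolverStatus.OPTIMAL, str(res.message))


def perturbation_for_case(case: TestCase,
                          cfg: SolverConfig = SolverConfig()) -> Perturbation:
    value = cfg.up_value if case.direction is Direction.UP else cfg.down_value
    return Perturbation(node=case.root_input, value=value)


def predict_outputs(net: LogicNetwork,
                    roles: list[NodeRole] | None,
                    case: TestCase,
                    cfg: SolverConfig = SolverConfig()) -> float:
    """Continuous activity of the key output under the single-root
    perturbation implied by the case direction (raw scale, 1.0 = unchanged)."""
    if case.key_output not in net.nodes:
        raise ValidationError(f"key output {case.key_output!r} not in network")
    model = build_model(net, [perturbation_for_case(case, cfg)], cfg,
                        roles=roles)
    sol = solve(model)
    if sol.status is SolverStatus.FAILED:
        raise RuntimeError(f"solver failed: {sol.message}")
    key = case.key_output
    if key not in sol.x_out:
        raise RuntimeError(f"no solution value for {key!r}")
    return sol.x_out[key]
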