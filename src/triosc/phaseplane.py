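"""Phase-plane analysis in the (AMPK, ULK1) plane.

The five-variable model is reduced to two dimensions by quasi-steady-state
(QSS) elimination: for a given (AMPK, ULK1) pair, mTORC1 and PROT are
solved at their inner steady state (each is a monotone scalar balance, so
the inner solution is unique), and AUTOPHAGY is a pure output that feeds
nothing back.  The reduction is exact at equilibria, so reduced and full
fixed points coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .model import ModelDefinition, rhs

__all__ = [
    "ReducedModel",
    "Nullcline",
    "PhasePortrait",
    "ReductionError",
    "qss_reduce",
    "compute_nullcline",
    "portrait",
]

FREE = ("AMPK", "ULK1")
ELIMINATED = ("mTORC1", "PROT", "AUTOPHAGY")
INNER_TOL = 1e-13
RESIDUAL_TOL = 1e-10


class ReductionError(RuntimeError):
    pass


def _gk_root(act, inact, j_act, j_inact, total):
    """Root in [0, total] of act*(T-v)/(Ja+T-v) - inact*v/(Ji+v).

    Vectorized over numpy arrays.  Clearing denominators gives
    a*v^2 + b*v + c = 0 with a = inact - act,
    b = act*(T - Ji) - inact*(Ja + T), c = act*Ji*T; the equation has
    exactly one root in [0, T] whenever act, inact >= 0 are not both 0.
    """
    act = np.asarray(act, dtype=float)
    inact = np.asarray(inact, dtype=float)
    a = inact - act
    b = act * (total - j_inact) - inact * (j_act + total)
    c = act * j_inact * total
    disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
    sign_b = np.where(b >= 0.0, 1.0, -1.0)
    q = -0.5 * (b + sign_b * disc)     # stable: no cancellation
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(a != 0.0, q / np.where(a != 0.0, a, 1.0), np.inf)
        r2 = np.where(q != 0.0, c / np.where(q != 0.0, q, 1.0), 0.0)
    eps = 1e-12 * max(total, 1.0)
    in2 = (r2 >= -eps) & (r2 <= total + eps)
    root = np.where(in2, r2, r1)
    root = np.where(act == 0.0, 0.0, root)
    root = np.where((inact == 0.0) & (act > 0.0), total, root)
    return np.clip(root, 0.0, total)


@dataclass
class ReducedModel:
    """The (AMPK, ULK1) reduction of a full model."""

    model: ModelDefinition
    parent_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.parent_fingerprint = self.model.fingerprint()
        self._idx = {name: self.model.index(name) for name in
                     FREE + ELIMINATED}

    # -- inner steady-state solves ----------------------------------------

    def _solve_one(self, species: str, state: np.ndarray) -> float:
        """Steady activity of one eliminated species, others held fixed.

        No species regulates itself, so its activation/inactivation rate
        sums do not depend on its own activity and the balance

            a * (T - v)/(J_act + T - v) = i * v/(J_inact + v)

        is a quadratic in v with exactly one root in [0, T] (the familiar
        Goldbeter-Koshland switch).  Solved in closed form.
        """
        i = self._idx[species]
        total = self.model.totals[i]
        state[i] = 0.0
        act, inact = self.model.rates(state)
        *_, j_act, j_inact, _ = self.model._compiled()
        return float(_gk_root(act[i], inact[i], j_act[i], j_inact[i], total))

    def inner_state(self, ampk: float, ulk1: float) -> np.ndarray:
        """Full state with eliminated species at their inner steady state."""
        x = np.zeros(len(self.model.species))
        x[self._idx["AMPK"]] = ampk
        x[self._idx["ULK1"]] = ulk1
        # mTORC1 and PROT may in principle be coupled through custom
        # wiring, so iterate the scalar solves to a joint fixed point.
        for _ in range(50):
            m_old = x[self._idx["mTORC1"]]
            p_old = x[self._idx["PROT"]]
            x[self._idx["mTORC1"]] = self._solve_one("mTORC1", x)
            x[self._idx["PROT"]] = self._solve_one("PROT", x)
            if (abs(x[self._idx["mTORC1"]] - m_old) < INNER_TOL
                    and abs(x[self._idx["PROT"]] - p_old) < INNER_TOL):
                break
        x[self._idx["AUTOPHAGY"]] = self._solve_one("AUTOPHAGY", x)
        resid = rhs(self.model, x, check=False)
        inner = [self._idx[s] for s in ELIMINATED]
        if np.max(np.abs(resid[inner])) > RESIDUAL_TOL:
            raise ReductionError(
                f"inner solve residual {np.max(np.abs(resid[inner])):.2e} "
                f"at (AMPK={ampk:.4f}, ULK1={ulk1:.4f})")
        return x

    def rhs(self, ampk: float, ulk1: float) -> np.ndarray:
        """Reduced derivatives (dAMPK/dt, dULK1/dt) at the inner QSS."""
        ampk = float(np.clip(ampk, 0.0, self.model.totals[self._idx["AMPK"]]))
        ulk1 = float(np.clip(ulk1, 0.0, self.model.totals[self._idx["ULK1"]]))
        x = self.inner_state(ampk, ulk1)
        d = rhs(self.model, x, check=False)
        return np.array([d[self._idx["AMPK"]], d[self._idx["ULK1"]]])

    def rhs_grid(self, ampk: np.ndarray, ulk1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized reduced derivatives over arrays of (AMPK, ULK1).

        Uses the closed-form inner solve per eliminated species, iterated
        a few times in case eliminated species regulate each other (they
        do not in the shipped wiring, so one pass already converges).
        """
        model = self.model
        A = np.asarray(ampk, dtype=float)
        U = np.asarray(ulk1, dtype=float)
        act_terms, inact_terms, base_act, base_inact, j_act, j_inact, totals = \
            model._compiled()
        vals = [np.zeros_like(A) for _ in model.species]
        vals[self._idx["AMPK"]] = A
        vals[self._idx["ULK1"]] = U

        def rates(i):
            act = np.full_like(A, base_act[i])
            inact = np.full_like(A, base_inact[i])
            for w, srcs in act_terms[i]:
                prod = np.full_like(A, w)
                for s in srcs:
                    prod = prod * vals[s]
                act += prod
            for w, srcs in inact_terms[i]:
                prod = np.full_like(A, w)
                for s in srcs:
                    prod = prod * vals[s]
                inact += prod
            return act, inact

        for _ in range(3):
            for name in ("mTORC1", "PROT"):
                i = self._idx[name]
                act, inact = rates(i)
                vals[i] = _gk_root(act, inact, j_act[i], j_inact[i], totals[i])
        out = []
        for name in FREE:
            i = self._idx[name]
            act, inact = rates(i)
            x = vals[i]
            head = totals[i] - x
            out.append(act * head / (j_act[i] + head) - inact * x / (j_inact[i] + x))
        return out[0], out[1]

    def jacobian2(self, ampk: float, ulk1: float, eps: float = 1e-6) -> np.ndarray:
        J = np.empty((2, 2))
        for j, (a, u) in enumerate([(eps, 0.0), (0.0, eps)]):
            fp = self.rhs(ampk + a, ulk1 + u)
            fm = self.rhs(ampk - a, ulk1 - u)
            J[:, j] = (fp - fm) / (2 * eps)
        return J


@dataclass
class Nullcline:
    """Zero set of one reduced derivative, as (AMPK, ULK1) points."""

    variable: str                  # "AMPK" or "ULK1"
    points: np.ndarray             # shape (n, 2), columns (AMPK, ULK1)


@dataclass
class PhasePortrait:
    nullclines: dict[str, Nullcline]
    fixed_points: list            # (point2, eigenvalues2, stable)
    trajectories: list[np.ndarray] = field(default_factory=list)


def qss_reduce(model: ModelDefinition, check_grid: int = 9) -> ReducedModel:
    """Build the reduction; verify the inner solve on a coarse grid."""
    red = ReducedModel(model)
    bad = []
    for a in np.linspace(0.0, 1.0, check_grid):
        for u in np.linspace(0.0, 1.0, check_grid):
            try:
                red.inner_state(float(a), float(u))
            except ReductionError:
                bad.append((float(a), float(u)))
    if bad:
        raise ReductionError(f"inner solve failed on grid cells {bad[:5]}...")
    return red


def compute_nullcline(reduced: ReducedModel, variable: str,
                      grid_n: int = 201, tol: float = 1e-12) -> Nullcline:
    """Trace one nullcline by grid scan + bisection.

    For each grid line of the *other* variable, every sign change of the
    reduced derivative of ``variable`` along its own axis is bracketed and
    bisected to ``tol``.
    """
    if grid_n < 16:
        raise ValueError("grid_n must be >= 16")
    if variable not in FREE:
        raise ValueError(f"variable must be one of {FREE}")
    k = FREE.index(variable)       # derivative component to zero
    scan = 1 - k                   # index of the variable being scanned over
    grid = np.linspace(0.0, 1.0, grid_n)
    own, other = np.meshgrid(grid, grid, indexing="ij")   # rows: own axis
    pair = (own, other) if k == 0 else (other, own)
    field = reduced.rhs_grid(pair[0], pair[1])[k]         # (own, other)
    sign = np.sign(field)
    points = []
    for jcol, other_val in enumerate(grid):
        col = field[:, jcol]

        def deriv(v: float) -> float:
            p = [0.0, 0.0]
            p[k] = v
            p[scan] = other_val
            return reduced.rhs(p[0], p[1])[k]

        for i in range(len(grid) - 1):
            if sign[i, jcol] == 0:
                pt = [0.0, 0.0]; pt[k] = grid[i]; pt[scan] = other_val
                points.append((pt[0], pt[1]))
            elif sign[i, jcol] * sign[i + 1, jcol] < 0:
                v = brentq(deriv, grid[i], grid[i + 1], xtol=tol)
                pt = [0.0, 0.0]; pt[k] = v; pt[scan] = other_val
                points.append((pt[0], pt[1]))
        if sign[-1, jcol] == 0:
            pt = [0.0, 0.0]; pt[k] = grid[-1]; pt[scan] = other_val
            points.append((pt[0], pt[1]))
    if not points:
        warnings.warn(f"no {variable} nullcline points found", stacklevel=2)
        return Nullcline(variable, np.empty((0, 2)))
    pts = np.array(points)
    order = np.lexsort((pts[:, k], pts[:, scan]))
    return Nullcline(variable, pts[order])


def _reduced_fixed_points(reduced: ReducedModel, n_starts: int = 48,
                          seed: int = 0, merge_tol: float = 1e-6):
    rng = np.random.default_rng(seed)
    fun = lambda x: reduced.rhs(x[0], x[1])
    points = []
    for x0 in rng.uniform(0.01, 0.99, (n_starts, 2)):
        sol = root(fun, x0, method="hybr", tol=1e-13)
        x = sol.x
        if np.max(np.abs(fun(x))) >= 1e-10:
            continue
        if np.any(x < -merge_tol) or np.any(x > 1 + merge_tol):
            continue
        if any(np.max(np.abs(x - q)) < merge_tol for q in points):
            continue
        points.append(np.clip(x, 0.0, 1.0))
    out = []
    for x in points:
        ev = np.linalg.eigvals(reduced.jacobian2(x[0], x[1]))
        out.append((x, ev, bool(np.all(ev.real < 0))))
    out.sort(key=lambda t: tuple(t[0]))
    return out


def portrait(model: ModelDefinition, trajectory_starts=None,
             t_end: float = 300.0, grid_n: int = 201,
             seed: int = 0) -> PhasePortrait:
    """Nullclines, reduced fixed points with 2D stability, trajectories.

    Trajectories integrate the reduced two-variable system, matching what
    a two-dimensional phase plane can faithfully display.
    """
    reduced = qss_reduce(model)
    ncls = {v: compute_nullcline(reduced, v, grid_n=grid_n) for v in FREE}
    fps = _reduced_fixed_points(reduced, seed=seed)
    trajectories = []
    if trajectory_starts is None:
        trajectory_starts = [fp[0] + 1e-3 for fp in fps if not fp[2]]
    fun = lambda t, x: reduced.rhs(x[0], x[1])
    for x0 in trajectory_starts:
        sol = solve_ivp(fun, (0.0, t_end), np.asarray(x0, dtype=float),
                        method="LSODA", rtol=1e-9, atol=1e-11,
                        t_eval=np.linspace(0.0, t_end, max(int(t_end * 10), 2)))
        trajectories.append(sol.y.T)
    return PhasePortrait(ncls, fps, trajectories)
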