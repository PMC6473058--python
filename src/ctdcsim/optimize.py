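"""Constrained least-squares montage design ("current steering").

Given a lead field LF and a desired region-field pattern b, choose electrode
currents x minimizing the weighted Euclidean deviation

    arg min_x || W (LF x - b) ||^2
    s.t.      sum(x) = 0                      (anodal equals cathodal current)
              sum |x| <= cap                  (safety/comfort budget, 4 mA
                                               default, i.e. at most 2 mA
                                               total anodal current)
              |x_n| <= per-electrode cap      (optional)

This is a convex quadratic program.  It is solved in two stages: the
equality-constrained least squares (zero-sum handled by an orthonormal
nullspace basis) is solved exactly first; if that solution already respects
the current budget it is optimal.  Otherwise the L1 ball is handled by the
exact variable split x = p - q, p, q >= 0, sum(p + q) <= cap, and the
resulting smooth QP is solved with SLSQP.  The returned currents are then
projected exactly onto {sum x = 0} (mean subtraction) and, if needed, scaled
into the L1 ball, so the reported solution satisfies both constraints to
machine precision regardless of solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .leadfield import DIRECTIONS, CurrentVector, LeadField

__all__ = ["TargetSpec", "MontageSolution", "optimize_montage", "uniform_target"]


@dataclass
class TargetSpec:
    """Desired region fields per direction plus weights and safety caps.

    ``b`` maps direction ("X"|"Y"|"Z") to a desired-field vector over the
    lead field's regions (V/m); only listed directions enter the objective.
    ``weights`` (>= 0, at least one nonzero) scale each region's rows.
    """

    b: dict[str, np.ndarray]
    weights: np.ndarray
    total_cap_ma: float = 4.0
    per_electrode_cap_ma: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.b:
            raise ValueError("target must specify at least one direction")
        for d in self.b:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 with at least one positive entry")
        if self.total_cap_ma <= 0:
            raise ValueError("total current cap must be > 0 mA")
        if self.per_electrode_cap_ma is not None and self.per_electrode_cap_ma <= 0:
            raise ValueError("per-electrode cap must be > 0 mA")

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(self.b.keys())


@dataclass
class MontageSolution:
    """Optimized currents plus the fit and constraint report."""

    x: CurrentVector
    residual: float  # ||LF x - b||_2 over the optimized directions, unweighted
    objective: float  # weighted squared residual actually minimized
    active_electrodes: list[str]
    constraints: dict = field(default_factory=dict)
    note: str = ""

    @property
    def net_current_ma(self) -> float:
        return sum(self.x.currents.values())

    @property
    def total_abs_current_ma(self) -> float:
        return self.x.total_abs_ma

    @property
    def total_anodal_ma(self) -> float:
        return sum(c for c in self.x.currents.values() if c > 0)


def uniform_target(
    lf: LeadField,
    regions: list[str] | list[int],
    direction,
    magnitude: float,
    spillover_weight: float = 1.0,
    total_cap_ma: float = 4.0,
    per_electrode_cap_ma: float | None = None,
) -> TargetSpec:
    """Uniform desired field of ``magnitude`` V/m on the listed regions (by
    name or id), zero elsewhere including the pooled non-cerebellar brain row.

    ``direction`` is either a single axis name ("X"|"Y"|"Z"), giving a
    one-direction target (solved per direction by default), or a 3-vector,
    giving a uniform vector-field target over all three directions (solve
    with ``stacked=True`` so off-axis components are penalized too — the
    variant that actually steers the field-magnitude hotspot).  Target rows
    get weight 1, all other rows ``spillover_weight`` (0 removes them from
    the objective)."""
    if not regions:
        raise ValueError("regions must be nonempty")
    rows = []
    for r in regions:
        if isinstance(r, str):
            if r not in lf.region_names:
                raise ValueError(f"unknown region {r!r}")
            rows.append(lf.region_names.index(r))
        else:
            if int(r) not in lf.region_ids:
                raise ValueError(f"unknown region id {r}")
            rows.append(lf.region_ids.index(int(r)))
    w = np.full(lf.n_regions, float(spillover_weight))
    w[rows] = 1.0
    if isinstance(direction, str):
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        b1 = np.zeros(lf.n_regions)
        b1[rows] = magnitude
        b = {direction: b1}
        label = direction
    else:
        vec = np.asarray(direction, dtype=float)
        if vec.shape != (3,) or not np.any(vec):
            raise ValueError("direction vector must be a nonzero 3-vector")
        vec = vec / np.linalg.norm(vec)
        b = {}
        for d, comp in zip(DIRECTIONS, vec):
            col = np.zeros(lf.n_regions)
            col[rows] = magnitude * comp
            b[d] = col
        label = "vec(" + ",".join(f"{v:.2f}" for v in vec) + ")"
    return TargetSpec(
        b=b,
        weights=w,
        total_cap_ma=total_cap_ma,
        per_electrode_cap_ma=per_electrode_cap_ma,
        name=f"uniform:{label}:{magnitude:g}",
    )


def _zero_sum_nullspace(n: int) -> np.ndarray:
    """Orthonormal basis (n x (n-1)) of {x : sum(x) = 0}."""
    a = np.eye(n) - np.full((n, n), 1.0 / n)
    q, r = np.linalg.qr(a)
    keep = np.abs(np.diag(r)) > 1e-12
    return q[:, keep]


def _solve_qp_l1(
    A: np.ndarray, b: np.ndarray, cap: float, per_cap: float | None, x0: np.ndarray
) -> np.ndarray:
    """Variable-split QP: min ||A(p-q) - b||^2, p,q >= 0, sum(p+q) <= cap,
    sum(p-q) = 0, optional 0 <= p,q <= per_cap."""
    n = A.shape[1]
    AtA = A.T @ A
    Atb = A.T @ b

    def fun(z):
        x = z[:n] - z[n:]
        r = A @ x - b
        return float(r @ r)

    def grad(z):
        x = z[:n] - z[n:]
        g = 2.0 * (AtA @ x - Atb)
        return np.concatenate([g, -g])

    cons = [
        {"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum(),
         "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])},
        {"type": "ineq", "fun": lambda z: cap - z.sum(),
         "jac": lambda z: -np.ones(2 * n)},
    ]
    hi = per_cap if per_cap is not None else None
    bounds = [(0.0, hi)] * (2 * n)
    z0 = np.concatenate([np.maximum(x0, 0.0), np.maximum(-x0, 0.0)])
    res = minimize(
        fun,
        z0,
        jac=grad,
        bounds=bounds,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    z = res.x
    return z[:n] - z[n:]


def optimize_montage(
    lf: LeadField,
    target: TargetSpec,
    stacked: bool = False,
    sparsify_threshold_frac: float | None = None,
    active_threshold_frac: float = 0.01,
):
    """Solve the montage-design program.

    With one target direction (or ``stacked=True``) returns a single
    :class:`MontageSolution`; with several directions and ``stacked=False``
    (the default) each direction is optimized independently and a dict
    direction -> solution is returned, mirroring how montages are tabulated
    per field direction.

    ``sparsify_threshold_frac`` optionally drops electrodes with |x| below
    that fraction of the cap and re-solves on the rest (off by default; the
    program imposes no cardinality constraint).
    """
    dirs = target.directions
    if len(dirs) > 1 and not stacked:
        return {
            d: optimize_montage(
                lf,
                TargetSpec(
                    b={d: target.b[d]},
                    weights=target.weights,
                    total_cap_ma=target.total_cap_ma,
                    per_electrode_cap_ma=target.per_electrode_cap_ma,
                    name=target.name,
                ),
                sparsify_threshold_frac=sparsify_threshold_frac,
                active_threshold_frac=active_threshold_frac,
            )
            for d in dirs
        }

    for d in dirs:
        if len(np.asarray(target.b[d])) != lf.n_regions:
            raise ValueError(
                f"target direction {d}: {len(target.b[d])} rows, lead field has {lf.n_regions}"
            )
    if len(target.weights) != lf.n_regions:
        raise ValueError("weights length must match the lead field's region count")

    w = np.sqrt(target.weights)
    A = np.vstack([w[:, None] * lf.matrices[d] for d in dirs])
    bvec = np.concatenate([w * np.asarray(target.b[d], dtype=float) for d in dirs])
    A_raw = np.vstack([lf.matrices[d] for d in dirs])
    b_raw = np.concatenate([np.asarray(target.b[d], dtype=float) for d in dirs])

    # the optimization variable covers every catalog electrode including the
    # reference; the reference has no lead-field column (zero contribution)
    ids = lf.electrode_ids + [lf.reference_id]
    n = len(ids)
    A_full = np.hstack([A, np.zeros((A.shape[0], 1))])

    x, note = _solve(A_full, bvec, n, target)

    if sparsify_threshold_frac is not None:
        keep = np.abs(x) >= sparsify_threshold_frac * target.total_cap_ma
        keep[-1] = True  # reference stays available for balance
        if keep.sum() >= 2 and keep.sum() < n:
            x_sub, _ = _solve(A_full[:, keep], bvec, int(keep.sum()), target)
            x = np.zeros(n)
            x[keep] = x_sub
            note = (note + "; " if note else "") + f"sparsified to {int(keep.sum())} electrodes"

    x_nonref = x[:-1]
    resid = float(np.linalg.norm(A_raw @ x_nonref - b_raw))
    objective = float(np.sum((A_full @ x - bvec) ** 2))
    currents = {i: float(v) for i, v in zip(ids, x)}
    active = [i for i, v in currents.items() if abs(v) > active_threshold_frac * target.total_cap_ma]
    tot = float(np.abs(x).sum())
    constraints = {
        "net_current_ma": float(x.sum()),
        "total_abs_current_ma": tot,
        "total_cap_ma": target.total_cap_ma,
        "cap_slack_ma": target.total_cap_ma - tot,
        "per_electrode_cap_ma": target.per_electrode_cap_ma,
        "max_abs_electrode_ma": float(np.max(np.abs(x))) if n else 0.0,
    }
    return MontageSolution(
        x=CurrentVector(currents),
        residual=resid,
        objective=objective,
        active_electrodes=active,
        constraints=constraints,
        note=note,
    )


def _solve(A: np.ndarray, b: np.ndarray, n: int, target: TargetSpec) -> tuple[np.ndarray, str]:
    cap = target.total_cap_ma
    per_cap = target.per_electrode_cap_ma
    note = ""

    if not np.any(b):
        return np.zeros(n), "zero target"

    # stage 1: equality-constrained LS via nullspace basis (exact)
    Z = _zero_sum_nullspace(n)
    y, *_ = np.linalg.lstsq(A @ Z, b, rcond=None)
    x = Z @ y
    x -= x.mean()  # exact zero sum
    feasible = np.abs(x).sum() <= cap and (
        per_cap is None or np.abs(x).max() <= per_cap
    )
    if not np.any(np.abs(x) > 0):
        note = "trivial problem (rank-deficient or zero lead field): x = 0"
    if not feasible:
        # stage 2: budget binds; exact split QP
        x0 = x * min(1.0, cap / np.abs(x).sum())
        if per_cap is not None:
            x0 = np.clip(x0, -per_cap, per_cap)
        x = _solve_qp_l1(A, b, cap, per_cap, x0)
        note = "current budget active"
        # exact feasibility projections (negligible objective change)
        x = x - x.mean()
        tot = np.abs(x).sum()
        if tot > cap:
            x *= cap / tot
        if per_cap is not None and np.abs(x).max() > per_cap:
            x = np.clip(x, -per_cap, per_cap)
            x = x - x.mean()
            tot = np.abs(x).sum()
            if tot > cap:
                x *= cap / tot
    return x, note
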