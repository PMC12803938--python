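"""Linear-programming engine: FBA, parsimonious FBA and flux variability.

All optimisation is plain LP via ``scipy.optimize.linprog`` (HiGHS).  Absolute
values (total flux, loop removal) are handled by splitting each flux into
nonnegative forward/reverse components ``v = f - r``; with the cap
``sum(f + r) <= C`` the feasible set in flux space is exactly
``sum(|v|) <= C``, so no integer variables are needed.

Loopless analysis follows the CycleFreeFlux idea: given an optimal solution,
fix the boundary fluxes and the objective value, constrain every internal
flux to keep its sign and not exceed its magnitude, and minimise the internal
L1 norm.  Flux variability with ``loopless=True`` post-processes each
per-reaction optimum this way (with the COBRApy-style "almost loopless"
re-optimisation when the optimum itself rode on a loop), so reported ranges
contain only fluxes attainable without thermodynamically infeasible cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .exceptions import InfeasibleError, UnboundedError
from .model import MetabolicModel

__all__ = [
    "FVASettings",
    "FluxDistribution",
    "FluxRange",
    "fba",
    "pfba",
    "fva",
    "remove_loops",
]


@dataclass(frozen=True)
class FVASettings:
    """Settings for flux variability analysis.

    Defaults are the pipeline's standard operating point: at least 90% of
    the optimal biomass objective, at most 10% more than the minimum
    necessary total flux, and loopless post-processing on.
    """

    fraction_of_optimum: float = 0.9
    pfba_factor: Optional[float] = 1.1
    loopless: bool = True
    solver_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_of_optimum <= 1.0:
            raise ValueError("fraction_of_optimum must be in (0, 1]")
        if self.pfba_factor is not None and self.pfba_factor < 1.0:
            raise ValueError("pfba_factor must be >= 1 (or None)")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")

    def to_dict(self) -> dict:
        return {
            "fraction_of_optimum": self.fraction_of_optimum,
            "pfba_factor": self.pfba_factor,
            "loopless": self.loopless,
            "solver_tolerance": self.solver_tolerance,
        }


@dataclass
class FluxDistribution:
    """One feasible (usually optimal) flux vector."""

    fluxes: pd.Series
    objective_value: float
    total_flux: float

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])

    def to_frame(self) -> pd.DataFrame:
        return self.fluxes.rename("flux").rename_axis("reaction_id").to_frame()

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class FluxRange:
    """Per-reaction feasible [minimum, maximum] flux from FVA."""

    ranges: pd.DataFrame  # index reaction_id, columns minimum/maximum
    settings: FVASettings = field(default_factory=FVASettings)

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        row = self.ranges.loc[rid]
        return (float(row["minimum"]), float(row["maximum"]))

    @property
    def minimum(self) -> pd.Series:
        return self.ranges["minimum"]

    @property
    def maximum(self) -> pd.Series:
        return self.ranges["maximum"]

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.ranges.rename_axis("reaction_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# solver plumbing
# ---------------------------------------------------------------------------

def _solve(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None, context=""):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(f"infeasible LP ({context}): {res.message}")
    if res.status == 3:
        raise UnboundedError(f"unbounded LP ({context}): {res.message}")
    if res.status != 0:
        raise InfeasibleError(f"solver failure ({context}): {res.message}")
    return res


class _Problem:
    """Cached matrices for one model, in declared reaction order."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rids = model.reaction_ids
        self.n = len(self.rids)
        self.S = model.stoichiometric_matrix().tocsr()
        self.lb, self.ub = model.bounds_arrays()
        self.c = model.objective_array()
        self.boundary = np.array([r.is_exchange for r in model.reactions])
        self.index = {rid: j for j, rid in enumerate(self.rids)}

    # split space: x = [f, r], v = f - r, f/r >= 0
    def split_bounds(self) -> list:
        fb = [(max(l, 0.0), max(u, 0.0)) for l, u in zip(self.lb, self.ub)]
        rb = [(max(-u, 0.0), max(-l, 0.0)) for l, u in zip(self.lb, self.ub)]
        return fb + rb

    def split_eq(self):
        return sparse.hstack([self.S, -self.S]).tocsr()

    def split_vec(self, w: np.ndarray) -> np.ndarray:
        return np.concatenate([w, -w])

    def series(self, v: np.ndarray) -> pd.Series:
        return pd.Series(v, index=pd.Index(self.rids, name="reaction_id"))


def fba(model: MetabolicModel) -> FluxDistribution:
    """Maximise the model objective: max c'v s.t. S v = 0, lb <= v <= ub."""
    if not model.objective:
        raise ValueError("model has an empty objective; nothing to maximise")
    p = _Problem(model)
    res = _solve(
        -p.c,
        A_eq=p.S,
        b_eq=np.zeros(p.S.shape[0]),
        bounds=list(zip(p.lb, p.ub)),
        context=f"FBA on {model.id}",
    )
    v = res.x
    return FluxDistribution(
        fluxes=p.series(v),
        objective_value=float(p.c @ v),
        total_flux=float(np.abs(v).sum()),
    )


def _min_total_flux(p: _Problem, min_objective: float) -> Tuple[float, np.ndarray]:
    """Minimum of sum(|v|) subject to steady state, bounds, c'v >= min_objective."""
    n = p.n
    cost = np.ones(2 * n)
    A_ub = sparse.csr_matrix(-p.split_vec(p.c)[None, :])
    res = _solve(
        cost,
        A_ub=A_ub,
        b_ub=np.array([-min_objective]),
        A_eq=p.split_eq(),
        b_eq=np.zeros(p.S.shape[0]),
        bounds=p.split_bounds(),
        context=f"total-flux minimisation on {p.model.id}",
    )
    v = res.x[:n] - res.x[n:]
    return float(res.fun), v


def pfba(model: MetabolicModel, fraction_of_optimum: float = 1.0) -> FluxDistribution:
    """Parsimonious FBA: minimise total flux at (a fraction of) the optimum.

    Stage 1 finds the FBA optimum ``z*``; stage 2 minimises ``sum(|v|)``
    subject to ``c'v >= fraction_of_optimum * z*``.  The reported
    ``total_flux`` is the stage-2 objective.
    """
    z = fba(model).objective_value
    p = _Problem(model)
    total, v = _min_total_flux(p, fraction_of_optimum * z)
    return FluxDistribution(
        fluxes=p.series(v),
        objective_value=float(p.c @ v),
        total_flux=total,
    )


# ---------------------------------------------------------------------------
# loop removal (CycleFreeFlux-style LP)
# ---------------------------------------------------------------------------

def _cycle_free_lp(
    p: _Problem,
    v0: np.ndarray,
    pinned: Optional[int] = None,
    extra_ub: Sequence[Tuple[np.ndarray, float]] = (),
    fix_objective: bool = False,
) -> np.ndarray:
    """Minimise internal L1 norm around ``v0`` with signs and boundary fixed.

    Boundary (exchange) fluxes are fixed to their ``v0`` values; each
    internal flux keeps its sign and may not exceed its ``v0`` magnitude;
    ``pinned`` (a reaction index) is held exactly at its ``v0`` value.
    Signs are fixed, so the problem stays an LP in the original variables.
    """
    lo = np.empty(p.n)
    hi = np.empty(p.n)
    sign = np.zeros(p.n)
    for j in range(p.n):
        if p.boundary[j] or j == pinned:
            lo[j] = hi[j] = v0[j]
        elif v0[j] >= 0:
            lo[j], hi[j] = max(0.0, p.lb[j]), min(v0[j], p.ub[j])
            sign[j] = 1.0
        else:
            lo[j], hi[j] = max(v0[j], p.lb[j]), min(0.0, p.ub[j])
            sign[j] = -1.0
    # guard against solver jitter in v0
    hi = np.maximum(hi, lo)
    cost = np.where(p.boundary, 0.0, sign)
    if pinned is not None:
        cost[pinned] = 0.0
    rows, bs = [], []
    for a, b in extra_ub:
        rows.append(a)
        bs.append(b)
    if fix_objective:
        rows.append(-p.c)
        bs.append(-float(p.c @ v0))
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.array(bs) if rows else None
    res = _solve(
        cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=p.S,
        b_eq=np.zeros(p.S.shape[0]),
        bounds=list(zip(lo, hi)),
        context=f"loop removal on {p.model.id}",
    )
    return res.x


def remove_loops(
    model: MetabolicModel,
    solution: FluxDistribution,
    pinned_reaction: Optional[str] = None,
) -> FluxDistribution:
    """Strip internal-cycle circulation from a flux distribution.

    The result keeps identical exchange fluxes and objective value, every
    internal flux keeps its sign (or drops to zero), the pinned reaction's
    flux is unchanged, and the internal L1 norm is minimal subject to these
    constraints.  A loop-free input is a fixed point.
    """
    p = _Problem(model)
    v0 = solution.fluxes.reindex(p.rids).to_numpy(dtype=float)
    pinned = p.index[pinned_reaction] if pinned_reaction is not None else None
    v = _cycle_free_lp(p, v0, pinned=pinned, fix_objective=True)
    return FluxDistribution(
        fluxes=p.series(v),
        objective_value=float(p.c @ v),
        total_flux=float(np.abs(v).sum()),
    )


# ---------------------------------------------------------------------------
# flux variability analysis
# ---------------------------------------------------------------------------

def fva(
    model: MetabolicModel,
    settings: Optional[FVASettings] = None,
    reactions: Optional[Sequence[str]] = None,
    optimum: Optional[float] = None,
) -> FluxRange:
    """Feasible flux range per reaction under biomass and total-flux limits.

    For each reaction the flux is minimised and maximised subject to steady
    state, the bounds, ``c'v >= fraction_of_optimum * z*`` and — when
    ``pfba_factor`` is set — ``sum(|v|) <= pfba_factor * T``, where ``T`` is
    the minimum total flux attainable under the same biomass constraint.
    With ``loopless=True`` each per-reaction optimum is post-processed to a
    cycle-free value before being reported.

    ``optimum`` overrides the objective value used for the fraction
    constraint (by default the model's own FBA optimum), which lets a caller
    constrain several related models by one shared reference optimum.
    """
    settings = settings or FVASettings()
    p = _Problem(model)
    z = fba(model).objective_value if optimum is None else float(optimum)
    min_obj = settings.fraction_of_optimum * z
    zero_cutoff = max(1e-6, settings.solver_tolerance * 1e3)

    cap: Optional[float] = None
    if settings.pfba_factor is not None:
        t_min, _ = _min_total_flux(p, min_obj)
        cap = settings.pfba_factor * t_min

    n = p.n
    if reactions is None:
        targets = list(range(n))
    else:
        targets = [p.index[r] for r in reactions]

    # constraint rows shared by every subproblem, in split space
    A_rows = [sparse.csr_matrix(-p.split_vec(p.c)[None, :])]
    b_rows = [-min_obj]
    if cap is not None:
        A_rows.append(sparse.csr_matrix(np.ones((1, 2 * n))))
        b_rows.append(cap)
    A_ub = sparse.vstack(A_rows).tocsr()
    b_ub = np.array(b_rows)
    A_eq = p.split_eq()
    b_eq = np.zeros(p.S.shape[0])
    base_bounds = p.split_bounds()

    # plain-space rows for the cycle-free subproblems
    plain_rows: list = [(-p.c, -min_obj)]

    def solve_dir(j: int, sense: int, bounds) -> Tuple[float, np.ndarray]:
        """sense=+1 maximise, -1 minimise flux of reaction j."""
        cost = np.zeros(2 * n)
        cost[j] = -float(sense)
        cost[n + j] = float(sense)
        res = _solve(
            cost,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=bounds,
            context=f"FVA subproblem for {p.rids[j]}",
        )
        v = res.x[:n] - res.x[n:]
        return float(sense * -res.fun), v

    def loopless_value(j: int, sense: int, current: float, v0: np.ndarray) -> float:
        if p.boundary[j]:
            return current
        extra = list(plain_rows)
        if cap is not None:
            # signs are fixed inside the cycle-free LP, so |v| is linear
            sgn = np.where(v0 >= 0, 1.0, -1.0)
            extra.append((sgn, cap))
        ll = _cycle_free_lp(p, v0, extra_ub=extra)
        if abs(ll[j] - current) < zero_cutoff:
            return current
        almost = _cycle_free_lp(p, v0, pinned=j, extra_ub=extra)
        clamp = [
            i
            for i in range(n)
            if not p.boundary[i]
            and abs(ll[i]) < zero_cutoff
            and abs(almost[i]) > zero_cutoff
        ]
        bounds = list(base_bounds)
        for i in clamp:
            bounds[i] = (0.0, 0.0)          # forward part
            bounds[n + i] = (0.0, 0.0)      # reverse part
        value, _ = solve_dir(j, sense, bounds)
        return value

    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in targets:
        lo, v_lo = solve_dir(j, -1, base_bounds)
        hi, v_hi = solve_dir(j, +1, base_bounds)
        if settings.loopless:
            lo = loopless_value(j, -1, lo, v_lo)
            hi = loopless_value(j, +1, hi, v_hi)
        if lo > hi:
            if lo - hi < 1e-6:
                lo = hi = 0.5 * (lo + hi)
            else:  # pragma: no cover - indicates a solver defect
                raise InfeasibleError(
                    f"FVA returned min > max for reaction {p.rids[j]}"
                )
        vmin[j], vmax[j] = lo, hi

    idx = [p.rids[j] for j in targets]
    vmin += 0.0  # normalise -0.0
    vmax += 0.0
    df = pd.DataFrame(
        {"minimum": vmin[targets], "maximum": vmax[targets]},
        index=pd.Index(idx, name="reaction_id"),
    )
    return FluxRange(ranges=df, settings=settings)
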