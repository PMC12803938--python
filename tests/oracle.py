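"""Independent brute-force LP oracle used to cross-check the package.

Deliberately shares no code with ``difflux.analysis``: dense matrices, and
absolute values encoded with auxiliary |v| <= t variables instead of
forward/reverse splitting.  Loopless ranges are computed exactly for
networks whose internal cycles are explicitly enumerated (each cycle a list
of irreversible reaction ids: a loopless solution must zero at least one
member of every cycle, so the true range is the union over those cases).
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog


def dense_arrays(model):
    rids = [r.id for r in model.reactions]
    mids = [m.id for m in model.metabolites]
    S = np.zeros((len(mids), len(rids)))
    mi = {m: i for i, m in enumerate(mids)}
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[mi[mid], j] = coef
    lb = np.array([r.lower_bound for r in model.reactions], float)
    ub = np.array([r.upper_bound for r in model.reactions], float)
    c = np.zeros(len(rids))
    for j, r in enumerate(model.reactions):
        c[j] = model.objective.get(r.id, 0.0)
    return rids, S, lb, ub, c


def _lp(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return res


def brute_fba(model) -> Tuple[float, Dict[str, float]]:
    rids, S, lb, ub, c = dense_arrays(model)
    res = _lp(-c, None, None, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    return float(c @ res.x), dict(zip(rids, res.x))


def brute_min_total(model, min_objective: float) -> Tuple[float, Dict[str, float]]:
    """min sum(|v|) s.t. S v = 0, bounds, c'v >= min_objective; |v|<=t encoding."""
    rids, S, lb, ub, c = dense_arrays(model)
    n = len(rids)
    # variables [v, t]
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    I = np.eye(n)
    A_ub = np.block([[I, -I], [-I, -I]])
    A_ub = np.vstack([A_ub, np.concatenate([-c, np.zeros(n)])])
    b_ub = np.concatenate([np.zeros(2 * n), [-min_objective]])
    A_eq = np.hstack([S, np.zeros_like(S)])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    res = _lp(cost, A_ub, b_ub, A_eq, np.zeros(S.shape[0]), bounds)
    return float(res.x[n:].sum()), dict(zip(rids, res.x[:n]))


def brute_fva(
    model,
    fraction_of_optimum: float = 1.0,
    pfba_factor: Optional[float] = None,
    forced_zero: Sequence[str] = (),
) -> Dict[str, Tuple[float, float]]:
    rids, S, lb, ub, c = dense_arrays(model)
    n = len(rids)
    z, _ = brute_fba(model)
    min_obj = fraction_of_optimum * z
    lb, ub = lb.copy(), ub.copy()
    for rid in forced_zero:
        j = rids.index(rid)
        lb[j] = max(lb[j], 0.0)
        ub[j] = min(ub[j], 0.0)

    I = np.eye(n)
    rows = [np.concatenate([-c, np.zeros(n)])]
    rhs = [-min_obj]
    use_t = pfba_factor is not None
    if use_t:
        t_min, _ = brute_min_total(model, min_obj)
        rows.append(np.concatenate([np.zeros(n), np.ones(n)]))
        rhs.append(pfba_factor * t_min)
        A_ub = np.vstack([np.block([[I, -I], [-I, -I]]), np.vstack(rows)])
        b_ub = np.concatenate([np.zeros(2 * n), rhs])
        A_eq = np.hstack([S, np.zeros_like(S)])
        bounds = list(zip(lb, ub)) + [(0.0, None)] * n
        nv = 2 * n
    else:
        A_ub = np.vstack(rows)
        b_ub = np.array(rhs)
        A_eq = S
        bounds = list(zip(lb, ub))
        nv = n

    out = {}
    for j, rid in enumerate(rids):
        cost = np.zeros(nv)
        cost[j] = 1.0
        lo = float(_lp(cost, A_ub, b_ub, A_eq, np.zeros(S.shape[0]), bounds).x[j])
        cost[j] = -1.0
        hi = float(_lp(cost, A_ub, b_ub, A_eq, np.zeros(S.shape[0]), bounds).x[j])
        out[rid] = (lo, hi)
    return out


def brute_loopless_fva(
    model,
    fraction_of_optimum: float = 1.0,
    pfba_factor: Optional[float] = None,
    cycles: Sequence[Sequence[str]] = (),
) -> Dict[str, Tuple[float, float]]:
    """Exact loopless FVA given an explicit enumeration of internal cycles."""
    assert cycles, "provide the model's internal cycles"
    union: Dict[str, Tuple[float, float]] = {}
    for choice in itertools.product(*cycles):
        ranges = brute_fva(
            model,
            fraction_of_optimum=fraction_of_optimum,
            pfba_factor=pfba_factor,
            forced_zero=choice,
        )
        for rid, (lo, hi) in ranges.items():
            if rid in union:
                plo, phi = union[rid]
                union[rid] = (min(plo, lo), max(phi, hi))
            else:
                union[rid] = (lo, hi)
    return union


def to_cobra(model):
    """Convert a difflux model to a cobra model (for cross-checks only)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    cm.objective = {
        cm.reactions.get_by_id(rid): coef for rid, coef in model.objective.items()
    }
    return cm


def max_mass_imbalance(model, fluxes: Dict[str, float]) -> float:
    _, S, _, _, _ = dense_arrays(model)
    rids = [r.id for r in model.reactions]
    v = np.array([fluxes[r] for r in rids])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0
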