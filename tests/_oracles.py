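"""Independent brute-force oracles used to cross-check the LP machinery.

These deliberately avoid the package's solver path: vertices of the flux
polytope {S v = 0, lb <= v <= ub} are enumerated directly from basic
feasible solutions with numpy linear algebra.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def enumerate_vertices(S, lb, ub, tol=1e-9):
    """All vertices of {v : S v = 0, lb <= v <= ub}.

    Every vertex is a basic feasible solution: at least n - rank(S)
    variables sit at a bound and the rest are uniquely determined by the
    steady-state equations.  Enumerate all such candidate fixings; only
    bounded polytopes are supported (finite lb/ub).
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    vertices: list[np.ndarray] = []
    for fixed_idx in combinations(range(n), n_fixed):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if free_idx and np.linalg.matrix_rank(A) < len(free_idx):
            continue  # free part underdetermined: not a basis
        for choice in product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, c in zip(fixed_idx, choice):
                v[j] = lb[j] if c == 0 else ub[j]
            rhs = -S[:, list(fixed_idx)] @ v[list(fixed_idx)] if fixed_idx else np.zeros(m)
            if free_idx:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free_idx] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                vertices.append(v)
    return vertices


def fva_by_vertex_enumeration(model):
    """FVA ranges as (min, max) dicts via vertex enumeration.

    Valid for bounded polytopes: the extremum of each coordinate over a
    polytope is attained at a vertex.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb = [model.reactions[r].lower_bound for r in rxn_ids]
    ub = [model.reactions[r].upper_bound for r in rxn_ids]
    vertices = enumerate_vertices(S, lb, ub)
    assert vertices, "empty flux polytope"
    V = np.array(vertices)
    return (
        {r: float(V[:, j].min()) for j, r in enumerate(rxn_ids)},
        {r: float(V[:, j].max()) for j, r in enumerate(rxn_ids)},
    )


def fba_by_vertex_enumeration(model, objective, direction="max"):
    """Optimal objective value via vertex enumeration."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb = [model.reactions[r].lower_bound for r in rxn_ids]
    ub = [model.reactions[r].upper_bound for r in rxn_ids]
    vertices = enumerate_vertices(S, lb, ub)
    assert vertices, "empty flux polytope"
    idx = {r: j for j, r in enumerate(rxn_ids)}
    values = [
        sum(coef * v[idx[r]] for r, coef in objective.items()) for v in vertices
    ]
    return max(values) if direction == "max" else min(values)
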