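"""Independent reference implementations used only to check wcsim.

These are deliberately naive and share no code with the package's engines:
a first-reaction-method stochastic simulator, and a brute-force
vertex-enumeration LP solver for small flux polytopes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def first_reaction_ssa(reactions, counts, t_end, rng):
    """First-reaction-method Gillespie run; returns final counts.

    ``reactions`` is a list of (reactants, products, c) with stoichiometry
    dicts.  Statistically equivalent to the direct method, implemented
    independently (per-reaction tentative times, fire the earliest).
    """
    counts = dict(counts)
    t = 0.0
    while True:
        taus = []
        for reactants, _, c in reactions:
            a = c
            for sid, s in reactants.items():
                a *= math.comb(counts[sid], s) if counts[sid] >= s else 0
            taus.append(rng.exponential(1.0 / a) if a > 0 else math.inf)
        j = int(np.argmin(taus))
        if not math.isfinite(taus[j]) or t + taus[j] > t_end:
            return counts
        t += taus[j]
        reactants, products, _ = reactions[j]
        for sid, s in reactants.items():
            counts[sid] -= s
        for sid, s in products.items():
            counts[sid] = counts.get(sid, 0) + s


def lp_vertex_max(problem, tol: float = 1e-7) -> float:
    """Brute-force optimum of an FBAProblem by vertex enumeration.

    Candidate active sets are drawn from the availability inequalities and
    the variable bounds on top of the always-active steady-state rows; every
    nonsingular square system is solved and checked for feasibility.  Only
    valid for small problems (≤ ~6 reactions).
    """
    n = len(problem.reaction_ids)
    base_rows = [problem.stoichiometry[i] for i in range(len(problem.internal_ids))]
    base_rhs = [0.0] * len(base_rows)

    cands: list[tuple[np.ndarray, float]] = []
    for i in range(len(problem.boundary_ids)):
        cands.append((-problem.boundary_stoichiometry[i], float(problem.availability[i])))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        if math.isfinite(problem.lower[j]):
            cands.append((e, float(problem.lower[j])))
        if math.isfinite(problem.upper[j]):
            cands.append((e.copy(), float(problem.upper[j])))

    need = n - len(base_rows)
    best = -math.inf
    for combo in itertools.combinations(range(len(cands)), need):
        A = np.array(base_rows + [cands[k][0] for k in combo])
        b = np.array(base_rhs + [cands[k][1] for k in combo])
        if A.shape[0] != n or abs(np.linalg.det(A)) < 1e-12:
            continue
        v = np.linalg.solve(A, b)
        if np.any(v < problem.lower - tol) or np.any(v > problem.upper + tol):
            continue
        if len(problem.internal_ids) and np.max(np.abs(problem.stoichiometry @ v)) > tol:
            continue
        if len(problem.boundary_ids) and np.any(
            -problem.boundary_stoichiometry @ v > problem.availability + tol
        ):
            continue
        best = max(best, float(problem.objective @ v))
    return best
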