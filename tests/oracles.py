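"""Independent oracles used to cross-check the library implementations.

These deliberately avoid the code paths under test: LP optima come from
exhaustive vertex enumeration of the polytope (not from gsmm.fba_engine),
producibility from raw scipy linprog calls on an augmented system, GPR truth
values from Python ``eval`` of the rule string, and formula counts from a
regex-free character walk.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def brute_force_lp_max(S: np.ndarray, bounds, c: np.ndarray, tol: float = 1e-7):
    """Maximum of c.v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Every vertex of the (box-bounded, hence pointed) polyhedron has at least
    n - rank(S) variables at a bound; all such fixings are enumerated and the
    remaining square-ish system solved by least squares, keeping feasible
    candidates only.  Returns None when no candidate is feasible.
    """
    m, n = S.shape
    lbs = np.array([b[0] for b in bounds], dtype=float)
    ubs = np.array([b[1] for b in bounds], dtype=float)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = None
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for choice in itertools.product((0, 1), repeat=k):
            v = np.zeros(n)
            for j, at_upper in zip(fixed, choice):
                v[j] = ubs[j] if at_upper else lbs[j]
            rhs = -S[:, list(fixed)] @ v[list(fixed)] if k else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lbs - tol) or np.any(v > ubs + tol):
                continue
            z = float(c @ v)
            if best is None or z > best:
                best = z
    return best


def lp_producible(model, met_id: str, sense: str) -> bool:
    """Can the network produce (sense='production') or absorb a metabolite?

    Augments S v = 0 with a drain (production test) or a supply (consumption
    test) column for the metabolite and asks whether that auxiliary flux can
    exceed zero — the LP formulation of the gapFind question.
    """
    S = model.stoichiometric_matrix()
    met_pos = model.metabolite_ids.index(met_id)
    aux = np.zeros((S.shape[0], 1))
    aux[met_pos, 0] = -1.0 if sense == "production" else 1.0
    S_aug = np.hstack([S, aux])
    bounds = model.bounds() + [(0.0, 1000.0)]
    c = np.zeros(S_aug.shape[1])
    c[-1] = -1.0  # maximize the auxiliary flux
    result = linprog(c, A_eq=S_aug, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    return result.status == 0 and -result.fun > 1e-6


def gpr_truth_eval(rule_text: str, assignment: dict[str, bool]) -> bool:
    """Evaluate a GPR rule via Python's own boolean operators."""
    expr = rule_text
    names = dict(assignment)
    return bool(eval(expr, {"__builtins__": {}}, names))  # noqa: S307 - test oracle


def charwalk_formula(formula: str) -> dict[str, int]:
    """Regex-free formula parser: walk characters, accumulate counts."""
    counts: dict[str, int] = {}
    i = 0
    while i < len(formula):
        assert formula[i].isupper(), f"bad formula {formula!r}"
        element = formula[i]
        i += 1
        if i < len(formula) and formula[i].islower():
            element += formula[i]
            i += 1
        digits = ""
        while i < len(formula) and formula[i].isdigit():
            digits += formula[i]
            i += 1
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return counts
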