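"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
parsimony scores come from exhaustive enumeration of internal-node
labelings, calibration from constraint-propagation to a fixed point, and
predictions from one-shot closed-form generalized-least-squares algebra.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# parsimony by exhaustive enumeration
# ---------------------------------------------------------------------------


def _collect_structure(tree):
    """Postorder (children, labels) lists for a nested-tuple tree."""
    children, labels = [], []

    def walk(node):
        if isinstance(node, str):
            children.append([])
            labels.append(node)
            return len(children) - 1
        idx = [walk(c) for c in node]
        children.append(idx)
        labels.append(None)
        return len(children) - 1

    walk(tree)
    return children, labels


def step_cost(a: int, b: int, ordered: bool) -> int:
    return abs(a - b) if ordered else int(a != b)


def enumerate_char(tree, tip_states: dict[str, frozenset[int]], n_states: int, ordered: bool):
    """(min cost, node -> MPR set) for one character by full enumeration.

    Internal labelings are enumerated exhaustively; each tip contributes the
    cheapest transition from its parent's state among its allowed states
    (all states if the set is empty / missing).
    """
    children, labels = _collect_structure(tree)
    n_nodes = len(children)
    internal = [i for i in range(n_nodes) if children[i]]
    tips = [i for i in range(n_nodes) if not children[i]]
    parent = {}
    for i, kids in enumerate(children):
        for c in kids:
            parent[c] = i
    allowed = {
        i: sorted(tip_states.get(labels[i], frozenset()) or range(n_states))
        for i in tips
    }

    if not internal:  # single-tip tree
        return 0, {tips[0]: frozenset(allowed[tips[0]])}

    best_cost = None
    optima = []  # list of internal labelings achieving the minimum
    for combo in itertools.product(range(n_states), repeat=len(internal)):
        lab = dict(zip(internal, combo))
        cost = 0
        for i in internal:
            if i in parent:
                cost += step_cost(lab[parent[i]], lab[i], ordered)
        for i in tips:
            p = lab[parent[i]]
            cost += min(step_cost(p, s, ordered) for s in allowed[i])
        if best_cost is None or cost < best_cost:
            best_cost, optima = cost, [lab]
        elif cost == best_cost:
            optima.append(lab)

    mpr: dict[int, set[int]] = {i: set() for i in range(n_nodes)}
    for lab in optima:
        for i in internal:
            mpr[i].add(lab[i])
        for i in tips:
            p = lab[parent[i]]
            m = min(step_cost(p, s, ordered) for s in allowed[i])
            mpr[i] |= {s for s in allowed[i] if step_cost(p, s, ordered) == m}
    return best_cost, {i: frozenset(s) for i, s in mpr.items()}


def enumerate_matrix_length(tree, matrix) -> int:
    """Total parsimony length by per-character enumeration."""
    total = 0
    for j in range(matrix.n_chars):
        tip_states = {t: matrix.cells[i][j] for i, t in enumerate(matrix.taxa)}
        n_states = matrix.n_states(j)
        cost, _ = enumerate_char(tree, tip_states, max(n_states, 1), matrix.ordered[j])
        total += cost
    return total


# ---------------------------------------------------------------------------
# mbl calibration by constraint propagation
# ---------------------------------------------------------------------------


def propagate_mbl(children, tip_age, min_branch, max_iter=10_000):
    """Pointwise-minimal node ages satisfying the mbl constraints.

    *children* is a postorder adjacency list (tips empty), *tip_age* maps
    postorder tip index -> age.  Repeatedly raises each node to satisfy
    (i) node >= oldest descendant tip and (ii) parent >= child + min_branch,
    until nothing changes.
    """
    n = len(children)
    desc_tips = [set() for _ in range(n)]
    for i, kids in enumerate(children):
        if not kids:
            desc_tips[i] = {i}
        else:
            for c in kids:
                desc_tips[i] |= desc_tips[c]
    age = [tip_age[i] if not children[i] else 0.0 for i in range(n)]
    for _ in range(max_iter):
        changed = False
        for i, kids in enumerate(children):
            if not kids:
                continue
            lo = max(max(tip_age[t] for t in desc_tips[i]),
                     max(age[c] + min_branch for c in kids))
            if lo > age[i] + 1e-12:
                age[i] = lo
                changed = True
        if not changed:
            return age
    raise RuntimeError("propagation did not converge")


# ---------------------------------------------------------------------------
# closed-form GLS conditional prediction
# ---------------------------------------------------------------------------


def gls_conditional_mean(X_obs, y_obs, x_new, V_full, n_obs):
    """Kriging mean for the last rows of V_full given the first n_obs.

    beta from GLS on the observed block; prediction x_new beta +
    C_no C_oo^-1 (y - X beta).  Returns an array, one value per new tip.
    """
    V_oo = V_full[:n_obs, :n_obs]
    V_no = V_full[n_obs:, :n_obs]
    Vi = np.linalg.inv(V_oo)
    beta = np.linalg.solve(X_obs.T @ Vi @ X_obs, X_obs.T @ Vi @ y_obs)
    resid = y_obs - X_obs @ beta
    return np.asarray(x_new) @ beta + V_no @ Vi @ resid
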