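"""Independent oracles used by the test suite.

These deliberately avoid the package's own fitting code paths: the
log-linear oracle goes through a generic Poisson count regression with a log
link, and the chain utilities are direct forward simulations.
"""

import itertools

import numpy as np
import statsmodels.api as sm


def loglinear_design(dims, levels, classes):
    """Dummy-coded design matrix for a hierarchical log-linear model.

    One column per interaction subset contained in a generating class (the
    intercept included), products of 0/1 treatment codes per factor level
    above baseline.
    """
    class_sets = [frozenset(c) for c in classes]
    shape = [len(levels[d]) for d in dims]
    cells = list(itertools.product(*[range(s) for s in shape]))
    cols = []
    for r in range(len(dims) + 1):
        for subset in itertools.combinations(range(len(dims)), r):
            if not any({dims[i] for i in subset} <= cs for cs in class_sets):
                continue
            # one column per combination of non-baseline levels
            level_choices = [range(1, shape[i]) for i in subset]
            for combo in itertools.product(*level_choices):
                col = [
                    float(all(cell[ax] == lv for ax, lv in zip(subset, combo)))
                    for cell in cells
                ]
                cols.append(col)
    return np.array(cols).T if cols else np.ones((len(cells), 1))


def poisson_deviance(table, classes) -> float:
    """G² of a hierarchical log-linear model via maximum-likelihood Poisson
    regression — the classical equivalence used as an IPF cross-check."""
    y = table.counts.reshape(-1)
    X = loglinear_design(table.dims, table.levels, [tuple(c) for c in classes])
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200, tol=1e-12)
    return float(res.deviance)


def simulate_two_state_chain(p_ia, p_ai, n, rng):
    """Forward-simulate a two-state chain; returns the 2x2 transition counts."""
    counts = np.zeros((2, 2), dtype=int)
    state = 0
    u = rng.random(n)
    for i in range(n):
        p_active = p_ia if state == 0 else 1.0 - p_ai
        nxt = 1 if u[i] < p_active else 0
        counts[state, nxt] += 1
        state = nxt
    return counts
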