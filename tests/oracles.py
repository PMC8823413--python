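"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: direct formula evaluation, exhaustive
enumeration and grid search, kept free of any code path they are used to
check.
"""

import numpy as np


def cox_partial_loglik(beta, time, event, x, ties="efron"):
    """Single-covariate Cox partial log-likelihood, written out longhand."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(time[event]):
        dead = event & (time == t)
        risk = time >= t
        d = dead.sum()
        sum_dead = np.exp(beta * x[dead]).sum()
        sum_risk = np.exp(beta * x[risk]).sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            ll -= np.log(sum_risk - frac * sum_dead)
    return ll


def cox_grid_maximizer(time, event, x, ties="efron", lo=-5.0, hi=5.0, tol=1e-6):
    """Maximize the hand-coded partial likelihood by iterated grid refinement."""
    for _ in range(12):
        grid = np.linspace(lo, hi, 101)
        vals = [cox_partial_loglik(b, time, event, x, ties) for b in grid]
        k = int(np.argmax(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def auc_pairwise(scores, labels):
    """All-pairs concordance with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Best 'score >= t' threshold over all observed values, lowest-t ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = (None, -np.inf)
    for t in sorted(set(scores)):
        high = scores >= t
        sens = high[labels].mean()
        spec = (~high[~labels]).mean()
        j = sens + spec - 1
        if j > best[1] + 1e-12:
            best = (t, j)
    return best


def km_product_limit(times, events, t_query):
    """Hand product-limit estimate at one query time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    for t in sorted(set(times[events])):
        if t > t_query:
            break
        at_risk = (times >= t).sum()
        d = (events & (times == t)).sum()
        s *= 1 - d / at_risk
    return s
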