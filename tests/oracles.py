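"""Independent reference implementations used only by the test suite.

Each oracle deliberately takes a different computational route from the
package code it checks: recursive kinship vs Meuwissen-Luo tracing /
tabular matrix, exhaustive window enumeration vs two-pointer scanning,
longhand pseudo-values vs vectorized jackknife, normal equations vs
scipy's linregress.
"""

from functools import lru_cache

import numpy as np

from autozyg.runs import MISSING


def kinship_recursive(parents: dict):
    """Classical recursive kinship on a parent map {id: (sire, dam)} with
    None for unknown.  Returns a function f(a, b) -> coancestry."""

    @lru_cache(maxsize=None)
    def depth(a):
        if a is None:
            return -1
        s, d = parents[a]
        return 1 + max(depth(s), depth(d))

    @lru_cache(maxsize=None)
    def f(a, b):
        if a is None or b is None:
            return 0.0
        if a == b:
            s, d = parents[a]
            return 0.5 * (1.0 + f(s, d))
        # recurse on the deeper (younger) member so recursion terminates
        if depth(a) < depth(b):
            a, b = b, a
        s, d = parents[a]
        return 0.5 * (f(s, b) + f(d, b))

    return f


def inbreeding_recursive(parents: dict) -> dict:
    """F_i = kinship(sire, dam) via the recursive oracle."""
    f = kinship_recursive(parents)
    out = {}
    for a, (s, d) in parents.items():
        out[a] = f(s, d) if (s is not None and d is not None) else 0.0
    return out


def enumerate_max_windows(vec, pos, params, kind):
    """All maximal conforming windows by exhaustive enumeration.

    Returns a list of (start_idx, end_idx) into the vector, already
    filtered by min_snps and min_length_bp.  A window conforms when its
    endpoints are run-state SNPs, interruption counts fit the budgets,
    and no internal gap exceeds max_gap_bp; it is maximal when no other
    conforming window strictly contains it.
    """
    vec = np.asarray(vec)
    pos = np.asarray(pos)
    n = len(vec)
    missing = vec == MISSING
    het = vec == 1
    if kind == "ROH":
        conform, opposite = (~missing) & (~het), het
    else:
        conform, opposite = het, (~missing) & (~het)

    big_gap = np.diff(pos) > params.max_gap_bp
    copp = np.concatenate(([0], np.cumsum(opposite)))
    cmis = np.concatenate(([0], np.cumsum(missing)))
    cgap = np.concatenate(([0], np.cumsum(big_gap)))

    i_idx = np.arange(n)[:, None]
    j_idx = np.arange(n)[None, :]
    upper = j_idx >= i_idx
    feasible = (upper
                & conform[:, None] & conform[None, :]
                & (copp[j_idx + 1] - copp[i_idx] <= params.max_opposite)
                & (cmis[j_idx + 1] - cmis[i_idx] <= params.max_missing)
                & (cgap[j_idx] - cgap[i_idx] == 0))

    # max feasible end per start; a window (i, J[i]) is contained in some
    # other window iff an earlier start reaches at least as far
    J = np.where(feasible.any(axis=1), n - 1 - np.argmax(feasible[:, ::-1], axis=1), -1)
    out = []
    best = -1
    for i in range(n):
        if J[i] < 0:
            continue
        if J[i] > best:
            out.append((i, int(J[i])))
        best = max(best, int(J[i]))
    return [(i, j) for i, j in out
            if j - i + 1 >= params.min_snps
            and pos[j] - pos[i] + 1 >= params.min_length_bp]


def jackknife_longhand(values, weights=None):
    """Delete-one pseudo-value jackknife written out with explicit loops."""
    values = [v for v in values]
    n = len(values)
    w = [1.0] * n if weights is None else list(weights)

    def wmean(vals, ws):
        return sum(v * x for v, x in zip(vals, ws)) / sum(ws)

    theta_all = wmean(values, w)
    pseudo = []
    for c in range(n):
        loo = wmean([v for k, v in enumerate(values) if k != c],
                    [x for k, x in enumerate(w) if k != c])
        pseudo.append(n * theta_all - (n - 1) * loo)
    est = sum(pseudo) / n
    var = sum((p - est) ** 2 for p in pseudo) / (n - 1)
    return est, (var / n) ** 0.5


def ols_normal_equations(x, y):
    """Slope and R^2 straight from the normal equations."""
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return float(beta[1]), 1.0 - ss_res / ss_tot


def random_pedigree(rng, n_max=50):
    """A random valid pedigree as a parent map {id: (sire, dam)}.

    Individuals are added in order; parents are sampled (or left unknown)
    from earlier individuals regardless of sex, which is valid for
    kinship arithmetic and exercises deep, tangled ancestries.
    """
    n = int(rng.integers(3, n_max + 1))
    parents = {}
    ids = [f"X{k}" for k in range(n)]
    for k, iid in enumerate(ids):
        if k < 2 or rng.random() < 0.25:
            parents[iid] = (None, None)
        else:
            s, d = rng.choice(k, size=2)
            parents[iid] = (ids[int(s)], ids[int(d)])
    return parents


def gene_drop_kinship(parents: dict, pair, n_reps, rng):
    """Monte-Carlo kinship: drop labelled founder alleles down the pedigree
    and count identity of random alleles drawn from the two individuals."""
    order = []
    seen = set()

    def visit(a):
        if a is None or a in seen:
            return
        s, d = parents[a]
        visit(s)
        visit(d)
        seen.add(a)
        order.append(a)

    for a in parents:
        visit(a)

    i, j = pair
    hits = 0
    for _ in range(n_reps):
        alleles = {}
        label = 0
        for a in order:
            s, d = parents[a]
            pa = alleles[s][rng.integers(2)] if s is not None else (label := label + 1)
            ma = alleles[d][rng.integers(2)] if d is not None else (label := label + 1)
            alleles[a] = (pa, ma)
        hits += alleles[i][rng.integers(2)] == alleles[j][rng.integers(2)]
    return hits / n_reps
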