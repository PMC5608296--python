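"""Independent brute-force oracles used only by the tests.

The Mann-Whitney oracle computes U by direct pairwise comparison counting
(wins plus half-ties) and the two-sided p by enumerating every assignment
of the pooled values to the two groups with :func:`itertools.combinations`
— a different route from the package's rank-sum counting, so agreement is
a genuine cross-check rather than the same code run twice.
"""

import itertools


def pairwise_u(x, y):
    """U statistic of x by counting pairwise wins, ties counted half."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def brute_force_mwu(x, y):
    """Exact two-sided MWU p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    u_obs = pairwise_u(x, y)
    u_all = []
    for comb in itertools.combinations(range(n), n1):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        u_all.append(pairwise_u(xs, ys))
    eps = 1e-9
    p_ge = sum(u >= u_obs - eps for u in u_all) / len(u_all)
    p_le = sum(u <= u_obs + eps for u in u_all) / len(u_all)
    return u_obs, min(1.0, 2.0 * min(p_ge, p_le))
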