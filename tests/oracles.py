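"""Independent statistical oracles shared by the test modules.

These re-derive quantities from first principles (hand product-limit
products, the log-rank O-E/V formula, permutation nulls) so the package
implementations are checked against code that shares nothing with them.
"""
import numpy as np


def hand_km(times, events):
    """Product-limit estimate computed as an explicit running product."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    at_risk = len(times)
    surv = 1.0
    out = []
    for t in np.unique(times):
        d = int(events[times == t].sum())
        n = int((times >= t).sum())
        if d > 0:
            surv *= 1.0 - d / n
            out.append((t, n, surv))
    return out


def logrank_statistic(times, events, group):
    """One-df log-rank chi-square from the O-E / hypergeometric-V sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 1)).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var


def permutation_logrank_p(times, events, group, n_perm=10_000, seed=0):
    """Permutation null of the log-rank statistic, vectorized over the
    at-risk/event incidence matrices. Returns ((r+1)/(B+1), observed chi2)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    ev_times = np.unique(times[events == 1])
    at_risk = times[:, None] >= ev_times[None, :]            # n x T
    ev = (times[:, None] == ev_times[None, :]) & (events == 1)[:, None]
    n_j = at_risk.sum(axis=0)
    d_j = ev.sum(axis=0)

    def chi2_for(memberships):                               # B x n
        n1 = memberships @ at_risk                           # B x T
        d1 = memberships @ ev
        e1 = d_j * n1 / n_j
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(n_j > 1,
                         d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1),
                         0.0)
        num = (d1 - e1).sum(axis=1) ** 2
        den = v.sum(axis=1)
        return np.where(den > 0, num / den, 0.0)

    obs = chi2_for(group[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(group) for _ in range(n_perm)])
    null = chi2_for(perms)
    p = (1 + (null >= obs - 1e-12).sum()) / (n_perm + 1)
    return p, obs


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    import math

    n1, n2 = a + b, c + d
    k = a + c

    def log_choose(n, r):
        return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    total = log_choose(n1 + n2, k)
    lo, hi = max(0, k - n2), min(k, n1)
    probs = [math.exp(log_choose(n1, x) + log_choose(n2, k - x) - total)
             for x in range(lo, hi + 1)]
    obs = probs[a - lo]
    return sum(p for p in probs if p <= obs * (1 + 1e-9))
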