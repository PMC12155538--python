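"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — explicit loops over risk sets,
dense grids, exhaustive pair enumeration — and shares no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from coxsusie import SimulationConfig, SurvivalOutcome, make_finemap_dataset


def naive_partial_loglik(b, x, times, status, offset=None, ties="efron"):
    """Cox partial log-likelihood by direct summation over risk sets."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    c = np.zeros_like(x) if offset is None else np.asarray(offset, float)
    eta = b * x + c
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[status == 1]):
        D = [i for i in range(len(times)) if times[i] == t and status[i] == 1]
        R = [i for i in range(len(times)) if times[i] >= t]
        d = len(D)
        ll += sum(eta[i] for i in D)
        sum_r = sum(w[i] for i in R)
        sum_d = sum(w[i] for i in D)
        for k in range(d):
            if ties == "efron":
                ll -= np.log(sum_r - (k / d) * sum_d)
            else:
                ll -= np.log(sum_r)
    return ll


def random_survival_fixture(seed, n=50, maf=0.3, effect=1.0, censoring=0.2,
                            round_times=None):
    """One small genotype column + outcome; optional rounding creates ties."""
    cfg = SimulationConfig(n=n, p=1, maf=maf, causal_indices=(0,),
                           effects=(effect,), target_censoring=censoring,
                           seed=seed)
    X, outcome, _ = make_finemap_dataset(cfg)
    if round_times is not None:
        times = np.round(outcome.times, round_times) + 1e-6
        outcome = SurvivalOutcome(times=times, status=outcome.status)
    return X[:, 0], outcome


def exhaustive_power_fdr(pips, truth, threshold):
    """TP/FP/FN by an explicit loop over variables."""
    tp = fp = fn = 0
    for p_j, t_j in zip(pips, truth):
        if p_j >= threshold:
            if t_j:
                tp += 1
            else:
                fp += 1
        elif t_j:
            fn += 1
    return tp, fp, fn


def pairwise_abs_correlations(members, X):
    """All pairwise |Pearson r| among member columns, by explicit pairs."""
    out = []
    members = list(members)
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            xa, xb = X[:, members[a]], X[:, members[b]]
            r = np.corrcoef(xa, xb)[0, 1]
            out.append(abs(r) if np.isfinite(r) else 0.0)
    return out
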