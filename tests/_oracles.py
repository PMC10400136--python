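"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, O(n^2) scans, direct
likelihood optimisation) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import minimize


# --- Fisher exact, by exhaustive fixed-margin enumeration -------------------


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed p as an exact rational: sum P(table) over all tables with
    the observed margins whose probability <= the observed probability."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


# --- product-limit estimator with delayed-entry risk sets -------------------


def km_oracle(entries, times, events):
    """(event_times, survival) by direct risk-set counting."""
    entries = np.asarray(entries, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    ev_times = np.unique(times[events])
    surv = []
    s = 1.0
    for t in ev_times:
        at_risk = np.sum((entries < t) & (times >= t))
        d = np.sum((times == t) & events)
        s *= 1.0 - d / at_risk
        surv.append(s)
    return ev_times, np.array(surv)


# --- Cox partial likelihood (no ties), direct optimisation ------------------


def cox_oracle(X, times, events, entries=None, tol=1e-12):
    """Maximum partial-likelihood coefficients for untied survival data.

    Risk sets honour delayed entry when ``entries`` is given.  With no tied
    event times Breslow, Efron and exact partial likelihoods coincide.
    """
    X = np.asarray(X, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    entries = np.zeros_like(times) if entries is None else np.asarray(entries, float)
    assert len(np.unique(times[events])) == events.sum(), "oracle requires no ties"

    ev_idx = np.where(events)[0]
    risk_masks = [
        (entries < times[i]) & (times >= times[i]) for i in ev_idx
    ]

    def negloglik_grad(beta):
        lp = X @ beta
        w = np.exp(lp)
        nll = 0.0
        grad = np.zeros_like(beta)
        for i, mask in zip(ev_idx, risk_masks):
            denom = w[mask].sum()
            nll -= lp[i] - np.log(denom)
            grad -= X[i] - (w[mask] @ X[mask]) / denom
        return nll, grad

    res = minimize(
        negloglik_grad,
        np.zeros(X.shape[1]),
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": 500},
    )
    # polish with explicit Newton steps (analytic Hessian)
    beta = res.x
    for _ in range(25):
        lp = X @ beta
        w = np.exp(lp)
        grad = np.zeros_like(beta)
        hess = np.zeros((len(beta), len(beta)))
        for i, mask in zip(ev_idx, risk_masks):
            denom = w[mask].sum()
            xbar = (w[mask] @ X[mask]) / denom
            grad -= X[i] - xbar
            xc = X[mask] - xbar
            hess += (w[mask][:, None] * xc).T @ xc / denom
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.linalg.norm(step) < 1e-13:
            break
    return beta


# --- brute-force scar-feature counters --------------------------------------


def lst_oracle(profile, min_seg=10_000_000, smooth_below=3_000_000):
    """Large-scale transitions by explicit per-arm list manipulation."""
    total = 0
    for arm in profile.genome.arms():
        runs = []  # (state, length) merged runs
        for seg in profile.segments:
            if seg.chrom != arm.chrom or not (arm.start <= seg.start < arm.end):
                continue
            state = (seg.total_cn, seg.minor_cn)
            if runs and runs[-1][0] == state:
                runs[-1][1] += seg.length
            else:
                runs.append([state, seg.length])
        kept = [r for r in runs if r[1] >= smooth_below]
        merged = []
        for state, length in kept:
            if merged and merged[-1][0] == state:
                merged[-1][1] += length
            else:
                merged.append([state, length])
        for i in range(len(merged) - 1):
            if merged[i][1] >= min_seg and merged[i + 1][1] >= min_seg:
                total += 1
    return total


def interstitial_loh_oracle(profile, min_len=15_000_000):
    """LOH runs per chromosome, counted by brute-force interval merging."""
    count = 0
    for chrom, p_len, q_len in profile.genome.chromosomes:
        loh = sorted(
            [(s.start, s.end) for s in profile.segments
             if s.chrom == chrom and s.minor_cn == 0 and s.total_cn >= 1]
        )
        merged = []
        for s, e in loh:
            if merged and merged[-1][1] == s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s > min_len and e - s < p_len + q_len:
                count += 1
    return count


def breakpoints_oracle(profile):
    """State transitions between adjacent segments within each arm."""
    count = 0
    for arm in profile.genome.arms():
        segs = [s for s in profile.segments
                if s.chrom == arm.chrom and arm.start <= s.start < arm.end]
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if (a.total_cn, a.minor_cn) != (b.total_cn, b.minor_cn):
                count += 1
    return count
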