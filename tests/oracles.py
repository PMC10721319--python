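"""Independent brute-force oracles used to cross-check the implementation.

Each oracle applies the written scoring/statistical rule directly, by
exhaustive scanning or enumeration, sharing no code with the package's
implementation paths.
"""

from itertools import product

import numpy as np


def gap_scan_apneas(breaths, baseline, trace, gap_factor=1.75, flat_fraction=0.25):
    """Exhaustively scan every inter-breath gap (including trace edges).

    Returns tuples (end_time, missed, flat) for every gap exceeding
    ``gap_factor * T0``; ``flat`` marks whether the interior RMS (from the
    end of the previous breath to the next onset) is below
    ``flat_fraction * rms0``.
    """
    t = trace.t0 + np.arange(trace.samples.size) / trace.fs
    x = trace.samples - trace.samples.mean()

    def interior_rms(s, e):
        i0, i1 = np.searchsorted(t, [s, e])
        seg = x[i0:i1]
        return float(np.sqrt(np.mean(seg**2))) if seg.size else 0.0

    T0 = baseline.T0
    thr = flat_fraction * baseline.rms0
    found = []
    if not breaths:
        if trace.duration > gap_factor * T0:
            found.append((trace.t_end, round(trace.duration / T0), interior_rms(trace.t0, trace.t_end) < thr))
        return found
    lead = breaths[0].onset - trace.t0
    if lead > gap_factor * T0:
        found.append((breaths[0].onset, round(lead / T0), interior_rms(trace.t0, breaths[0].onset) < thr))
    for prev, nxt in zip(breaths[:-1], breaths[1:]):
        gap = nxt.onset - prev.onset
        if gap > gap_factor * T0:
            flat = interior_rms(prev.end, nxt.onset) < thr
            found.append((nxt.onset, round(gap / T0) - 1, flat))
    tail = trace.t_end - breaths[-1].onset
    if tail > gap_factor * T0:
        flat = interior_rms(breaths[-1].end, trace.t_end) < thr
        found.append((trace.t_end, round(tail / T0) - 1, flat))
    return [f for f in found if f[2] and f[1] >= 1]


def rule_label(scenario, epoch, persistent_threshold=20.0, coverage_frac=0.9):
    """Apply the written outcome rules directly to generator ground truth."""
    within = list(scenario.within_stim_apnea)
    post = list(scenario.post_stim_apnea)
    dur = epoch.end - epoch.start
    post_total = sum(e - s for s, e in post)
    if post_total >= persistent_threshold:
        return "persistent_apnea"
    coverage = sum(min(e, dur) - s for s, e in within) / dur if within else 0.0
    resumed = bool(within) and max(e for _, e in within) < dur - 2.0
    if coverage >= coverage_frac and not resumed:
        return "apnea"
    if (within or post) and resumed:
        return "transient_apnea"
    return "no_apnea"


def bh_stepup(pvals, alpha):
    """Brute-force Benjamini-Hochberg: largest k with p_(k) <= k/m * alpha."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k / m * alpha:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    # step-up adjusted p-values
    adj = np.minimum.accumulate((m / np.arange(m, 0, -1)) * sorted_p[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return reject, out


def signed_rank_exact_p(diffs):
    """Exact two-sided signed-rank p by full enumeration of sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = _rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / 2**n


def _rankdata(a):
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a))
    sa = np.asarray(a)[order]
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
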