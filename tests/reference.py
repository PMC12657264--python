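"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain sample-by-sample / enumeration code,
deliberately avoiding the vectorised paths of the package itself.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# EEG


def brute_envelope(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Per-sample centred max-|x| with truncated edge windows."""
    size = int(round(window_s * fs))
    size += 1 - size % 2
    half = size // 2
    absx = np.abs(x)
    return np.array(
        [absx[max(0, i - half) : i + half + 1].max() for i in range(len(x))]
    )


def _scan_runs(above: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    i, n = 0, len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j + 1])
            i = j + 1
        i += 1
    return runs


def _merge(runs: list[list[int]], max_gap: int) -> list[list[int]]:
    out: list[list[int]] = []
    for run in runs:
        if out and run[0] - out[-1][1] < max_gap:
            out[-1][1] = run[1]
        else:
            out.append(list(run))
    return out


def brute_detect_seizures(x: np.ndarray, fs: float, baseline_uV: float, params):
    """(onset_s, duration_s) tuples by naive envelope scan + edge refinement."""
    thr = params.baseline_multiplier * baseline_uV
    env = brute_envelope(x, fs, params.envelope_window_s)
    regions = _merge(_scan_runs(env > thr), int(round(params.seizure_merge_gap_s * fs)))
    half = (int(round(params.envelope_window_s * fs)) + 1 - int(round(params.envelope_window_s * fs)) % 2) // 2
    absx = np.abs(x)
    events = []
    for a, b in regions:
        lo, hi = max(0, a - half), min(len(x), b + half)
        crossings = [i for i in range(lo, hi) if absx[i] > thr]
        if not crossings:
            continue
        first, last = crossings[0], crossings[-1]
        duration = (last - first + 1) / fs
        if duration > params.seizure_min_s:
            events.append((first / fs, duration))
    merged = []
    for onset, dur in sorted(events):
        if merged and onset < merged[-1][0] + merged[-1][1]:
            end = max(merged[-1][0] + merged[-1][1], onset + dur)
            merged[-1] = (merged[-1][0], end - merged[-1][0])
        else:
            merged.append((onset, dur))
    return merged


def brute_detect_spikes(x: np.ndarray, fs: float, params):
    """(onset_s, offset_s) tuples by naive threshold scan."""
    absx = np.abs(x)
    runs = _merge(
        _scan_runs(absx >= params.spike_min_uV),
        int(round(params.spike_min_ms / 1000.0 * fs)),
    )
    out = []
    for a, b in runs:
        dur_ms = (b - a) / fs * 1000.0
        if params.spike_min_ms <= dur_ms <= params.spike_max_ms and absx[a:b].max() <= params.spike_max_uV:
            out.append((a / fs, b / fs))
    return out


def brute_group_trains(spikes, params):
    """Greedy non-overlapping selection among all valid contiguous windows.

    A window [i, j] is valid iff it has >= train_min_spikes members, every
    consecutive inter-onset interval lies within the bounds, and its span
    (last offset - first onset) is below train_max_total_s. Scanning left to
    right, the longest valid-or-extendable window at each start is taken.
    """
    n = len(spikes)

    def intervals_ok(i, j):
        return all(
            params.train_min_interval_s
            <= spikes[k + 1].onset_s - spikes[k].onset_s
            <= params.train_max_interval_s
            for k in range(i, j)
        )

    def window_valid(i, j):
        return (
            j - i + 1 >= params.train_min_spikes
            and intervals_ok(i, j)
            and spikes[j].offset_s - spikes[i].onset_s < params.train_max_total_s
        )

    trains = []
    i = 0
    while i < n:
        # the largest j reachable from i through valid consecutive intervals
        # and an in-bound span
        j_best = i
        for j in range(i + 1, n):
            if not intervals_ok(i, j):
                break
            if spikes[j].offset_s - spikes[i].onset_s >= params.train_max_total_s:
                break
            j_best = j
        if window_valid(i, j_best):
            trains.append(list(range(i, j_best + 1)))
        i = j_best + 1
    return trains


# ---------------------------------------------------------------------------
# statistics


def exact_ranksum_pvalues(x1: np.ndarray, x2: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value via scipy's exhaustive permutation test."""
    from scipy import stats

    def statistic(a, b):
        ranks = stats.rankdata(np.concatenate([a, b]))
        return ranks[: len(a)].sum()

    res = stats.permutation_test(
        (x1, x2),
        statistic,
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=np.inf,
    )
    return float(res.pvalue)


def mc_auc_expectation(
    n_genes: int, set_size: int, k: int, n_draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo mean and SE of the normalised recovery-curve AUC for a
    random ranking, by direct recovery-curve construction."""
    max_auc = sum(k - i for i in range(set_size))
    vals = np.empty(n_draws)
    for d in range(n_draws):
        ranks = rng.choice(n_genes, size=set_size, replace=False)  # 0-based
        hits = np.zeros(k, dtype=int)
        for r in ranks:
            if r < k:
                hits[r] = 1
        recovery = np.cumsum(hits)
        vals[d] = recovery.sum() / max_auc
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))
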