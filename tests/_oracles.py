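"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the defining recipe of the statistic it
checks, with naive loops and no shared code with the package, so agreement
is a genuine dual-route check.
"""

from __future__ import annotations

import itertools

import numpy as np


def fluctuation_oracle(window, scale_min, scale_max) -> float:
    """F from the run-decomposition recipe, via itertools.groupby on signs."""
    w = [float(v) for v in window]
    m = len(w)
    s = scale_max - scale_min
    if s <= 0:
        return 0.0
    diffs = [w[i + 1] - w[i] for i in range(m - 1)]
    signs = [0 if d == 0 else (1 if d > 0 else -1) for d in diffs]
    total = 0.0
    pos = 0
    for sign, grp in itertools.groupby(signs):
        d = len(list(grp))
        if sign == 0:
            # zero differences terminate runs; each is its own 0-amplitude run
            pos += d
            continue
        amplitude = abs(w[pos + d] - w[pos])
        total += amplitude / d
        pos += d
    return total / (s * (m - 1))


def distribution_oracle(window, scale_min, scale_max) -> float:
    """D from the sorted-spread-shortfall recipe, pairwise loops."""
    y = sorted(float(v) for v in window)
    m = len(y)
    s = scale_max - scale_min
    if s <= 0:
        return 0.0
    u = s / (m - 1)
    shortfall, total = 0.0, 0.0
    for i in range(m):
        for j in range(i + 1, m):
            uniform = (j - i) * u
            total += uniform
            empirical = y[j] - y[i]
            if uniform > empirical:
                shortfall += uniform - empirical
    return 1.0 - shortfall / total


def _sse(values) -> float:
    v = list(values)
    mean = sum(v) / len(v)
    return sum((x - mean) ** 2 for x in v)


def exhaustive_segmentation(y, min_seg: int, cp: float) -> list[int]:
    """All accepted cut positions (0-based) by exhaustive best-split search.

    Mirrors CART semantics on a 1-D ordered predictor: at each node every
    admissible cut is scored by direct SSE computation; the earliest
    minimiser wins; a cut is accepted iff its SSE reduction is at least
    ``cp`` times the root SSE.
    """
    y = [float(v) for v in y]
    n = len(y)
    root_sse = _sse(y) if n else 0.0
    cuts: list[int] = []

    def best_cut(a: int, b: int):
        best = None
        for c in range(a + min_seg, b - min_seg + 1):
            sse = _sse(y[a:c]) + _sse(y[c:b])
            if best is None or sse < best[1] - 1e-12:
                best = (c, sse)
        if best is None:
            return None
        gain = _sse(y[a:b]) - best[1]
        return best[0], gain

    def recurse(a: int, b: int) -> None:
        if b - a < 2 * min_seg:
            return
        found = best_cut(a, b)
        if found is None:
            return
        c, gain = found
        if root_sse == 0 or gain <= 0 or gain < cp * root_sse:
            return
        cuts.append(c)
        recurse(a, c)
        recurse(c, b)

    recurse(0, n)
    return sorted(cuts)


def ar1_kalman_impute(y_masked, phi: float, innov_sd: float) -> np.ndarray:
    """Exact fixed-interval Kalman smoother for a zero-mean AR(1) state.

    State x_t = phi x_{t-1} + w_t, w ~ N(0, innov_sd^2); observation equals
    the state (tiny observation noise for numerical stability); missing
    entries (NaN) get no measurement update.  Returns the smoothed state.
    """
    y = np.asarray(y_masked, dtype=float)
    n = y.size
    q = innov_sd**2
    r = 1e-8
    var0 = q / (1 - phi**2)

    xf = np.zeros(n)  # filtered mean
    pf = np.zeros(n)  # filtered variance
    xp = np.zeros(n)  # one-step predicted mean
    pp = np.zeros(n)
    x, p = 0.0, var0
    for t in range(n):
        if t > 0:
            x, p = phi * x, phi**2 * p + q
        xp[t], pp[t] = x, p
        if not np.isnan(y[t]):
            k = p / (p + r)
            x = x + k * (y[t] - x)
            p = (1 - k) * p
        xf[t], pf[t] = x, p

    xs = np.zeros(n)
    xs[-1] = xf[-1]
    ps = pf[-1]
    for t in range(n - 2, -1, -1):
        c = pf[t] * phi / pp[t + 1]
        xs[t] = xf[t] + c * (xs[t + 1] - xp[t + 1])
        ps = pf[t] + c**2 * (ps - pp[t + 1])
    return xs


def recount_durations(event_days, n_days: int) -> np.ndarray:
    """Single-pass recount of the 1-based inter-event clock."""
    event_set = set(int(d) for d in event_days)
    out = np.zeros(n_days, dtype=int)
    since = 0
    for d in range(1, n_days + 1):
        since += 1
        out[d - 1] = since
        if d in event_set:
            since = 0
    return out
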