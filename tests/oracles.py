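"""Independent brute-force oracles the engine implementations are checked
against.  These deliberately use the dumbest possible algorithms: a
day-by-day pill-stock simulation for coverage, and an exhaustive pair scan
for the administrative diabetes rule."""

import datetime as dt

import numpy as np
from numba import njit


@njit(cache=True)
def _stock_sim(days, supplies, horizon, cap):
    """Day-by-day simulation: stock tops up (capped leftover) at each
    dispensing, one pill consumed per covered day."""
    covered = np.zeros(horizon, dtype=np.bool_)
    stock = 0
    k = 0
    n = days.shape[0]
    for day in range(horizon):
        while k < n and days[k] == day:
            if stock > cap:
                stock = cap
            stock += supplies[k]
            k += 1
        if stock > 0:
            covered[day] = True
            stock -= 1
    return covered


def daily_coverage_oracle(days, supplies, horizon, cap=100):
    """Boolean covered-day array over [0, horizon) from (day, supply) events.

    Events must carry non-negative day offsets; sorted internally.
    """
    days = np.asarray(days, dtype=np.int64)
    supplies = np.asarray(supplies, dtype=np.int64)
    order = np.argsort(days, kind="stable")
    return _stock_sim(days[order], supplies[order], horizon, cap)


def odd_oracle(claims, discharges, pair_window=730, before=120, after=180):
    """Exhaustive administrative diabetes rule on one patient's records.

    ``claims``: list of (day, code); ``discharges``: list of
    (day, code, pregnancy_flag).  Returns (positive, index_day or None).
    """
    preg = [d for d, _, flag in discharges if flag]

    def excluded(day):
        return any(g - before <= day <= g + after for g in preg)

    dia_claims = sorted(d for d, code in claims if str(code).startswith("250") and not excluded(d))
    dia_disch = sorted(
        d for d, code, flag in discharges
        if str(code).startswith("250") and not flag and not excluded(d)
    )
    best = None
    if dia_disch:
        best = dia_disch[0]
    for i in range(len(dia_claims)):
        for j in range(i + 1, len(dia_claims)):
            if dia_claims[j] - dia_claims[i] <= pair_window:
                if best is None or dia_claims[j] < best:
                    best = dia_claims[j]
    return (best is not None), best


def normal_equations_fit(t, y, t0):
    """Closed-form least squares for the segmented design via solve()."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    post = (t >= t0).astype(float)
    X = np.column_stack([np.ones_like(t), t, post, (t - t0) * post])
    return np.linalg.solve(X.T @ X, X.T @ y)


def random_dispensing_sequence(rng, max_events=12, horizon_days=7 * 365):
    """Random sequence for stress tests: 0..max_events events, supplies 1-100."""
    k = int(rng.integers(0, max_events + 1))
    days = rng.integers(0, horizon_days - 1, size=k)
    supplies = rng.integers(1, 101, size=k)
    return days, supplies
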