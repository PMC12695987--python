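"""Independent reference implementations used as test oracles.

These deliberately re-derive results with naive, hand-checkable logic
(plain loops, grid search, closed forms) and never call the package's
own code paths for the quantity under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm


# --- brute-force measure extraction -----------------------------------------


def reference_measured_rows(log):
    """Naive re-derivation of (item, building session) measure rows.

    Works directly off the raw event list of a marker-bearing TrialLog:
    pairs session markers in order, collects view intervals and
    placements by scanning, then applies the measure definitions row by
    row.  Returns tuples (building_session_index, item, viewing_time,
    delay, placed, n_views, last_view_session).
    """
    markers = [e for e in log.events if e.kind in ("session_start", "session_end")]
    sessions = []
    for start, end in zip(markers[0::2], markers[1::2]):
        assert start.kind == "session_start" and end.kind == "session_end"
        assert start.item_id == end.item_id
        sessions.append((start.item_id, start.time_s, end.time_s))

    views = []  # (item, start, end)
    open_start = {}
    for e in log.events:
        if e.kind == "view_start":
            open_start[e.item_id] = e.time_s
        elif e.kind == "view_end":
            views.append((e.item_id, open_start.pop(e.item_id), e.time_s))
    places = [(e.item_id, e.time_s) for e in log.events if e.kind == "place"]

    viewing_sessions = [s for s in sessions if s[0] == "viewing"]

    def session_of_view(start, end):
        for i, (_, s0, s1) in enumerate(viewing_sessions, start=1):
            if s0 <= start and end <= s1:
                return i
        raise AssertionError("view outside viewing sessions")

    rows = []
    b_idx = 0
    already_placed = set()
    for kind, s0, s1 in sessions:
        if kind != "building":
            continue
        b_idx += 1
        in_session = {it: t for it, t in places if s0 <= t <= s1}
        items = sorted(
            {
                it
                for it, vs, ve in views
                if ve <= s0 and it not in already_placed and it in {v[0] for v in views}
            }
        )
        for item in items:
            if item in in_session:
                cutoff, placed = in_session[item], True
                end_time = in_session[item]
            else:
                cutoff, placed = s0, False
                end_time = s1
            counted = [(vs, ve) for it, vs, ve in views if it == item and ve <= cutoff]
            if not counted:
                continue
            vt = sum(ve - vs for vs, ve in counted)
            last_end = max(ve for _, ve in counted)
            last_sess = max(session_of_view(vs, ve) for vs, ve in counted)
            rows.append(
                (b_idx, item, vt, end_time - last_end, placed, len(counted), last_sess)
            )
        already_placed |= set(in_session)
    return rows


# --- grid-search logistic MLE ------------------------------------------------


def grid_search_logistic(x: np.ndarray, y: np.ndarray, span=8.0, tol=1e-5):
    """Maximize the Bernoulli log-likelihood of logit(p) = b0 + b1 x by
    recursive grid refinement over (b0, b1)."""

    def nll(b0, b1):
        eta = b0 + b1 * x
        # log(1 + e^eta) stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    lo0, hi0, lo1, hi1 = -span, span, -span, span
    best = (0.0, 0.0)
    while (hi0 - lo0) > tol:
        g0 = np.linspace(lo0, hi0, 21)
        g1 = np.linspace(lo1, hi1, 21)
        vals = [(nll(b0, b1), b0, b1) for b0 in g0 for b1 in g1]
        _, b0, b1 = min(vals)
        best = (b0, b1)
        w0 = (hi0 - lo0) / 10
        w1 = (hi1 - lo1) / 10
        lo0, hi0 = b0 - w0, b0 + w0
        lo1, hi1 = b1 - w1, b1 + w1
    return best


# --- closed-form free-report success probability -----------------------------


def analytic_placement_probability(v, d, tau_e, tau_d, ceiling, theta, sd, guess):
    """Phi((c - theta)/sd) * max(c, guess) with c the decayed certainty."""
    c = ceiling * (1.0 - math.exp(-v / tau_e)) * math.exp(-d / tau_d)
    if theta <= 0:
        p_act = 1.0
    elif sd == 0:
        p_act = 1.0 if c >= theta else 0.0
    else:
        p_act = norm.cdf((c - theta) / sd)
    return p_act * max(c, guess)


# --- random legal copying-task logs ------------------------------------------


def random_legal_log(rng: np.random.Generator, with_markers: bool = True):
    """Sample a small legal trial log (a dozen or so view/place events)."""
    from vwmdyn import Event, TrialLog

    items = ["A", "B", "C", "D", "E"]
    t = round(float(rng.uniform(0, 5)), 3)
    events = []
    viewed, placed = set(), set()
    n_cycles = int(rng.integers(1, 3))
    for _ in range(n_cycles):
        n_views = int(rng.integers(1, 4))
        v_start = None
        for _ in range(n_views):
            item = items[int(rng.integers(len(items)))]
            if item in placed:
                continue
            t += round(float(rng.uniform(0.1, 0.6)), 3)
            start = t
            t += round(float(rng.uniform(0.2, 1.5)), 3)
            if v_start is None:
                v_start = start
            events.append(Event("view_start", item, start))
            events.append(Event("view_end", item, t))
            viewed.add(item)
        if v_start is None:
            continue
        v_end = t
        if with_markers:
            events.append(Event("session_start", "viewing", v_start))
            events.append(Event("session_end", "viewing", v_end))
        candidates = sorted(viewed - placed)
        chosen = [it for it in candidates if rng.random() < 0.6]
        b_end = v_end
        place_events = []
        for item in chosen:
            b_end += round(float(rng.uniform(0.5, 2.0)), 3)
            place_events.append(Event("place", item, b_end))
            placed.add(item)
        b_end += round(float(rng.uniform(0.1, 1.0)), 3)
        if with_markers:
            events.append(Event("session_start", "building", v_end))
            events.extend(place_events)
            events.append(Event("session_end", "building", b_end))
            t = b_end
        elif place_events:
            events.extend(place_events)
            t = b_end
    events.sort(key=lambda e: (e.time_s, _ORDER[e.kind]))
    return TrialLog("px", 1, events)


_ORDER = {
    "view_end": 0,
    "place": 1,
    "session_end": 2,
    "session_start": 3,
    "view_start": 4,
}
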