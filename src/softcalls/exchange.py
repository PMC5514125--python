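"""Answer scoring, response tables, habituation bins and repeatability.

An *answer* is a vocalization whose onset falls within a fixed window
after a trigger onset: 0.5 s for counting answers (baseline exchanges
and answer-type composition), 1.5 s for the first-answer latency
analysis.  All timing is onset-to-onset.  A responder event answers at
most one trigger — the nearest preceding one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ANSWER_WINDOW_S = 0.5
LATENCY_WINDOW_S = 1.5

SERIES_COLUMNS = ["subject_id", "trial", "call_type", "familiarity", "audience_id", "playback_order", "n_answers"]

__all__ = [
    "ANSWER_WINDOW_S",
    "LATENCY_WINDOW_S",
    "SERIES_COLUMNS",
    "detect_answers",
    "first_answer_latency",
    "first_answer_latencies",
    "build_series_responses",
    "answer_type_proportions",
    "bin_call_counts",
    "exchange_summary",
    "RepeatabilityResult",
    "repeatability_index",
]


def _onsets(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        return events["onset_s"].to_numpy(dtype=np.float64)
    return np.asarray(events, dtype=np.float64)


def detect_answers(trigger_events, responder_events, window_s: float = ANSWER_WINDOW_S) -> pd.DataFrame:
    """Match responder events to the triggers they answer.

    A responder onset in ``(t, t + window_s]`` after trigger onset ``t``
    answers its nearest preceding trigger.  Both streams must be
    time-sorted.  Returns one row per answer: ``trigger_idx,
    responder_idx, trigger_s, responder_s, latency_s`` (plus
    ``call_type`` of the responder when available).
    """
    trig = _onsets(trigger_events)
    resp = _onsets(responder_events)
    for name, arr in (("trigger", trig), ("responder", resp)):
        if np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} events must be time-sorted")
    if len(trig) == 0 or len(resp) == 0:
        cols = ["trigger_idx", "responder_idx", "trigger_s", "responder_s", "latency_s"]
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    idx = np.searchsorted(trig, resp, side="left") - 1
    ok = idx >= 0
    lat = np.full(len(resp), np.nan)
    lat[ok] = resp[ok] - trig[idx[ok]]
    hit = ok & (lat > 0) & (lat <= window_s)
    out = pd.DataFrame(
        {
            "trigger_idx": idx[hit],
            "responder_idx": np.flatnonzero(hit),
            "trigger_s": trig[idx[hit]],
            "responder_s": resp[hit],
            "latency_s": lat[hit],
        }
    )
    if isinstance(responder_events, pd.DataFrame) and "call_type" in responder_events.columns:
        out["call_type"] = responder_events["call_type"].to_numpy()[out["responder_idx"].to_numpy()]
    return out


def first_answer_latency(emission_s: float, responder_events, window_s: float = LATENCY_WINDOW_S) -> float | None:
    """Latency of the earliest responder onset in ``(0, window_s]`` after
    the emission, or None when there is no answer in the window."""
    resp = _onsets(responder_events)
    i = np.searchsorted(resp, emission_s, side="right")
    if i == len(resp):
        return None
    lat = resp[i] - emission_s
    while lat == 0:  # onset ties: strictly after the emission
        i += 1
        if i == len(resp):
            return None
        lat = resp[i] - emission_s
    return float(lat) if lat <= window_s else None


def first_answer_latencies(emissions_s, responder_events, window_s: float = LATENCY_WINDOW_S) -> np.ndarray:
    """Vectorized :func:`first_answer_latency`; NaN where unanswered."""
    em = np.asarray(emissions_s, dtype=np.float64)
    resp = _onsets(responder_events)
    out = np.full(len(em), np.nan)
    if len(resp) == 0:
        return out
    i = np.searchsorted(resp, em, side="right")
    ok = i < len(resp)
    lat = np.where(ok, resp[np.minimum(i, len(resp) - 1)] - em, np.nan)
    good = ok & (lat > 0) & (lat <= window_s)
    out[good] = lat[good]
    return out


def build_series_responses(
    schedule,
    responder_events,
    subject_id: str,
    trial: str,
    audience_id: str,
    answer_window_s: float = ANSWER_WINDOW_S,
    latency_window_s: float = LATENCY_WINDOW_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score one trial: per-series answer counts and first-answer latencies.

    Returns ``(series, latencies)``: ``series`` has one row per playback
    series (columns :data:`SERIES_COLUMNS`); ``latencies`` is long
    format with one row per answered emission.  Events with onset
    before the trial start are excluded with a warning (clock
    mismatch).
    """
    emissions = schedule.emissions if hasattr(schedule, "emissions") else schedule
    resp = responder_events
    t0 = float(emissions["emission_s"].min())
    onsets = _onsets(resp)
    before = onsets < min(0.0, t0)
    if before.any():
        warnings.warn(
            f"{int(before.sum())} responder events precede the trial start; excluded (clock mismatch?)"
        )
        if isinstance(resp, pd.DataFrame):
            resp = resp.loc[~before].reset_index(drop=True)
        else:
            resp = onsets[~before]

    answers = detect_answers(emissions["emission_s"].to_numpy(), resp, window_s=answer_window_s)
    em_series = emissions[["block_idx", "series_idx"]].to_numpy()
    series_rows = []
    lat_rows = []
    order = 0
    g = emissions.groupby(["block_idx", "series_idx"], sort=False)
    for (b, s), grp in sorted(g, key=lambda kv: kv[1]["emission_s"].min()):
        order += 1
        ct = grp["call_type"].iloc[0]
        fam = grp["familiarity"].iloc[0]
        mask = (em_series[answers["trigger_idx"].to_numpy(dtype=int), 0] == b) & (
            em_series[answers["trigger_idx"].to_numpy(dtype=int), 1] == s
        ) if len(answers) else np.array([], dtype=bool)
        n_ans = int(mask.sum())
        lats = first_answer_latencies(grp["emission_s"].to_numpy(), resp, window_s=latency_window_s)
        series_rows.append((subject_id, trial, ct, fam, audience_id, order, n_ans))
        for k, lat in enumerate(lats):
            if np.isfinite(lat):
                lat_rows.append((subject_id, trial, ct, fam, audience_id, order, k, float(lat)))
    series = pd.DataFrame(series_rows, columns=SERIES_COLUMNS)
    latencies = pd.DataFrame(
        lat_rows, columns=SERIES_COLUMNS[:6] + ["emission_idx", "latency_s"]
    )
    return series, latencies


def answer_type_proportions(answers: pd.DataFrame, min_answers: int = 5) -> dict[str, float] | None:
    """Composition of answer call types for one playback series.

    Returns None (series excluded) when there are fewer than
    ``min_answers`` answers; otherwise proportions over answer call
    types, summing to 1.
    """
    if len(answers) < min_answers:
        return None
    counts = answers["call_type"].value_counts()
    total = counts.sum()
    return {ct: float(c) / total for ct, c in counts.items()}


def bin_call_counts(events, bin_s: float = 500.0, span_s: float | None = None) -> np.ndarray:
    """Counts of events in half-open bins ``[k*bin_s, (k+1)*bin_s)``.

    ``span_s`` defaults to the last event time; events outside
    ``[0, span)`` where span is the bin-aligned ceiling are dropped.
    """
    onsets = _onsets(events)
    if span_s is None:
        span_s = float(onsets.max()) if len(onsets) else bin_s
    if span_s <= 0:
        raise ValueError("span must be positive")
    n_bins = int(np.ceil(span_s / bin_s))
    idx = np.floor(onsets / bin_s).astype(int)
    ok = (onsets >= 0) & (idx < n_bins)
    return np.bincount(idx[ok], minlength=n_bins)


def exchange_summary(
    caller_events: pd.DataFrame,
    responder_events: pd.DataFrame,
    window_s: float = ANSWER_WINDOW_S,
) -> pd.DataFrame:
    """Baseline answer table per (caller call type -> responder call type).

    For each combination: the number of answers and the proportion of
    the caller's calls of that type that received an answer of that
    type.  ``n_caller_calls`` supports the >= 3 calls screening used
    before repeatability analysis.
    """
    rows = []
    for ct, grp in caller_events.groupby("call_type"):
        n_calls = len(grp)
        answers = detect_answers(grp.sort_values("onset_s"), responder_events, window_s=window_s)
        if len(answers) == 0:
            continue
        # one answer per trigger: keep the earliest answer of each trigger
        answers = answers.sort_values("latency_s").drop_duplicates("trigger_idx")
        for rt, agrp in answers.groupby("call_type"):
            rows.append((ct, rt, n_calls, len(agrp), len(agrp) / n_calls))
    return pd.DataFrame(
        rows, columns=["caller_type", "responder_type", "n_caller_calls", "n_answers", "proportion"]
    )


@dataclass(frozen=True)
class RepeatabilityResult:
    r: float  # intraclass repeatability, clamped to [0, 1]
    f_ratio: float  # MS among / MS within
    ms_among: float
    ms_within: float
    n0: float  # effective group size
    n_groups: int


def repeatability_index(values, groups) -> RepeatabilityResult:
    """Repeatability of a measure from a one-way ANOVA over groups.

    ``r = (MSA - MSW) / (MSA + (n0 - 1) * MSW)`` — the intraclass
    correlation of Lessells & Boag, clamped to [0, 1] — with the raw
    F ratio ``MSA / MSW`` reported alongside.  ``n0`` is the effective
    per-group sample size correcting for unequal group sizes.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    N = len(values)
    grand = values.mean()
    if np.all(values == values[0]):
        raise ValueError("degenerate: all values identical")
    ss_among = 0.0
    ss_within = 0.0
    sizes = []
    for g in uniq:
        v = values[groups == g]
        sizes.append(len(v))
        ss_among += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    a = len(uniq)
    sizes = np.asarray(sizes, dtype=float)
    df_among = a - 1
    df_within = N - a
    if df_within == 0:
        raise ValueError("need replicate values within groups")
    msa = ss_among / df_among
    msw = ss_within / df_within
    n0 = (N - (sizes**2).sum() / N) / (a - 1)
    f_ratio = np.inf if msw == 0 else msa / msw
    if msw == 0:
        r = 1.0
    else:
        r = (msa - msw) / (msa + (n0 - 1) * msw)
    return RepeatabilityResult(
        r=float(np.clip(r, 0.0, 1.0)),
        f_ratio=float(f_ratio),
        ms_among=float(msa),
        ms_within=float(msw),
        n0=float(n0),
        n_groups=a,
    )
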