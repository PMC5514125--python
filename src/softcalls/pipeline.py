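"""End-to-end orchestration: simulate, score and assemble model tables.

These helpers wire the synthetic generator, the playback schedule and
the answer scoring together so that a whole playback experiment — or a
reduced version for simulation studies — is one call.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import split_rng
from .exchange import build_series_responses
from .playback import build_schedule, default_exemplars
from .synth import BirdProfile, ExchangeModel, SimConfig, generate_playback_responses

__all__ = ["simulate_trial", "simulate_experiment", "subset_emissions", "response_magnitudes"]


def simulate_trial(
    sex: str,
    model: ExchangeModel,
    seed: int,
    subject_id: str = "focal",
    trial: str = "A",
    audience_id: str = "aud0",
    subject: BirdProfile | None = None,
    schedule_kwargs: Mapping | None = None,
) -> dict:
    """Build a schedule, simulate the focal bird, score the trial.

    Returns ``{"schedule", "responses", "series", "latencies"}``.
    ``schedule_kwargs`` is forwarded to :func:`build_schedule` (e.g.
    ``emissions_per_exemplar`` for reduced designs).
    """
    kwargs = dict(schedule_kwargs or {})
    sched_seed = int(split_rng(seed, "pipeline", "schedule", subject_id, trial).integers(2**31))
    schedule = build_schedule(sex, default_exemplars(sex), seed=sched_seed, **kwargs)
    resp_seed = int(split_rng(seed, "pipeline", "responses", subject_id, trial).integers(2**31))
    responses = generate_playback_responses(schedule, model, seed=resp_seed, subject=subject)
    if subject is None and len(responses):
        responses = responses.assign(bird_id=subject_id)
    series, latencies = build_series_responses(
        schedule, responses, subject_id=subject_id, trial=trial, audience_id=audience_id
    )
    return {"schedule": schedule, "responses": responses, "series": series, "latencies": latencies}


def simulate_experiment(
    model: ExchangeModel,
    config: SimConfig,
    sexes: Mapping[str, str] | None = None,
    n_audiences: int = 7,
    schedule_kwargs: Mapping | None = None,
) -> dict:
    """Simulate all subjects and trials of a playback experiment.

    ``sexes`` maps subject_id -> sex; by default ``config.n_pairs``
    males and females are simulated.  Audience identities rotate over
    ``n_audiences`` and change between trials, as in the original
    design.  Returns concatenated ``series`` and ``latencies`` tables.
    """
    if sexes is None:
        sexes = {}
        for i in range(config.n_pairs):
            sexes[f"M{i}"] = "M"
            sexes[f"F{i}"] = "F"
    series_all, lat_all = [], []
    for si, (subject_id, sex) in enumerate(sexes.items()):
        for ti, trial in enumerate(config.trials):
            audience = f"aud{(si + ti) % n_audiences}"
            out = simulate_trial(
                sex,
                model,
                seed=config.seed,
                subject_id=subject_id,
                trial=trial,
                audience_id=audience,
                schedule_kwargs=schedule_kwargs,
            )
            series_all.append(out["series"])
            lat_all.append(out["latencies"])
    return {
        "series": pd.concat(series_all, ignore_index=True),
        "latencies": pd.concat(lat_all, ignore_index=True),
    }


def subset_emissions(emissions: pd.DataFrame, n: int, which: str = "first") -> pd.DataFrame:
    """Restrict each playback series to its first or last ``n`` emissions.

    Series shorter than ``n`` are kept whole with a warning.
    """
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    short = [
        key
        for key, grp in emissions.groupby(["block_idx", "series_idx"])
        if len(grp) < n
    ]
    if short:
        warnings.warn(f"{len(short)} series shorter than {n} emissions; using all of them")
    picker = (lambda g: g.head(n)) if which == "first" else (lambda g: g.tail(n))
    out = (
        emissions.sort_values("emission_s")
        .groupby(["block_idx", "series_idx"], group_keys=False, sort=False)[emissions.columns]
        .apply(picker)
    )
    return out.reset_index(drop=True)


def response_magnitudes(series: pd.DataFrame, latencies: pd.DataFrame) -> pd.DataFrame:
    """Response magnitude per (subject, call type, contrast).

    For each contrast in {mate-familiar, mate-unfamiliar}:
    ``delta_count`` = mate answer count minus the other level's count,
    and ``delta_latency`` = the difference of per-subject mean
    first-answer latencies (latencies averaged within subject before
    differencing).  Counts/latencies are first averaged over trials.
    """
    cnt = series.groupby(["subject_id", "call_type", "familiarity"])["n_answers"].mean()
    lat = latencies.groupby(["subject_id", "call_type", "familiarity"])["latency_s"].mean()
    rows = []
    for (subj, ct), _ in series.groupby(["subject_id", "call_type"]):
        for other in ("f", "uf"):
            try:
                dc = cnt.loc[(subj, ct, "m")] - cnt.loc[(subj, ct, other)]
            except KeyError:
                continue
            dl = np.nan
            try:
                dl = lat.loc[(subj, ct, "m")] - lat.loc[(subj, ct, other)]
            except KeyError:
                pass
            rows.append(
                {
                    "subject_id": subj,
                    "call_type": ct,
                    "contrast": f"m-{other}",
                    "delta_count": float(dc),
                    "delta_latency": float(dl),
                }
            )
    return pd.DataFrame(rows)
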