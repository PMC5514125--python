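"""Synthetic birds, call exchanges and playback responses.

This module manufactures ground-truthed stand-ins for the three data
streams of a paired-playback recognition experiment:

* call waveforms — a harmonic stack at a bird- and type-specific
  fundamental with geometric harmonic roll-off plus white noise, so the
  spectral feature extractors have closed-form expectations;
* baseline pair exchanges — each bird calls as a homogeneous Poisson
  process and its mate answers with a configurable probability after a
  truncated-normal lag;
* playback responses — the focal bird answers each stimulus emission
  with familiarity-dependent probability and latency.

The truncated-normal latency distribution is parameterized by its
*realized* mean: the underlying location is solved numerically so that
the mean of the truncated draw equals ``answer_latency_mean`` exactly.
Planted effects are therefore recovered without truncation bias.

All randomness is split per operation from a single seed (see
:mod:`softcalls._rng`), so regenerating one stream never shifts another.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ._rng import split_rng
from .acoustics import VocalSegment
from .io import EVENT_COLUMNS

FAMILIARITY_LEVELS = ("m", "f", "uf")  # mate, familiar, unfamiliar

#: call-type roster; the soft calls plus the distance call are shared,
#: song is produced by males only (and therefore played back to females)
FEMALE_CALL_TYPES = ("tet", "stack", "distance", "kackle", "hat")
MALE_CALL_TYPES = FEMALE_CALL_TYPES + ("song",)

#: species-typical base fundamentals (Hz) and durations (s) per type
BASE_FUNDAMENTAL_HZ = {
    "tet": 500.0,
    "stack": 600.0,
    "distance": 700.0,
    "kackle": 800.0,
    "hat": 900.0,
    "song": 650.0,
}
BASE_DURATION_S = {
    "tet": 0.06,
    "stack": 0.09,
    "distance": 0.13,
    "kackle": 0.10,
    "hat": 0.07,
    "song": 0.30,
}

__all__ = [
    "FAMILIARITY_LEVELS",
    "FEMALE_CALL_TYPES",
    "MALE_CALL_TYPES",
    "CallTimbre",
    "BirdProfile",
    "ExchangeModel",
    "SimConfig",
    "make_bird_profiles",
    "generate_call_waveform",
    "generate_exchange_session",
    "generate_playback_responses",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class CallTimbre:
    """Acoustic parameters of one call type for one bird."""

    fundamental_hz: float
    n_harmonics: int = 5
    duration_s: float = 0.1
    noise_floor: float = 0.05  # additive white-noise amplitude, relative
    #: relative linear sweep of the fundamental over the call: the
    #: instantaneous f0 runs from f0*(1 - glide/2) to f0*(1 + glide/2)
    fm_glide: float = 0.0

    def __post_init__(self) -> None:
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 <= self.noise_floor < 1:
            raise ValueError("noise_floor must lie in [0, 1)")


@dataclass(frozen=True)
class BirdProfile:
    bird_id: str
    sex: str  # "M" or "F"
    calls: Mapping[str, CallTimbre]

    def timbre(self, call_type: str) -> CallTimbre:
        try:
            return self.calls[call_type]
        except KeyError:
            raise KeyError(
                f"unknown call type {call_type!r} for bird {self.bird_id}; "
                f"repertoire: {sorted(self.calls)}"
            ) from None


def make_bird_profiles(
    n_pairs: int = 6,
    seed: int = 0,
    f0_spread_hz: float = 120.0,
    n_harmonics: int = 5,
    noise_floor: float = 0.05,
) -> list[tuple[BirdProfile, BirdProfile]]:
    """Create ``n_pairs`` (male, female) profiles with distinct voices.

    Each bird receives one individual fundamental offset, shared across
    its call types; offsets are evenly spaced over ``±f0_spread_hz/2``
    and randomly permuted, so they are distinct by construction.
    """
    rng = split_rng(seed, "synth", "profiles")
    n_birds = 2 * n_pairs
    offsets = np.linspace(-f0_spread_hz / 2, f0_spread_hz / 2, n_birds)
    offsets = rng.permutation(offsets)
    pairs = []
    for i in range(n_pairs):
        birds = []
        for j, (sex, types) in enumerate((("M", MALE_CALL_TYPES), ("F", FEMALE_CALL_TYPES))):
            off = offsets[2 * i + j]
            calls = {
                ct: CallTimbre(
                    fundamental_hz=BASE_FUNDAMENTAL_HZ[ct] + off,
                    n_harmonics=n_harmonics,
                    duration_s=BASE_DURATION_S[ct],
                    noise_floor=noise_floor,
                )
                for ct in types
            }
            birds.append(BirdProfile(bird_id=f"{sex}{i}", sex=sex, calls=calls))
        pairs.append((birds[0], birds[1]))
    return pairs


@dataclass
class ExchangeModel:
    """Answering behaviour: who answers what, how often and how fast.

    ``answer_prob`` may be a single float or a mapping whose keys are,
    from most to least specific, ``(caller_type, responder_type,
    familiarity)``, ``(caller_type, familiarity)``, ``familiarity`` or
    ``"default"``; the most specific matching key wins.

    ``answer_latency_mean`` gives, per familiarity level, the realized
    mean (s) of the truncated-normal latency distribution on
    ``latency_bounds``; ``subject_latency_sd`` adds a per-subject
    offset to that mean, modelling stable individual response speed.
    """

    base_call_rate: float = 0.02  # spontaneous events/s per bird per call type
    answer_prob: float | Mapping = field(
        default_factory=lambda: {"m": 0.60, "f": 0.45, "uf": 0.45}
    )
    answer_latency_mean: Mapping[str, float] = field(
        default_factory=lambda: {"m": 0.55, "f": 0.67, "uf": 0.67}
    )
    answer_latency_sd: float = 0.25
    latency_bounds: tuple[float, float] = (0.0, 1.5)
    subject_latency_sd: float = 0.03
    response_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"stack": 0.60, "distance": 0.20, "hat": 0.10, "tet": 0.07, "kackle": 0.03}
    )

    def __post_init__(self) -> None:
        lo, hi = self.latency_bounds
        if not 0 <= lo < hi:
            raise ValueError("latency_bounds must satisfy 0 <= lo < hi")
        probs = [self.answer_prob] if isinstance(self.answer_prob, (int, float)) else list(
            dict(self.answer_prob).values()
        )
        for p in probs:
            if not 0 <= p <= 1:
                raise ValueError(f"answer probability {p} outside [0, 1]")
        for fam, m in dict(self.answer_latency_mean).items():
            if not lo < m < hi:
                raise ValueError(f"latency mean {m} for {fam!r} outside truncation bounds")

    def get_answer_prob(
        self,
        familiarity: str,
        caller_type: str | None = None,
        responder_type: str | None = None,
    ) -> float:
        if isinstance(self.answer_prob, (int, float)):
            return float(self.answer_prob)
        table = self.answer_prob
        for key in (
            (caller_type, responder_type, familiarity),
            (caller_type, familiarity),
            familiarity,
            "default",
        ):
            if key in table:
                return float(table[key])
        return 0.0


@dataclass(frozen=True)
class SimConfig:
    """Global simulation settings; the same config reproduces the same data."""

    seed: int
    n_pairs: int = 6
    session_duration_s: float = 14400.0  # 4 h scored per baseline day
    sample_rate: int = 44100
    trials: tuple[str, ...] = ("A", "B")


@functools.lru_cache(maxsize=4096)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location ``mu`` such that TruncNormal(mu, sd, lo, hi) has mean
    ``target_mean``; solved by bisection (the mean is monotone in mu)."""

    def realized(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(truncnorm.mean(a, b, loc=mu, scale=sd))

    span = 10 * sd
    return brentq(lambda mu: realized(mu) - target_mean, lo - span, hi + span, xtol=1e-10)


def _draw_latencies(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    lo, hi = bounds
    margin = 0.05 * (hi - lo)
    mean = float(np.clip(mean, lo + margin, hi - margin))
    if sd <= 0:  # degenerate: every latency exactly at the mean
        return np.full(n, mean)
    mu = _truncnorm_loc(round(mean, 9), round(sd, 9), lo, hi)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def _pick_types(rng: np.random.Generator, weights: Mapping[str, float], repertoire, n: int) -> np.ndarray:
    types = [t for t in weights if t in repertoire]
    if not types:
        types = list(repertoire)
        w = np.ones(len(types))
    else:
        w = np.array([weights[t] for t in types], dtype=np.float64)
    w = w / w.sum()
    return rng.choice(types, size=n, p=w)


def generate_call_waveform(
    profile: BirdProfile,
    call_type: str,
    seed: int,
    sample_rate: int = 44100,
    rolloff: float = 0.5,
) -> VocalSegment:
    """Synthesize one call: harmonic stack plus white noise.

    Harmonic ``h`` has amplitude ``rolloff**(h-1)`` and a random phase;
    the fundamental sweeps linearly by ``fm_glide`` across the call;
    white noise is added at the profile's ``noise_floor`` relative to
    the unit-peak harmonic part; 2.5 ms raised-cosine fades remove edge
    clicks and the result is scaled to peak 0.9 (so peak <= 1 always).
    """
    timbre = profile.timbre(call_type)
    rng = split_rng(seed, "synth", "waveform", profile.bird_id, call_type)
    n = int(round(timbre.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    frac = t / timbre.duration_s  # 0 .. 1 across the call
    f_inst = timbre.fundamental_hz * (1 + timbre.fm_glide * (frac - 0.5))
    phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
    y = np.zeros(n)
    for h in range(1, timbre.n_harmonics + 1):
        if h * f_inst.max() >= sample_rate / 2:
            break
        y += rolloff ** (h - 1) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    peak = np.abs(y).max()
    if peak > 0:
        y /= peak
    if timbre.noise_floor > 0:
        y = y + timbre.noise_floor * rng.standard_normal(n)
    n_fade = min(n // 2, int(round(0.0025 * sample_rate)))
    if n_fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        y[:n_fade] *= ramp
        y[-n_fade:] *= ramp[::-1]
    y *= 0.9 / np.abs(y).max()
    return VocalSegment(samples=y, sample_rate=sample_rate, onset_s=0.0, offset_s=n / sample_rate)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="float64" if c.endswith("_s") else "object") for c in EVENT_COLUMNS})


def _events_frame(rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return _empty_events()
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


def generate_exchange_session(
    pair: tuple[BirdProfile, BirdProfile],
    model: ExchangeModel,
    config: SimConfig,
    day: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one baseline recording day for a mated pair.

    Each bird emits spontaneous calls of every type in its repertoire
    as a homogeneous Poisson process at ``base_call_rate``; after each
    spontaneous call the partner answers with the mate-level
    probability at a truncated-normal lag.  Answers do not trigger
    further answers.  Returns the two time-sorted event streams.
    """
    if config.session_duration_s <= 0:
        raise ValueError("session_duration_s must be positive")
    T = config.session_duration_s
    rng = split_rng(config.seed, "synth", "exchange", pair[0].bird_id, pair[1].bird_id, day)
    spont: list[list[tuple]] = [[], []]
    for i, bird in enumerate(pair):
        for ct in bird.calls:
            n = rng.poisson(model.base_call_rate * T)
            onsets = np.sort(rng.uniform(0, T, size=n))
            dur = bird.timbre(ct).duration_s
            spont[i].extend((bird.bird_id, ct, float(o), float(o + dur)) for o in onsets)
    streams: list[list[tuple]] = [sorted(s, key=lambda r: r[2]) for s in spont]
    answers: list[list[tuple]] = [[], []]
    for i, caller in enumerate(pair):
        j = 1 - i
        responder = pair[j]
        for _, ct, onset, _ in streams[i]:
            rt = _pick_types(rng, model.response_type_weights, responder.calls, 1)[0]
            p = model.get_answer_prob("m", caller_type=ct, responder_type=rt)
            if rng.uniform() >= p:
                continue
            lat = _draw_latencies(rng, 1, model.answer_latency_mean["m"], model.answer_latency_sd, model.latency_bounds)[0]
            t0 = onset + lat
            if t0 >= T:
                continue
            answers[j].append((responder.bird_id, rt, float(t0), float(t0 + responder.timbre(rt).duration_s)))
    out = []
    for i in range(2):
        out.append(_events_frame(streams[i] + answers[i]))
    return out[0], out[1]


def generate_playback_responses(
    schedule,
    model: ExchangeModel,
    seed: int,
    subject: BirdProfile | None = None,
    subject_offset_s: float | None = None,
) -> pd.DataFrame:
    """Simulate the focal bird's answers to a playback schedule.

    Per emission, the bird answers with the familiarity-dependent
    probability; the latency is truncated-normal with realized mean
    ``answer_latency_mean[familiarity] + subject_offset`` and the
    answer's call type is drawn from ``response_type_weights``.  If
    ``subject_offset_s`` is None one offset is drawn from
    ``N(0, subject_latency_sd)`` for the whole schedule.
    """
    emissions = schedule.emissions if hasattr(schedule, "emissions") else schedule
    subject_id = subject.bird_id if subject is not None else "focal"
    rng = split_rng(seed, "synth", "playback", subject_id)
    if subject_offset_s is None:
        subject_offset_s = float(rng.normal(0, model.subject_latency_sd)) if model.subject_latency_sd > 0 else 0.0
    repertoire = subject.calls if subject is not None else dict(model.response_type_weights)
    group_cols = [c for c in ("block_idx", "series_idx") if c in emissions.columns] or ["familiarity"]
    rows: list[tuple] = []
    for _, grp in emissions.groupby(group_cols, sort=False):
        fam = grp["familiarity"].iloc[0]
        ct = grp["call_type"].iloc[0]
        p = model.get_answer_prob(str(fam), caller_type=ct)
        hit = rng.uniform(size=len(grp)) < p
        n_hit = int(hit.sum())
        if n_hit == 0:
            continue
        lats = _draw_latencies(
            rng, n_hit, model.answer_latency_mean[str(fam)] + subject_offset_s,
            model.answer_latency_sd, model.latency_bounds,
        )
        rts = _pick_types(rng, model.response_type_weights, repertoire, n_hit)
        onsets = grp.loc[hit, "emission_s"].to_numpy() + lats
        for t0, rt in zip(onsets, rts):
            dur = subject.timbre(rt).duration_s if subject is not None else 0.08
            rows.append((subject_id, rt, float(t0), float(t0 + dur)))
    return _events_frame(rows)


def save_config(path, config: SimConfig, model: ExchangeModel) -> None:
    """Serialize simulation settings to YAML (tuple keys joined by '/')."""

    def enc_map(m):
        if isinstance(m, (int, float)):
            return m
        return {("/".join(k) if isinstance(k, tuple) else k): v for k, v in dict(m).items()}

    doc = {
        "sim": {
            "seed": config.seed,
            "n_pairs": config.n_pairs,
            "session_duration_s": config.session_duration_s,
            "sample_rate": config.sample_rate,
            "trials": list(config.trials),
        },
        "exchange": {
            "base_call_rate": model.base_call_rate,
            "answer_prob": enc_map(model.answer_prob),
            "answer_latency_mean": dict(model.answer_latency_mean),
            "answer_latency_sd": model.answer_latency_sd,
            "latency_bounds": list(model.latency_bounds),
            "subject_latency_sd": model.subject_latency_sd,
            "response_type_weights": dict(model.response_type_weights),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[SimConfig, ExchangeModel]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sim = doc["sim"]
    exch = doc["exchange"]
    ap = exch["answer_prob"]
    if isinstance(ap, dict):
        ap = {(tuple(k.split("/")) if "/" in k else k): v for k, v in ap.items()}
    config = SimConfig(
        seed=int(sim["seed"]),
        n_pairs=int(sim["n_pairs"]),
        session_duration_s=float(sim["session_duration_s"]),
        sample_rate=int(sim["sample_rate"]),
        trials=tuple(sim["trials"]),
    )
    model = ExchangeModel(
        base_call_rate=float(exch["base_call_rate"]),
        answer_prob=ap,
        answer_latency_mean=exch["answer_latency_mean"],
        answer_latency_sd=float(exch["answer_latency_sd"]),
        latency_bounds=tuple(exch["latency_bounds"]),
        subject_latency_sd=float(exch["subject_latency_sd"]),
        response_type_weights=exch["response_type_weights"],
    )
    return config, model
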