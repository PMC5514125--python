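"""Playback schedule construction and stimulus preprocessing.

A trial presents one block per call type; each block holds three
series, one per familiarity level (mate / familiar / unfamiliar); each
series repeats 3 exemplar stimuli 100 times (300 emissions) with
uniformly jittered inter-call intervals of 2 +/- 0.5 s.  Series within a
block are separated by 70 +/- 10 s of silence, blocks by 130 +/- 10 s.
Male subjects hear the 5 female call types (15 series); female subjects
additionally hear song (18 series).

Block order, familiarity order within blocks and emission order within
series are uniform random permutations drawn from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from ._rng import split_rng
from .synth import FAMILIARITY_LEVELS, FEMALE_CALL_TYPES, MALE_CALL_TYPES

SCHEDULE_COLUMNS = ["emission_s", "block_idx", "series_idx", "call_type", "familiarity", "stimulus_id"]

#: call types played back to a subject of each sex (the opposite sex's voice)
PLAYBACK_TYPES = {"M": FEMALE_CALL_TYPES, "F": MALE_CALL_TYPES}

__all__ = [
    "SCHEDULE_COLUMNS",
    "PLAYBACK_TYPES",
    "PlaybackSchedule",
    "build_schedule",
    "default_exemplars",
    "preprocess_stimulus",
]


@dataclass
class PlaybackSchedule:
    """Timed stimulus emissions of one trial, plus design metadata."""

    sex: str
    seed: int
    emissions: pd.DataFrame  # SCHEDULE_COLUMNS, time-sorted
    gain_db: Mapping[str, float] | None = None  # per-call-type playback level, informational

    @property
    def n_series(self) -> int:
        return self.emissions.groupby(["block_idx", "series_idx"]).ngroups

    def series_table(self) -> pd.DataFrame:
        """One row per series: call type, familiarity, span, emission count."""
        g = self.emissions.groupby(["block_idx", "series_idx"], sort=True)
        rows = []
        for (b, s), grp in g:
            rows.append(
                {
                    "block_idx": b,
                    "series_idx": s,
                    "call_type": grp["call_type"].iloc[0],
                    "familiarity": grp["familiarity"].iloc[0],
                    "start_s": float(grp["emission_s"].min()),
                    "end_s": float(grp["emission_s"].max()),
                    "n_emissions": len(grp),
                }
            )
        out = pd.DataFrame(rows).sort_values("start_s").reset_index(drop=True)
        out["playback_order"] = np.arange(1, len(out) + 1)
        return out

    def to_csv(self, path) -> None:
        self.emissions.loc[:, SCHEDULE_COLUMNS].to_csv(path, index=False)

    def to_json(self, path) -> None:
        doc = {
            "sex": self.sex,
            "seed": self.seed,
            "gain_db": dict(self.gain_db) if self.gain_db else None,
            "emissions": self.emissions.loc[:, SCHEDULE_COLUMNS].to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "PlaybackSchedule":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            sex=doc["sex"],
            seed=doc["seed"],
            emissions=pd.DataFrame(doc["emissions"]),
            gain_db=doc.get("gain_db"),
        )


def default_exemplars(sex: str, callers: Mapping[str, str] | None = None) -> dict[tuple[str, str], list[str]]:
    """Synthetic exemplar map: 3 stimulus IDs per (call type, familiarity).

    ``callers`` optionally maps familiarity level to a caller ID used in
    the stimulus names (defaults to the level itself).
    """
    callers = callers or {fam: fam for fam in FAMILIARITY_LEVELS}
    return {
        (ct, fam): [f"{callers[fam]}_{ct}_{k}" for k in range(3)]
        for ct in PLAYBACK_TYPES[sex]
        for fam in FAMILIARITY_LEVELS
    }


def build_schedule(
    sex: str,
    exemplars: Mapping[tuple[str, str], Sequence[str]],
    seed: int,
    emissions_per_exemplar: int = 100,
    n_exemplars: int = 3,
    gap_s: tuple[float, float] = (1.5, 2.5),
    series_gap_s: tuple[float, float] = (60.0, 80.0),
    block_gap_s: tuple[float, float] = (120.0, 140.0),
    call_types: Sequence[str] | None = None,
    gain_db: Mapping[str, float] | None = None,
) -> PlaybackSchedule:
    """Build one trial's schedule for a subject of the given sex.

    Defaults reproduce the full design (3 exemplars x 100 repeats = 300
    emissions per series); the counts are parameters so reduced designs
    can be built for simulation studies.
    """
    if sex not in PLAYBACK_TYPES:
        raise ValueError("sex must be 'M' or 'F'")
    types = tuple(call_types) if call_types is not None else PLAYBACK_TYPES[sex]
    missing = []
    for ct in types:
        for fam in FAMILIARITY_LEVELS:
            ex = exemplars.get((ct, fam))
            if ex is None or len(ex) < n_exemplars:
                missing.append((ct, fam))
    if missing:
        raise ValueError(f"exemplar map incomplete; missing (call_type, familiarity): {missing}")

    rng = split_rng(seed, "playback", "schedule", sex)
    t = 0.0
    rows = []
    block_order = rng.permutation(len(types))
    for b_pos, b in enumerate(block_order):
        ct = types[b]
        if b_pos > 0:
            t += rng.uniform(*block_gap_s)
        fam_order = rng.permutation(len(FAMILIARITY_LEVELS))
        for s_pos, s in enumerate(fam_order):
            fam = FAMILIARITY_LEVELS[s]
            if s_pos > 0:
                t += rng.uniform(*series_gap_s)
            stim = np.repeat(np.asarray(exemplars[(ct, fam)][:n_exemplars], dtype=object), emissions_per_exemplar)
            stim = rng.permutation(stim)
            for k, sid in enumerate(stim):
                if k > 0:
                    t += rng.uniform(*gap_s)
                rows.append((t, int(b), int(s), ct, fam, str(sid)))
            t = rows[-1][0]
    emissions = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return PlaybackSchedule(sex=sex, seed=seed, emissions=emissions, gain_db=gain_db)


def preprocess_stimulus(
    wave: np.ndarray,
    sample_rate: int,
    highpass_hz: float = 85.0,
    ceiling_dbfs: float = -0.1,
    fade_s: float = 0.005,
) -> np.ndarray:
    """Prepare a stimulus: 85 Hz high-pass, fades, peak normalization.

    Raised-cosine fades of ``fade_s`` are applied before the zero-phase
    4th-order Butterworth high-pass (an abrupt onset would splatter
    energy across the band and ring at the edges) and re-applied after
    it, then the peak is scaled to ``10**(ceiling_dbfs/20)`` (default
    -0.1 dBFS).
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.size == 0 or np.all(wave == 0):
        raise ValueError("cannot normalize silence")

    def fade(y: np.ndarray) -> np.ndarray:
        n_fade = min(len(y) // 2, int(round(fade_s * sample_rate)))
        if n_fade > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
            y[:n_fade] *= ramp
            y[-n_fade:] *= ramp[::-1]
        return y

    sos = butter(4, highpass_hz, btype="highpass", fs=sample_rate, output="sos")
    y = fade(sosfiltfilt(sos, fade(wave.copy())))
    peak = np.abs(y).max()
    if peak == 0:
        raise ValueError("cannot normalize silence")
    return y * (10 ** (ceiling_dbfs / 20) / peak)
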