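"""Whole-corpus study: per-song MFDFA + surrogate tests, average-rhythm
contrast, and the paired statistics summarizing the contrast.

``run_study`` executes, per original song: pause zeroing, MFDFA, and the
IAAFT surrogate test; it then builds note/pause profiles from the whole
corpus, re-synthesizes each song's average-rhythm version, repeats the
analysis on those (with fresh surrogate ensembles), and compares the two
sets of SD-distances with a paired t-test. Because pause-duration
distributions can be skewed, the pause statistic can be the mean, the
median, or both (two full variants are then reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .envelope import SongRecord, zero_pauses
from .mfdfa import default_q_grid, default_scales
from .resynth import (build_note_profiles, build_pause_profiles,
                      collect_instances, synthesize_average_song)
from .surrogates import surrogate_test

__all__ = ["StudyConfig", "CorpusReport", "paired_t", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of a corpus study (q grid, scales, surrogate ensemble, seeds)."""

    q_min: float = 0.1
    q_max: float = 5.0
    q_step: float = 0.1
    n_scales: int = 19
    s_min: int = 10
    s_max_frac: float = 0.25
    n_surrogates: int = 100
    alpha: float = 0.05
    pause_stats: tuple[str, ...] = ("mean", "median")
    zero_pause: bool = True  # False reruns the robustness variant on raw envelopes
    seed: int = 0

    def q_grid(self) -> np.ndarray:
        return default_q_grid(self.q_min, self.q_max, self.q_step)

    def scales_for(self, n: int) -> np.ndarray:
        return default_scales(n, n_scales=self.n_scales, s_min=self.s_min,
                              s_max=int(n * self.s_max_frac))


@dataclass
class PairedTestSummary:
    t: float
    df: int
    p: float
    pause_statistic: str
    mean_difference: float


@dataclass
class CorpusReport:
    """Per-song widths/CIs/SD-distances plus the paired contrast tests."""

    per_song: pd.DataFrame
    paired: dict[str, PairedTestSummary]
    config: StudyConfig
    spectra: dict[str, object] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_song": self.per_song.to_dict(orient="records"),
            "paired": {k: vars(v) for k, v in self.paired.items()},
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
        }


def paired_t(d_orig, d_avg) -> dict:
    """Paired t-test between two per-song effect-size vectors.

    Returns {"t", "df", "p"} with df = n - 1 and a two-sided p. Raises on
    zero-variance differences (degenerate pairing).
    """
    a = np.asarray(d_orig, dtype=float)
    b = np.asarray(d_avg, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equally long")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate pairing: zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


def _song_seed(master: int, index: int, stream: int) -> int:
    # fixed, collision-free offsets below 2**31 for per-song sub-streams
    return (master * 1_000_003 + stream * 7919 + index) % (2**31 - 1)


def _analyse(songs: Iterable[SongRecord], cfg: StudyConfig, stream: int):
    qs = cfg.q_grid()
    rows = []
    for i, song in enumerate(songs):
        x = song.envelope.values
        scales = cfg.scales_for(x.size)
        res = surrogate_test(x, n=cfg.n_surrogates, alpha=cfg.alpha, qs=qs,
                             scales=scales, seed=_song_seed(cfg.seed, i, stream))
        rows.append({
            "song_id": song.envelope.song_id,
            "width": res.original_width,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "sd_distance": res.sd_distance,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)


def run_study(corpus: list[SongRecord], config: StudyConfig | None = None) -> CorpusReport:
    """Full average-rhythm study on an annotated corpus.

    Stages (per pause statistic in ``config.pause_stats``): zero pauses,
    per-song MFDFA + surrogate test; profile building; average-rhythm
    re-synthesis; the same analysis on the re-synthesized songs with
    fresh surrogate ensembles; paired t on the SD-distances.
    """
    cfg = config or StudyConfig()
    if not corpus:
        raise ValueError("empty corpus")
    try:
        cleaned = [zero_pauses(s) if cfg.zero_pause else s for s in corpus]
    except ValueError as err:
        raise ValueError(f"pause zeroing failed: {err}") from err

    orig = _analyse(cleaned, cfg, stream=0).rename(columns=lambda c: (
        c if c == "song_id" else f"orig_{c}"))

    instances = collect_instances(cleaned)
    note_profiles = build_note_profiles(instances)

    per_song = orig
    paired: dict[str, PairedTestSummary] = {}
    for k, statistic in enumerate(cfg.pause_stats):
        pause_profiles = build_pause_profiles(cleaned, statistic=statistic)
        avg_songs = []
        for song in cleaned:
            try:
                avg_songs.append(synthesize_average_song(song, note_profiles,
                                                         pause_profiles))
            except KeyError as err:
                raise RuntimeError(
                    f"re-synthesis failed for song "
                    f"{song.envelope.song_id!r}: {err}") from err
        avg = _analyse(avg_songs, cfg, stream=1 + k)
        avg = avg.drop(columns="song_id").rename(
            columns=lambda c: f"avg_{statistic}_{c}")
        per_song = pd.concat([per_song.reset_index(drop=True),
                              avg.reset_index(drop=True)], axis=1)
        res = paired_t(per_song["orig_sd_distance"],
                       per_song[f"avg_{statistic}_sd_distance"])
        paired[statistic] = PairedTestSummary(
            t=res["t"], df=res["df"], p=res["p"], pause_statistic=statistic,
            mean_difference=float((per_song["orig_sd_distance"]
                                   - per_song[f"avg_{statistic}_sd_distance"]).mean()))
    return CorpusReport(per_song=per_song, paired=paired, config=cfg)
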