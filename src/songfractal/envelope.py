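"""Amplitude envelopes, note segmentation and pause zeroing.

The rhythm analyses in this package operate on 1000 Hz amplitude
envelopes: windowed-RMS magnitude of the audio waveform (10 ms windows,
1 ms steps by default), which carries note timing, duration and
intensity but no spectral detail. Note boundaries are found from the
difference of a fast and a slow Hodrick-Prescott trend of the envelope —
a penalized-least-squares band-pass that goes positive during notes —
and between-note pauses are set to exactly zero amplitude so that pause
noise cannot contribute to measured multifractality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.tsa.filters.hp_filter import hpfilter

__all__ = [
    "Waveform",
    "Envelope",
    "NoteAnnotation",
    "SongRecord",
    "extract_envelope",
    "hp_filter",
    "segment_notes",
    "zero_pauses",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples at a fixed sampling rate (a.u.)."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")


@dataclass(frozen=True)
class Envelope:
    """Non-negative amplitude envelope sampled at ``rate`` Hz (default 1000)."""

    values: np.ndarray
    rate: float = 1000.0
    song_id: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.rate <= 0:
            raise ValueError("envelope rate must be positive")
        if values.size and values.min() < 0:
            raise ValueError("envelope values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_ms(self) -> float:
        return self.values.size * 1000.0 / self.rate

    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * (1000.0 / self.rate)


@dataclass(frozen=True)
class NoteAnnotation:
    """One note interval, half-open [onset, offset) in ms from song start."""

    onset_ms: float
    offset_ms: float
    type_label: str = ""

    def __post_init__(self):
        if not self.onset_ms < self.offset_ms:
            raise ValueError("note onset must precede offset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class SongRecord:
    """An envelope with its ordered note annotations and provenance."""

    envelope: Envelope
    notes: list[NoteAnnotation] = field(default_factory=list)
    provenance: str = "original"  # original | average_rhythm | surrogate | synthetic

    def __post_init__(self):
        if self.provenance not in {"original", "average_rhythm",
                                   "surrogate", "synthetic"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        prev_end = -np.inf
        for note in self.notes:
            if note.onset_ms < prev_end:
                raise ValueError("note annotations overlap or are unsorted")
            prev_end = note.offset_ms
        if self.notes and self.notes[-1].offset_ms > self.envelope.duration_ms + 1e-9:
            raise ValueError("note annotations exceed envelope duration")


def extract_envelope(w: Waveform, window_ms: float = 10.0,
                     step_ms: float = 1.0) -> Envelope:
    """Windowed-RMS amplitude envelope of a waveform.

    RMS is computed in ``window_ms`` windows advanced by ``step_ms``
    (defaults 10 ms / 1 ms, giving a 1000 Hz envelope); a partial final
    window is dropped rather than padded.
    """
    if not (0 < step_ms <= window_ms):
        raise ValueError("require window_ms >= step_ms > 0")
    x = w.samples
    if x.size == 0:
        raise ValueError("empty waveform")
    win = int(round(window_ms * w.sample_rate / 1000.0))
    step = int(round(step_ms * w.sample_rate / 1000.0))
    if win < 1 or step < 1:
        raise ValueError("window/step shorter than one audio sample")
    if win > x.size:
        raise ValueError("window longer than the waveform")
    n_windows = (x.size - win) // step + 1
    # cumulative sum of squares gives every window's energy in O(N)
    csq = np.concatenate([[0.0], np.cumsum(x**2)])
    starts = np.arange(n_windows) * step
    energy = csq[starts + win] - csq[starts]
    values = np.sqrt(np.maximum(energy / win, 0.0))
    return Envelope(values=values, rate=1000.0 / step_ms, song_id=w.source_id)


def hp_filter(x, lam: float) -> np.ndarray:
    """Hodrick-Prescott trend: argmin_tau sum(x-tau)^2 + lam*sum(d2 tau)^2.

    Natural (unconstrained) endpoints of the standard pentadiagonal
    system; lam = 0 returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if lam < 0:
        raise ValueError("smoothing coefficient must be non-negative")
    if lam == 0:
        return x.copy()
    _, trend = hpfilter(x, lamb=lam)
    return np.asarray(trend, dtype=float)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def segment_notes(e: Envelope, lam_fast: float = 50.0, lam_slow: float = 5e7,
                  min_note_ms: float = 5.0, merge_gap_ms: float = 3.0,
                  edge_frac: float = 0.05,
                  min_peak_frac: float = 0.05) -> list[NoteAnnotation]:
    """Note boundaries from the difference of two HP trends of the envelope.

    A fast trend (lam_fast, default 50) tracks the notes; a slow trend
    (lam_slow, default 5e7) tracks the overall level. Candidate notes
    are the maximal runs where fast - slow > 0, after merging gaps
    shorter than ``merge_gap_ms`` and dropping runs shorter than
    ``min_note_ms``. Because the trend crossing drifts into note attacks
    and decays, each run's boundaries are then localized on the envelope
    itself: walking outward from the run's amplitude peak until the
    envelope drops below ``edge_frac`` of that peak (set ``edge_frac=0``
    to keep the raw trend crossings). Runs peaking below
    ``min_peak_frac`` of the global envelope maximum are discarded: the
    slow trend dips below zero near silent stretches, which would
    otherwise promote noise-floor ripple to notes. Type labels are left
    empty; labels come from annotation files or the synthetic generator.
    """
    x = e.values
    if x.size == 0:
        raise ValueError("empty envelope")
    if np.ptp(x) == 0:
        return []
    diff = hp_filter(x, lam_fast) - hp_filter(x, lam_slow)
    ms_per_sample = 1000.0 / e.rate
    runs = _runs_of(diff > 0)
    # merge runs separated by sub-threshold gaps, then drop short runs
    merged: list[list[int]] = []
    max_gap = merge_gap_ms / ms_per_sample
    for start, stop in runs:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = min_note_ms / ms_per_sample
    min_peak = min_peak_frac * x.max()
    merged = [(a, b) for a, b in merged
              if (b - a) >= min_len and x[a:b].max() >= min_peak]
    if edge_frac > 0:
        merged = _refine_edges(x, merged, edge_frac)
        merged = [(a, b) for a, b in merged if (b - a) >= min_len]
    return [NoteAnnotation(onset_ms=a * ms_per_sample, offset_ms=b * ms_per_sample)
            for a, b in merged]


def _refine_edges(x: np.ndarray, runs: list[tuple[int, int]],
                  edge_frac: float) -> list[tuple[int, int]]:
    """Localize run boundaries at the envelope's own amplitude edges."""
    refined: list[tuple[int, int]] = []
    for k, (a, b) in enumerate(runs):
        lo = refined[-1][1] if refined else 0
        hi = runs[k + 1][0] if k + 1 < len(runs) else x.size
        peak_idx = a + int(np.argmax(x[a:b]))
        thr = edge_frac * x[peak_idx]
        i = peak_idx
        while i > lo and x[i - 1] >= thr:
            i -= 1
        j = peak_idx + 1
        while j < hi and x[j] >= thr:
            j += 1
        refined.append((i, j))
    return refined


def zero_pauses(s: SongRecord) -> SongRecord:
    """Set envelope amplitude outside the annotated notes to exactly zero."""
    env = s.envelope
    for note in s.notes:
        if note.offset_ms > env.duration_ms + 1e-9:
            raise ValueError("note annotation exceeds envelope duration")
    scale = env.rate / 1000.0
    mask = np.zeros(len(env), dtype=bool)
    for note in s.notes:
        a = int(round(note.onset_ms * scale))
        b = int(round(note.offset_ms * scale))
        mask[a:b] = True
    values = np.where(mask, env.values, 0.0)
    return replace(s, envelope=replace(env, values=values))
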