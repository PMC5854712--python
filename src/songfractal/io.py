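"""Plain-text I/O: WAV reading, envelope/annotation CSVs, corpus folders.

Envelopes travel as CSV with columns ``time_ms,amplitude``; annotations
as CSV with columns ``song_id,onset_ms,offset_ms,type_label``. A corpus
directory holds one ``<song_id>_env.csv`` per song plus a shared
``annotations.csv`` (and, for synthetic corpora, ``ground_truth.json``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .envelope import Envelope, NoteAnnotation, SongRecord, Waveform

__all__ = [
    "read_wav",
    "read_envelope_csv",
    "write_envelope_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "write_corpus",
    "read_corpus",
    "write_note_profiles_csv",
    "write_pause_profiles_csv",
]


def read_wav(path) -> Waveform:
    """Read a WAV file; stereo is downmixed by channel averaging."""
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(float) / max(abs(info.min), info.max)
    else:
        data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return Waveform(samples=data, sample_rate=int(rate),
                    source_id=Path(path).stem)


def write_envelope_csv(env: Envelope, path) -> None:
    pd.DataFrame({"time_ms": env.times_ms(), "amplitude": env.values}
                 ).to_csv(path, index=False)


def read_envelope_csv(path, song_id: str | None = None) -> Envelope:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size > 1:
        steps = np.diff(t)
        if np.ptp(steps) > 1e-6:
            raise ValueError("envelope CSV must be uniformly sampled")
        rate = 1000.0 / steps[0]
    else:
        rate = 1000.0
    return Envelope(values=df["amplitude"].to_numpy(dtype=float), rate=rate,
                    song_id=song_id if song_id is not None else Path(path).stem)


def write_annotations_csv(songs: list[SongRecord], path) -> None:
    rows = [{"song_id": s.envelope.song_id, "onset_ms": n.onset_ms,
             "offset_ms": n.offset_ms, "type_label": n.type_label}
            for s in songs for n in s.notes]
    pd.DataFrame(rows, columns=["song_id", "onset_ms", "offset_ms",
                                "type_label"]).to_csv(path, index=False)


def read_annotations_csv(path) -> dict[str, list[NoteAnnotation]]:
    df = pd.read_csv(path).sort_values(["song_id", "onset_ms"])
    out: dict[str, list[NoteAnnotation]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.song_id), []).append(NoteAnnotation(
            onset_ms=float(row.onset_ms), offset_ms=float(row.offset_ms),
            type_label="" if pd.isna(row.type_label) else str(row.type_label)))
    return out


def write_corpus(songs: list[SongRecord], directory, ground_truth=None) -> None:
    """Write per-song envelope CSVs, annotations.csv and optional ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for song in songs:
        write_envelope_csv(song.envelope,
                           directory / f"{song.envelope.song_id}_env.csv")
    write_annotations_csv(songs, directory / "annotations.csv")
    if ground_truth is not None:
        payload = [vars(gt) for gt in ground_truth]
        (directory / "ground_truth.json").write_text(
            json.dumps(payload, indent=1, default=float))


def write_note_profiles_csv(profiles: dict, path, courses_path=None) -> None:
    """Note profile summary CSV plus an optional normalized-course CSV.

    The summary has columns type_label, mean_duration_ms, n_instances;
    the companion file holds one column per type on the common
    duration-normalized grid.
    """
    rows = [{"type_label": p.type_label, "mean_duration_ms": p.mean_duration_ms,
             "n_instances": p.n_instances}
            for p in profiles.values()]
    pd.DataFrame(rows).sort_values("type_label").to_csv(path, index=False)
    if courses_path is not None:
        pd.DataFrame({p.type_label: p.course_norm
                      for p in profiles.values()}).to_csv(courses_path,
                                                          index=False)


def write_pause_profiles_csv(pauses: dict, path) -> None:
    """Pause profile CSV with columns left,right,duration_ms,statistic,n."""
    rows = [{"left": p.left_type, "right": p.right_type,
             "duration_ms": p.duration_ms, "statistic": p.statistic,
             "n": p.n_instances}
            for p in pauses.values()]
    pd.DataFrame(rows).sort_values(["left", "right"]).to_csv(path, index=False)


def read_corpus(directory, provenance: str = "original") -> list[SongRecord]:
    """Load a corpus directory written by :func:`write_corpus`."""
    directory = Path(directory)
    annotations = read_annotations_csv(directory / "annotations.csv")
    songs = []
    for env_path in sorted(directory.glob("*_env.csv")):
        song_id = env_path.name[: -len("_env.csv")]
        env = read_envelope_csv(env_path, song_id=song_id)
        songs.append(SongRecord(envelope=env,
                                notes=annotations.get(song_id, []),
                                provenance=provenance))
    return songs
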