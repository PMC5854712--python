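"""The average-rhythm contrast on a small synthetic corpus.

Generates 8 songs whose note timing and intensity drift and carry a
recurring deviation motif, re-synthesizes each song from per-type
average note profiles and per-pair average pauses (original note order,
fully stereotyped timing), and compares the two versions' surrogate-test
effect sizes with a paired t-test. A significant positive difference
means the instance-level deviations — not just the note arrangement —
contribute multi-timescale structure.
"""

from songfractal import SongConfig, StudyConfig, gen_song_corpus, run_study

songs, _ = gen_song_corpus(SongConfig(n_songs=8, notes_per_song=(8, 12),
                                      seed=3, deviation="mixed"))
report = run_study(songs, StudyConfig(n_surrogates=30,
                                      pause_stats=("mean",), seed=3))

cols = ["song_id", "orig_width", "orig_sd_distance", "avg_mean_sd_distance"]
print(report.per_song[cols].round(3).to_string(index=False))
res = report.paired["mean"]
print(f"\npaired t({res.df}) = {res.t:.2f}, p = {res.p:.4g}; "
      f"mean SD-distance difference = {res.mean_difference:.1f}")
print("Originals sit further above their IAAFT null than their "
      "average-rhythm versions:\nthe structured deviations carry part of "
      "the rhythm's multifractality.")
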