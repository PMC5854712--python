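"""Test a song envelope's multifractal width against its IAAFT null.

Generates one synthetic song with structured timing/intensity deviations
(drift + recurring motif), zeroes its pauses, and compares its spectrum
width with 50 IAAFT surrogates. The SD-distance is the effect size: how
many ensemble standard deviations the original lies above the surrogate
mean. A width outside the 95% interval flags structure beyond the
envelope's value distribution and linear correlations.
"""

from songfractal import SongConfig, gen_song_corpus, surrogate_test, zero_pauses

songs, _ = gen_song_corpus(SongConfig(n_songs=1, notes_per_song=(12, 12),
                                      seed=7, deviation="mixed"))
song = zero_pauses(songs[0])
res = surrogate_test(song.envelope.values, n=50, seed=11)

print(f"original width:        {res.original_width:.3f}")
print(f"surrogate 95% CI:      ({res.ci_low:.3f}, {res.ci_high:.3f})")
print(f"SD-distance:           {res.sd_distance:.1f}")
print(f"significant:           {res.significant}")
print("\nThe original's width exceeds the IAAFT interval: the envelope "
      "carries\nmulti-timescale structure that value-preserving phase "
      "randomization destroys.")
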