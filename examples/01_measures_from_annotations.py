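"""From Praat-style interval annotations to the five coordination measures.

Builds a tiny two-partner annotation in memory, binarizes each into a
1 Hz speech/silence series, aligns the dyad, and prints the measure
bundle for one conversation.
"""

from speechcoord import IntervalAnnotation, align_dyad, binarize, dyad_measures

# Partner 1 speaks 0-8 s and 12-20 s; partner 2 fills the gap and the tail.
ann1 = IntervalAnnotation(
    intervals=(
        (0.0, 8.0, "sounding"), (8.0, 12.0, "silent"),
        (12.0, 20.0, "sounding"), (20.0, 30.0, "silent"),
    ),
    total_duration=30.0,
    source_id="p1",
)
ann2 = IntervalAnnotation(
    intervals=(
        (0.0, 8.5, "silent"), (8.5, 12.0, "sounding"),
        (12.0, 21.0, "silent"), (21.0, 29.0, "sounding"), (29.0, 30.0, "silent"),
    ),
    total_duration=30.0,
    source_id="p2",
)

s1 = binarize(ann1, "majority", dyad_id="demo", participant_id="p1", task="introduction")
s2 = binarize(ann2, "majority", dyad_id="demo", participant_id="p2", task="introduction")
dyad = align_dyad(s1, s2)
m = dyad_measures(dyad, max_lag=10)

print(f"series length: {dyad.n} s; speech seconds p1={s1.speech_seconds}, p2={s2.speech_seconds}")
print(f"RR_global = {m.rr_global:.3f}   (speech coordination across all lags)")
print(f"RR_LOS    = {m.rr_los:.3f}   (simultaneous: one speaks while the other is silent)")
print(f"Q_DCRP    = {m.q_dcrp:.3f}   (0 = balanced leading/following, 1 = one partner leads)")
print(f"LAM_ARD   = {m.lam_ard:.3f}   (asymmetry in sustained-influence laminarity)")
print(f"TT_ARD    = {m.tt_ard:.3f}   (asymmetry in mean trapping time)")
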