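"""Quality control: gasps, pauses and sniffing must not silently bias rates.

Clips with irregular breathing were excluded by hand in the original
workflow; here the spectral-prominence and inter-breath-interval checks
do that automatically. A 4-second pause breaks the waveform's regularity
and the clip is flagged.
"""

from vivorate import respirometry as rp
from vivorate import synthetic_video as sv

for label, events in [
    ("regular breathing", ()),
    ("4-s pause        ", (sv.BreathingEvent("pause", 4.0, 4.0),)),
]:
    scenario = sv.BreathingScenario(
        rate_bpm=180.0, duration_s=12.0, seed=17, events=events
    )
    clip, truth = sv.render_breathing_clip(scenario)
    est = rp.estimate_rate_from_clip(clip, [rp.RoiContour(sv.flank_roi(scenario))])
    print(
        f"{label}: estimate {est.rate_bpm:6.1f} bpm, "
        f"ibi_cv {est.ibi_cv:5.2f}, qc_pass={est.qc_pass}"
    )
# Only QC-passing clips enter a mouse's summary; summarize_mouse takes
# the median of at least five passing clips.
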