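"""Parameterize a skewed daily waveform: crest, sections and FWHM.

Evaluates a morning-peaked waveform that rises for 9 h and falls for 15 h,
samples it on a 30-min grid, and reports the crest time, the ascending and
descending sections, the half-maximum crossings, and the FWHM — the hours
per day the gene spends above half of its peak expression.
"""

import numpy as np

import rhythmshift as rs

params = rs.WaveformParams(
    peak_phase=9, rise=9, fall=15, sharpness=2, amplitude=4, baseline=1
)
t = np.arange(0, 24, 0.5)
curve = rs.Curve(t, rs.make_waveform(params)(t))

sec = rs.sections(curve)
res = rs.fwhm(rs.normalize_minmax(curve))

print(f"crest at ZT{res.crest_time:.1f}")
print(f"ascending section {sec.ascending:.1f} h, descending {sec.descending:.1f} h")
print(f"half-max crossings: up ZT{res.ascend_cross:.2f}, down ZT{res.descend_cross:.2f}")
print(f"FWHM {res.fwhm:.2f} h (generator ground truth {rs.true_fwhm(params):.2f} h)")
print(f"a 16 h -> 18 h descending section is a {rs.percent_change(16, 18):+.1f}% change")
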