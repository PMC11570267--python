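"""Physiological time: validate by LOOCV, then map an age-warped matrix.

Two ridge regressions predict cos and sin of sampling time from a sample's
expression profile; the angle of their outputs is the predicted clock time.
Leave-one-time-point-out cross-validation checks the model on the reference
age; the model then reads the "subjective time" of an old-age matrix whose
waveforms were phase-advanced and attenuated, showing where the old
transcriptome sits on the young clock at each ZT.
"""

import rhythmshift as rs

cfg = rs.SimConfig(
    n_cycling=500,
    n_flat=0,
    noise_cv=0.1,
    seed=3,
    ages={
        "young": rs.AgeEffect(),
        "old": rs.AgeEffect(amplitude_scale=0.5, phase_shift=-2.0,
                            fwhm_delta_mode="broaden", applies_to=0.5),
    },
)
matrices, _ = rs.simulate_expression_matrix(cfg)

loocv = rs.loocv_by_timepoint(matrices["young"])
print(f"LOOCV circular error: mean {loocv['error'].mean():.2f} h, "
      f"max {loocv['error'].max():.2f} h (validation bound: < 2 h)")

model = rs.fit_time_model(matrices["young"], reference_label="young")
curve = rs.subjective_time_curve(model, matrices["old"])
dist = rs.distance_from_reference_time(curve, reference_time=8.0)
print("old-age samples on the young clock:")
for zt, pred, span, d in zip(curve.query_zts, curve.predicted, curve.spans,
                             dist.to_numpy()):
    print(f"  ZT{zt:4.0f} -> subjective ZT{pred:5.2f} "
          f"(span to next {span:4.1f} h, {d:4.1f} h from 'noon' ZT8)")
print(f"spans sum to {curve.spans.sum():.1f} h (one full day)")
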