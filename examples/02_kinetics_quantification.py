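"""SUVR vs reference-Logan DVR on simulated SRTM kinetics.

Simulates noiseless [11C]PIB-like time-activity curves for a range of true
binding potentials and quantifies each with the static 30-60 min SUVR and the
dynamic reference-Logan DVR (t* = 30 min), showing the systematic SUVR
overestimation that motivates dynamic imaging.
"""

from amytrial import (
    FrameSchedule,
    KineticParams,
    ReferenceShape,
    compute_rlogan_dvr,
    compute_suvr,
    simulate_reference_tac,
    simulate_srtm_tac,
)

sched60 = FrameSchedule.default(60.0)
sched90 = FrameSchedule.default(90.0)
shape = ReferenceShape()
ref60 = simulate_reference_tac(sched60, shape)
ref90 = simulate_reference_tac(sched90, shape)

print(f"{'true DVR':>9} {'RLogan DVR':>11} {'SUVR 30-60':>11} {'SUVR bias %':>12}")
for bpnd in (0.0, 0.25, 0.5, 1.0):
    params = KineticParams(R1=1.0, k2=0.15, BPND=bpnd)
    dvr, _ = compute_rlogan_dvr(
        simulate_srtm_tac(shape, params, sched90), ref90, t_star=30.0, k2_ref=0.15
    )
    suvr = compute_suvr(simulate_srtm_tac(shape, params, sched60), ref60)
    truth = 1.0 + bpnd
    print(f"{truth:9.2f} {dvr:11.4f} {suvr:11.4f} {100 * (suvr - truth) / truth:12.1f}")

print()
print(
    "RLogan recovers the true DVR to well under 1%, while the late-window\n"
    "SUVR overshoots increasingly with binding - the proportional bias seen\n"
    "when static and dynamic quantification are compared on real scans."
)
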