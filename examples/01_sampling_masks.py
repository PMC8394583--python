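"""Build the accelerated Cartesian sampling pattern and read off its cost.

A regular undersampling grid (every R-th phase-encode line) is combined with
a fully sampled autocalibration (ACS) block at the k-space center and an
optional phase-resolution truncation of the periphery.  The fraction of
lines actually acquired is the nominal scan-time factor.
"""

from mskrecon import make_regular_mask, nominal_scan_time_factor

for R, acs, pr in [(1, 0, 1.0), (2, 16, 1.0), (4, 16, 1.0), (4, 16, 0.75)]:
    p = make_regular_mask(n_pe=96, R=R, acs_width=acs, phase_resolution=pr)
    print(
        f"R={R} acs={acs:2d} phase_res={pr:4.2f} -> "
        f"{p.n_sampled:2d}/96 lines, scan-time factor "
        f"{nominal_scan_time_factor(p):.3f}"
    )

# The factor is the acquisition-time cost of the protocol relative to full
# sampling: R=4 with a 16-line ACS block needs 36/96 = 0.375 of the time, and
# skipping 25% of the periphery (phase resolution 75%) brings it to 0.312.
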