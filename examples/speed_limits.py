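"""Calibrate the speed-limit model and print the allowed doubling-time band.

A yeast cell's doubling time is tau = t + dt: a protein-synthesis-limited
floor t = c_t * r(T)^-0.77 plus a ROS-dependent G1 delay dt proportional
to exp(ROS)/r(T).  Cells above a threshold ROS never divide, which caps
tau.  Calibrating from four printed anchors (3-day floor at 5 C, 28.4-day
floor at 1 C, 35-day cap at 5 C, 6000-unit ROS threshold) fixes every
constant; the band below shows how both limits stretch as cultures cool,
with the low-speed limit reaching years near the freezing point.
"""

from coldlife import calibrate, speed_limits, DEFAULT_ANCHORS
from coldlife.units import days, kelvin, years

params = calibrate(DEFAULT_ANCHORS)
print(f"activation energy: {params.E_a / 1000:.0f} kJ/mol, alpha = {params.alpha}")
print(f"{'T (degC)':>8} {'shortest tau':>14} {'longest tau':>14}")
for tc in (1.0, 3.0, 5.0, 8.0, 12.0):
    lim = speed_limits(kelvin(tc), params)
    longest = (
        f"{years(lim.tau_max):.2f} yr" if lim.tau_max > 24 * 365 else f"{days(lim.tau_max):.1f} d"
    )
    print(f"{tc:>8.1f} {days(lim.tau_min):>12.1f} d {longest:>14}")
print(
    "\nEvery observed doubling time must fall between the two columns; at 1 degC\n"
    "the longest allowed doubling time is on the scale of years."
)
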