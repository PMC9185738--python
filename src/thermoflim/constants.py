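"""Physical constants and unit conversions.

Internal unit conventions: lengths in angstrom (A), times in picoseconds
(ps) for trajectories; nanoseconds (ns) for fluorescence decays; masses in
atomic mass units (amu); temperatures in kelvin (K) for molecular
quantities and degrees Celsius for cell thermometry.
"""

# Boltzmann constant in amu * A^2 / ps^2 / K
KB_AMU_A2_PS2 = 0.831446262

# 1 A^2/ps = 1e-4 cm^2/s
A2_PER_PS_TO_CM2_PER_S = 1.0e-4
CM2_PER_S_TO_A2_PER_PS = 1.0e4
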