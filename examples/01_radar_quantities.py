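"""Derived quantities of the vital-sign acquisition configuration.

Builds the 60 GHz FMCW preset used for child vital-sign recording and prints
the analytic quantities that follow from it: the range-bin width c/(2B), the
maximum unambiguous range Fs*c*Tc/(2B), the carrier wavelength, and the beat
frequency a chest at 1 m produces.  The bin width sets how finely the radar
separates reflectors in distance; the wavelength sets the phase sensitivity
(a full phase cycle per half-wavelength of chest motion).
"""

import radarvitals as rv

config = rv.table2_config()

print(f"start frequency : {config.start_frequency / 1e9:.2f} GHz")
print(f"bandwidth       : {config.bandwidth / 1e9:.2f} GHz")
print(f"chirp duration  : {config.chirp_duration * 1e6:.2f} us")
print(f"range resolution: {rv.range_resolution(config) * 100:.1f} cm")
print(f"maximum range   : {rv.max_range(config):.1f} m")
print(f"wavelength      : {rv.wavelength(config) * 1e3:.2f} mm")
print(f"beat freq @ 1 m : {rv.beat_frequency(1.0, config) / 1e3:.1f} kHz")
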