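# Gaussian components of the canonical far-UV CD basis bands.
# Columns: state center_nm width_nm amplitude
# Amplitudes in 10^3 deg cm^2 dmol^-1 (mean residue ellipticity).
# H: positive band near 193 nm, negative bands near 208 and 222 nm.
# E: positive near 196 nm, negative near 217 nm.
# C: negative band around 200 nm.
H 193 5.5 65.0
H 208 6.5 -32.0
H 222 9.0 -33.0
E 196 5.0 35.0
E 217 9.0 -22.0
C 198 7.0 -42.0
C 220 12.0 3.0
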