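"""Unit conventions and conversion constants.

All lengths are micrometres (µm), times seconds (s), speeds metres per
second (m/s), and potentials arbitrary voltage units (treat as µV for
realistic scenes).  Effective charge q' = q/(4*pi*eps*eps0) carries units
of potential·µm so that V = q'/D with D in µm.
"""

#: micrometres per metre (speed m/s -> µm/s multiplies by this)
UM_PER_M = 1.0e6

#: converts a median absolute deviation to a Gaussian sigma estimate
MAD_TO_SIGMA = 1.0 / 0.6745
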