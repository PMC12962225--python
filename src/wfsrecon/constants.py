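"""Versioned spectral constants for water-fat-silicone chemical-shift encoding.

Chemical shifts are expressed in ppm *relative to the water resonance*
(negative = lower frequency than water). The nine-peak triglyceride model
below is the standard in-vivo characterization used throughout the
water-fat imaging literature; the amplitudes sum to 1 exactly after the
renormalization applied on load. Sites wishing to substitute their own
calibration can load a model from YAML (:func:`wfsrecon.spectral.SpectralModel.from_yaml`).
"""

from __future__ import annotations

# Nine-peak fat model: water-relative shifts (ppm) and relative amplitudes.
# Absolute peak positions 5.29, 5.19, 4.20, 2.75, 2.24, 2.02, 1.60, 1.30,
# 0.90 ppm referenced to water at 4.70 ppm.
NINE_PEAK_FAT_PPM = (0.59, 0.49, -0.50, -1.95, -2.46, -2.68, -3.10, -3.40, -3.80)
NINE_PEAK_FAT_AMP = (0.0473, 0.0390, 0.0387, 0.0061, 0.0577, 0.0766, 0.0413, 0.6193, 0.0740)

#: Silicone (polydimethylsiloxane) single-peak resonance relative to water.
SILICONE_PPM = -4.9

#: Proton Larmor frequency of a 3 T system [Hz].
DEFAULT_LARMOR_HZ = 127.7e6

CONSTANTS_VERSION = "1"
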