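"""Shared helper: synthetic pullulan-standard files for calibration tests.

The standards are generated from a known linear map from the universal-
calibration ordinate to elution volume (synthetic — the real standard
series' elution volumes are instrument-specific and not tabulated).
"""

import numpy as np

import sbecld as sb


def write_synthetic_standards(path, slope=-2.0, intercept=25.0):
    mh = sb.MarkHouwink()
    masses = np.geomspace(342.0, 2.35e6, 10)
    y = np.log10(sb.universal_ordinate(masses, mh))
    ve = (y - intercept) / slope
    sb.write_standards(
        [sb.PullulanStandard(m, v) for m, v in zip(masses, ve)], path
    )
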