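"""Single-level stationary (undecimated) 3D wavelet decomposition.

Separable low/high-pass filtering along x, y and z with `coif1` taps and
periodic boundary extension yields eight same-shape sub-bands named
LLL..HHH (letter order follows axis order x, y, z), so ROI masks apply to
every sub-band unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["wavelet_subbands", "SUBBAND_NAMES", "COIF1_LO", "COIF1_HI"]

# coif1 decomposition filters (orthonormal; low-pass sums to sqrt(2))
COIF1_LO = np.array(
    [
        -0.015655728135465,
        -0.072732619512854,
        0.384864846864203,
        0.852572020212255,
        0.337897662457809,
        -0.072732619512854,
    ]
)
# quadrature mirror: hi[k] = (-1)^k * lo[N-1-k]; taps sum to zero
COIF1_HI = np.array([(-1) ** k * COIF1_LO[len(COIF1_LO) - 1 - k] for k in range(len(COIF1_LO))])

SUBBAND_NAMES = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


def _filter_axis(vol: np.ndarray, axis: int, highpass: bool) -> np.ndarray:
    taps = COIF1_HI if highpass else COIF1_LO
    return correlate1d(vol, taps, axis=axis, mode="wrap")


def wavelet_subbands(volume: np.ndarray) -> dict[str, np.ndarray]:
    """Return the eight undecimated sub-bands of a 3D volume, keyed by
    name (e.g. 'HHL' = high-pass along x and y, low-pass along z)."""
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if min(vol.shape) < len(COIF1_LO):
        raise ValueError(
            f"volume dims {vol.shape} smaller than filter length {len(COIF1_LO)}"
        )
    out: dict[str, np.ndarray] = {}
    # filter axis by axis, reusing the two single-axis results per level
    lo_x = _filter_axis(vol, 0, False)
    hi_x = _filter_axis(vol, 0, True)
    for name_x, vx in (("L", lo_x), ("H", hi_x)):
        lo_y = _filter_axis(vx, 1, False)
        hi_y = _filter_axis(vx, 1, True)
        for name_y, vy in (("L", lo_y), ("H", hi_y)):
            for name_z, highpass in (("L", False), ("H", True)):
                out[name_x + name_y + name_z] = _filter_axis(vy, 2, highpass)
    return out
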