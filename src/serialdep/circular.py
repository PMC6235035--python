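"""Angle arithmetic on the 180°-periodic orientation circle.

Gabor orientation is undirected, so all differences live on a circle of
period 180° and are reported as signed angles in (-90, +90].
"""

from __future__ import annotations

import numpy as np

ORIENTATION_PERIOD = 180.0


def wrap_orientation(theta):
    """Reduce an orientation (degrees) into [0, 180)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("orientation must be finite")
    out = np.mod(theta, ORIENTATION_PERIOD)
    return out if out.ndim else float(out)


def wrap_difference(theta_a, theta_b=0.0):
    """Signed minimal difference theta_a - theta_b on the orientation circle.

    Returns a value in (-90, +90]; exactly ±90 maps to +90 (half-open
    convention). Positive means theta_a is more clockwise than theta_b
    under the convention that larger angles are more clockwise.
    """
    theta_a = np.asarray(theta_a, dtype=float)
    theta_b = np.asarray(theta_b, dtype=float)
    if not (np.all(np.isfinite(theta_a)) and np.all(np.isfinite(theta_b))):
        raise ValueError("orientations must be finite")
    d = 90.0 - np.mod(90.0 - (theta_a - theta_b), ORIENTATION_PERIOD)
    return d if d.ndim else float(d)
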