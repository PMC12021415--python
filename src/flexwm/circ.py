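"""Angular arithmetic on the 180-degree orientation circle.

Orientations are undirected, so all arithmetic is modulo 180 and the
maximal distance between two orientations is 90 degrees.
"""

from __future__ import annotations

import numpy as np

PERIOD = 180.0


def wrap(theta):
    """Reduce an angle (degrees) into [0, 180)."""
    return np.mod(theta, PERIOD)


def signed_diff(a, b):
    """Signed circular difference a - b mapped into [-90, 90)."""
    d = np.mod(np.asarray(a, dtype=float) - b + PERIOD / 2, PERIOD) - PERIOD / 2
    return d


def distance(a, b):
    """Unsigned circular distance between orientations, in [0, 90]."""
    return np.abs(signed_diff(a, b))
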