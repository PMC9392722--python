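"""Cardinal natural-cubic-spline basis used for flexible-shape deconvolution."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def cardinal_spline_basis(knots: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the cardinal natural-cubic-spline basis at times ``t``.

    Column ``j`` is the natural cubic spline interpolating 1 at ``knots[j]``
    and 0 at every other knot; outside ``[knots[0], knots[-1]]`` the basis is
    zero (the modelled response is confined to the window).

    Returns an array of shape ``(len(t), len(knots))``.
    """
    knots = np.asarray(knots, dtype=float)
    t = np.asarray(t, dtype=float)
    B = np.zeros((t.size, knots.size))
    inside = (t >= knots[0]) & (t <= knots[-1])
    for j in range(knots.size):
        e = np.zeros(knots.size)
        e[j] = 1.0
        B[inside, j] = CubicSpline(knots, e, bc_type="natural")(t[inside])
    return B
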