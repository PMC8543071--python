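"""Angle arithmetic on the 180-degree-periodic orientation space.

Orientations live in the half-open interval (-90, +90] degrees; positive
values are clockwise (rightward) tilts, negative values anticlockwise
(leftward) tilts.  All functions accept scalars or array-likes and
vectorise via numpy; scalars in give scalars out.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = ["wrap_orientation", "signed_diff", "abs_dev", "to_full_circle", "from_full_circle"]


def _validate_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("angles must be finite")


def wrap_orientation(angle):
    """Wrap arbitrary degrees into the canonical interval (-90, +90].

    Idempotent and invariant under shifts by multiples of 180.
    """
    a = np.asarray(angle, dtype=float)
    _validate_finite(a)
    r = np.mod(a, 180.0)  # [0, 180)
    r = np.where(r > 90.0, r - 180.0, r)  # (-90, 90]
    if np.ndim(angle) == 0:
        return float(r)
    return r


def signed_diff(a, b):
    """Signed angular difference a - b, wrapped into (-90, +90] degrees."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _validate_finite(a, b)
    return wrap_orientation(a - b)


def abs_dev(a, b):
    """Absolute angular deviation between two orientations, in [0, 90]."""
    d = signed_diff(a, b)
    if np.ndim(d) == 0:
        return abs(d)
    return np.abs(d)


def to_full_circle(o):
    """Doubling transform: orientation degrees -> radians on the full circle.

    Maps (-90, 90] onto (-pi, pi] so that 180-degree-periodic orientations
    can be modelled with circular distributions defined on 360 degrees.
    """
    o = np.asarray(o, dtype=float)
    _validate_finite(o)
    out = np.deg2rad(2.0 * o)
    if out.ndim == 0:
        return float(out)
    return out


def from_full_circle(theta):
    """Inverse of :func:`to_full_circle`: radians on the circle -> orientation."""
    theta = np.asarray(theta, dtype=float)
    _validate_finite(theta)
    return wrap_orientation(np.rad2deg(theta) / 2.0)
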