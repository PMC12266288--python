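"""Circular arithmetic and sign conventions shared by every analysis stage.

All angles are in degrees. Absolute directions live on ``[0, 360)``; signed
angular differences live on ``(-180, 180]``. The "toward-coding" convention
flips the sign of a response error so that positive always means *toward the
stimulus of the previous trial* and negative means *away* from it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_direction",
    "wrap_signed",
    "signed_diff",
    "toward_previous_sign",
    "distance_to_nearest_cardinal",
]


def wrap_direction(angle):
    """Reduce an angle (or array) to a direction in ``[0, 360)``."""
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_direction: non-finite angle")
    out = a % 360.0
    return out if out.ndim else float(out)


def wrap_signed(angle):
    """Wrap an angle (or array) to the signed interval ``(-180, 180]``.

    ``wrap_signed(a) == wrap_signed(a + 360)`` for every finite ``a``, and the
    boundary maps as ``-180 -> 180``.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_signed: non-finite angle")
    out = -((-a) % 360.0)          # in (-360, 0]
    out = np.where(out <= -180.0, out + 360.0, out + 0.0)
    return out if out.ndim else float(out)


def signed_diff(a, b):
    """Signed circular difference ``a - b`` in ``(-180, 180]``.

    Antisymmetric up to the 180 boundary: ``signed_diff(a, b) ==
    -signed_diff(b, a)`` whenever the difference is not exactly 180.
    """
    return wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def toward_previous_sign(error, delta_prev):
    """Recode a signed response error so positive means *toward* the previous
    stimulus.

    ``delta_prev`` is the signed circular difference previous - current
    target. The toward-coded error is ``error * sign(delta_prev)``; when the
    two targets coincide (``delta_prev == 0``) the coding is undefined and the
    result is 0 — callers exclude such trials.
    """
    e = np.asarray(error, dtype=float)
    d = np.asarray(delta_prev, dtype=float)
    out = e * np.sign(d)
    return out if out.ndim else float(out)


def distance_to_nearest_cardinal(angle):
    """Signed distance (degrees, in ``[-45, 45)``) from a direction to the
    nearest cardinal direction (0, 90, 180 or 270)."""
    a = np.asarray(angle, dtype=float)
    out = (a + 45.0) % 90.0 - 45.0
    return out if out.ndim else float(out)
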