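"""Exponential Eph/ephrin concentration profiles along the retinal and collicular axes.

The model works on two normalised one-dimensional axes:

* retina, nasotemporal axis: coordinate ``x`` in [0, 1], temporal pole at 0,
  nasal pole at 1;
* superior colliculus (SC), rostrocaudal axis: coordinate ``y`` in [0, 1],
  rostral pole at 0, caudal pole at 1.

Four exponential concentration profiles drive the mapping: retinal EphA
(high temporal, decaying with ``x``), retinal ephrin-A (low temporal, rising
with ``x``), SC ephrin-A (low rostral, rising with ``y``) and SC EphA (high
rostral, decaying with ``y``).  Retinal EphA plus SC ephrin-A form the
*gradient* (forward-signalling) system; retinal ephrin-A plus SC EphA form
the *countergradient* (reverse-signalling) system.  Each profile has a
height and a decay-or-rise constant, eight free parameters in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "ExponentialGradient",
    "GradientSet",
    "build_gradient_set",
    "matched_gradient_set",
]

#: orientation flags
DECAYING = "decaying"
RISING = "rising"


def _check_position(position) -> np.ndarray:
    pos = np.asarray(position, dtype=float)
    if np.any(pos < 0.0) or np.any(pos > 1.0):
        raise ValueError(f"position must lie in [0, 1], got {position!r}")
    return pos


@dataclass(frozen=True)
class ExponentialGradient:
    """An exponential concentration profile ``height * exp(±rate * position)``.

    Parameters
    ----------
    height
        Concentration scale at position 0 (dimensionless, >= 0).
    rate
        Decay-or-rise constant per unit axis length (>= 0).  A rate of 0
        gives a constant profile at ``height``.
    orientation
        ``"decaying"`` (concentration falls with the coordinate) or
        ``"rising"`` (concentration grows with the coordinate).
    """

    height: float
    rate: float = 0.0
    orientation: str = DECAYING

    def __post_init__(self):
        if self.height < 0:
            raise ValueError(f"gradient height must be >= 0, got {self.height}")
        if not np.isfinite(self.rate):
            raise ValueError("gradient rate must be finite")
        if self.rate < 0:
            raise ValueError(f"gradient rate must be >= 0, got {self.rate}")
        if self.orientation not in (DECAYING, RISING):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def signed_rate(self) -> float:
        """Rate with sign: negative for decaying, positive for rising."""
        return self.rate if self.orientation == RISING else -self.rate

    def __call__(self, position) -> Union[float, np.ndarray]:
        """Concentration at ``position`` in [0, 1]."""
        pos = _check_position(position)
        out = self.height * np.exp(self.signed_rate * pos)
        if np.ndim(position) == 0:
            return float(out)
        return out

    def scaled(self, factor: float) -> "ExponentialGradient":
        """A copy with the height multiplied by ``factor`` (>= 0)."""
        return replace(self, height=self.height * factor)


# Per-RGC concentration vectors (knock-in mosaics) may replace the smooth
# retinal EphA profile; everything downstream only ever needs per-RGC values.
RetinalEphA = Union[ExponentialGradient, np.ndarray]


@dataclass(frozen=True)
class GradientSet:
    """The four concentration profiles of one genotype.

    ``retinal_epha`` may be a per-RGC concentration vector instead of a
    smooth profile, which is how knock-in mosaics are represented.
    """

    retinal_epha: RetinalEphA
    retinal_ephrina: ExponentialGradient
    sc_ephrina: ExponentialGradient
    sc_epha: ExponentialGradient

    def retinal_epha_at(self, x) -> np.ndarray:
        """Retinal EphA at retinal position(s) ``x`` (smooth profile only)."""
        if not isinstance(self.retinal_epha, ExponentialGradient):
            raise TypeError(
                "retinal EphA is a per-RGC vector; index it by RGC instead"
            )
        return self.retinal_epha(x)

    def with_countergradient_scale(self, scale: float,
                                   retinal_only: bool = False) -> "GradientSet":
        """Scale the countergradient heights (reverse-signalling system).

        With ``retinal_only`` the SC EphA countergradient is left untouched
        and only the retinal ephrin-A height is scaled, which is the
        manipulation used in the countergradient/compensation trade-off
        sweep.
        """
        if scale < 0:
            raise ValueError("countergradient scale must be >= 0")
        sc_epha = self.sc_epha if retinal_only else self.sc_epha.scaled(scale)
        return replace(self, retinal_ephrina=self.retinal_ephrina.scaled(scale),
                       sc_epha=sc_epha)


def build_gradient_set(
    retinal_epha_height: float,
    retinal_epha_rate: float,
    retinal_ephrina_height: float,
    retinal_ephrina_rate: float,
    sc_ephrina_height: float,
    sc_ephrina_rate: float,
    sc_epha_height: float,
    sc_epha_rate: float,
) -> GradientSet:
    """Build a :class:`GradientSet` from the eight height/rate parameters.

    Orientations are fixed by the biology: retinal EphA decays
    temporal-to-nasal, retinal ephrin-A rises, SC ephrin-A rises
    rostral-to-caudal, SC EphA decays.  Setting both countergradient heights
    (retinal ephrin-A and SC EphA) to zero yields the forward-only regime.
    """
    return GradientSet(
        retinal_epha=ExponentialGradient(retinal_epha_height,
                                         retinal_epha_rate, DECAYING),
        retinal_ephrina=ExponentialGradient(retinal_ephrina_height,
                                            retinal_ephrina_rate, RISING),
        sc_ephrina=ExponentialGradient(sc_ephrina_height,
                                       sc_ephrina_rate, RISING),
        sc_epha=ExponentialGradient(sc_epha_height, sc_epha_rate, DECAYING),
    )


def matched_gradient_set(height: float = 1.0, rate: float = 1.0) -> GradientSet:
    """All four heights equal and all four rates equal.

    With matched parameters the closed-form optimal mapping is the identity
    y(x) = x.
    """
    return build_gradient_set(*([height, rate] * 4))
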