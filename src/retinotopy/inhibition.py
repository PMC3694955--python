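"""Branching inhibition from molecular signalling, and the optimal mapping.

A terminal of an axon from retinal position ``x`` experiences, at SC
position ``y``, a branching-inhibition signal with two repulsive parts:

* forward signalling: axonal EphA activated by SC ephrin-A, contributing
  ``[EphA]_ret(x) * [ephrinA]_SC(y)``;
* reverse signalling: axonal ephrin-A activated by SC EphA, contributing
  ``[ephrinA]_ret(x) * [EphA]_SC(y)``.

The molecular branching inhibition is their sum (unit coupling constants,
no receptor/ligand saturation).  Adding the density-compensation level
gives the total branching inhibition that drives terminal relocation.

For pure exponential profiles the SC position minimising the molecular
inhibition has a closed form: an affine function of ``x`` with slope
(sum of retinal rates)/(sum of SC rates) and an intercept involving the
log-ratio of rate-weighted height products.  With matched heights and
rates the optimal map is the identity.  A brute-force grid argmin serves
as an independent oracle.
"""

from __future__ import annotations

import numpy as np

from .gradients import ExponentialGradient, GradientSet

__all__ = [
    "molecular_inhibition",
    "inhibition_matrix",
    "total_inhibition",
    "NoInteriorOptimum",
    "optimal_position_closed_form",
    "optimal_position_bruteforce",
    "clamp_to_sc",
]


def molecular_inhibition(retinal_epha, retinal_ephrina,
                         gradients: GradientSet, y):
    """Molecular branching inhibition at SC position(s) ``y``.

    ``retinal_epha`` and ``retinal_ephrina`` are the concentrations carried
    by one axon (scalars); ``y`` may be a scalar or array of SC positions.
    """
    if np.any(np.asarray(retinal_epha) < 0) or np.any(np.asarray(retinal_ephrina) < 0):
        raise ValueError("axonal concentrations must be >= 0")
    forward = retinal_epha * gradients.sc_ephrina(y)
    reverse = retinal_ephrina * gradients.sc_epha(y)
    return forward + reverse


def inhibition_matrix(epha_per_rgc: np.ndarray, ephrina_per_rgc: np.ndarray,
                      gradients: GradientSet,
                      sc_pos: np.ndarray) -> np.ndarray:
    """(n_rgc, n_sc) molecular inhibition, one row per axon."""
    epha = np.asarray(epha_per_rgc, dtype=float)[:, None]
    ephrina = np.asarray(ephrina_per_rgc, dtype=float)[:, None]
    if np.any(epha < 0) or np.any(ephrina < 0):
        raise ValueError("axonal concentrations must be >= 0")
    return (epha * gradients.sc_ephrina(sc_pos)[None, :]
            + ephrina * gradients.sc_epha(sc_pos)[None, :])


def total_inhibition(molecular, compensation):
    """Elementwise sum of molecular inhibition and compensation levels."""
    molecular = np.asarray(molecular, dtype=float)
    compensation = np.asarray(compensation, dtype=float)
    if molecular.shape != compensation.shape:
        raise ValueError(
            f"length mismatch: molecular {molecular.shape} vs "
            f"compensation {compensation.shape}"
        )
    return molecular + compensation


class NoInteriorOptimum(ValueError):
    """No interior minimum of the molecular inhibition exists.

    Raised when a countergradient height is zero (the inhibition is then
    monotone in ``y`` and every axon favours one SC pole) or an SC rate is
    zero.
    """


def optimal_position_closed_form(x, gradients: GradientSet):
    """SC position minimising the molecular inhibition (unclamped).

    Closed form, valid for pure exponential profiles with both
    countergradient heights positive and both SC rates positive::

        y(x) = [(a_E + a_e) x + ln((b_E α_e β_E)/(b_e α_E β_e))] / (b_E + b_e)

    with α/a the retinal EphA/ephrin-A heights and rates and β/b the SC
    ones.  The result may lie outside [0, 1]; use :func:`clamp_to_sc` for
    the position realisable inside the SC.
    """
    if not isinstance(gradients.retinal_epha, ExponentialGradient):
        raise TypeError("closed form needs a smooth retinal EphA profile")
    gE, ge = gradients.retinal_epha, gradients.retinal_ephrina
    sE, se = gradients.sc_epha, gradients.sc_ephrina
    if ge.height == 0 or sE.height == 0:
        raise NoInteriorOptimum(
            "zero countergradient height: inhibition is monotone in y"
        )
    if gE.height == 0 or se.height == 0:
        raise NoInteriorOptimum(
            "zero gradient height: inhibition is monotone in y"
        )
    if sE.rate <= 0 or se.rate <= 0:
        raise NoInteriorOptimum("both SC rates must be positive")
    x = np.asarray(x, dtype=float)
    slope = (gE.rate + ge.rate) / (sE.rate + se.rate)
    intercept = np.log(
        (sE.rate * ge.height * sE.height) / (se.rate * gE.height * se.height)
    ) / (sE.rate + se.rate)
    y = slope * x + intercept
    return float(y) if y.ndim == 0 else y


def clamp_to_sc(y):
    """Clamp an optimal position onto the SC axis [0, 1]."""
    return np.clip(y, 0.0, 1.0)


def optimal_position_bruteforce(x: float, gradients: GradientSet,
                                grid_size: int = 10_001) -> float:
    """Grid argmin of the molecular inhibition over [0, 1].

    Independent oracle for the closed form.  Ties are broken toward the
    rostral pole (np.argmin returns the first minimum).
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    y = np.linspace(0.0, 1.0, grid_size)
    epha = gradients.retinal_epha_at(x)
    ephrina = gradients.retinal_ephrina(x)
    return float(y[np.argmin(molecular_inhibition(epha, ephrina, gradients, y))])
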