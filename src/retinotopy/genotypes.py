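"""Genotypes: EphA3 knock-in mosaics, EphA4 dosage and the Math5 knock-out.

EphA3 knock-in mice express a constant extra amount of EphA3 in roughly
40% of RGCs scattered across the retina, producing two interleaved RGC
populations and a doubled retinocollicular map.  The model idealises the
mosaic as a deterministic alternation ("every second axon"), so the
knock-in fraction is exactly 50%.  EphA4 is expressed uniformly along the
nasotemporal axis, so changing its gene dosage shifts every RGC's EphA by
the same constant.  The Math5 knock-out retains only ~5% of the normal RGC
complement, roughly evenly distributed across the retina.

The quantitative retinal EphA profile used for knock-in genotypes follows
the published in-situ hybridisation quantification: a graded component
0.26*exp(2.3*(1-x)) (x = 0 at the temporal pole), a uniform EphA4
contribution of 0.525 per allele (1.05 in wild type) and an EphA3
increment of 1.86 per knocked-in allele pair (0.93 in heterozygotes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gradients import DECAYING, ExponentialGradient

__all__ = [
    "Genotype",
    "rgc_positions",
    "sc_positions",
    "build_genotype_retinal_epha",
    "apply_math5",
    "INSITU_GRADED_GRADIENT",
    "EPHA4_UNIT",
    "EPHA3_INCREMENT",
]

# Transcribed quantification (relative in-situ signal units).
_INSITU_HEIGHT_TEMPORAL = 0.26 * float(np.exp(2.3))  # graded part at x = 0
INSITU_GRADED_GRADIENT = ExponentialGradient(_INSITU_HEIGHT_TEMPORAL, 2.3, DECAYING)
EPHA4_UNIT = 0.525        # uniform EphA4 per allele; wild type carries 2
EPHA3_INCREMENT = 1.86    # homozygous knock-in increment; het gets half

KNOCKIN_LEVELS = {"none": 0.0, "het": 0.5, "hom": 1.0}


@dataclass(frozen=True)
class Genotype:
    """Specification of the genetic manipulations applied to the retina.

    Parameters
    ----------
    epha3_knockin
        ``"none"``, ``"het"`` or ``"hom"``.  Heterozygotes carry half the
        homozygous EphA3 increment.
    epha4_dosage
        Number of EphA4 copies (0, 1 or 2); each copy adds a uniform EphA
        term to every RGC.
    rgc_survival_fraction
        Fraction of the wild-type RGC count present (1.0 normally, 0.05
        for the Math5 knock-out).
    """

    epha3_knockin: str = "none"
    epha4_dosage: int = 2
    rgc_survival_fraction: float = 1.0

    def __post_init__(self):
        if self.epha3_knockin not in KNOCKIN_LEVELS:
            raise ValueError(f"unknown knock-in state {self.epha3_knockin!r}")
        if self.epha4_dosage not in (0, 1, 2):
            raise ValueError("epha4_dosage must be 0, 1 or 2 copies")
        if not 0.0 < self.rgc_survival_fraction <= 1.0:
            raise ValueError("rgc_survival_fraction must lie in (0, 1]")


WILD_TYPE = Genotype()


def rgc_positions(n_rgc: int) -> np.ndarray:
    """Retinal positions of ``n_rgc`` RGCs at cell centres (i - 1/2)/n."""
    if n_rgc < 1:
        raise ValueError("need at least one RGC")
    return (np.arange(n_rgc) + 0.5) / n_rgc


def sc_positions(n_sc: int) -> np.ndarray:
    """Rostrocaudal positions of ``n_sc`` SC cells at cell centres."""
    if n_sc < 1:
        raise ValueError("need at least one SC cell")
    return (np.arange(n_sc) + 0.5) / n_sc


def knockin_labels(n_rgc: int, genotype: Genotype) -> np.ndarray:
    """Population label per RGC: ``"ki"`` for every second RGC, else ``"wt"``.

    With no knock-in all RGCs are labelled ``"wt"``.
    """
    labels = np.array(["wt"] * n_rgc, dtype=object)
    if genotype.epha3_knockin != "none":
        if n_rgc < 2:
            raise ValueError("a knock-in mosaic needs at least two RGCs")
        labels[1::2] = "ki"
    return labels


def build_genotype_retinal_epha(
    genotype: Genotype,
    wildtype_graded: ExponentialGradient = INSITU_GRADED_GRADIENT,
    knockin_increment: float = EPHA3_INCREMENT,
    epha4_unit: float = EPHA4_UNIT,
    n_rgc: int = 240,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-RGC retinal EphA concentrations and population labels.

    Each RGC ``i`` at position ``x_i`` carries::

        graded(x_i) + epha4_dosage * epha4_unit + level * knockin_increment

    where ``level`` is 1 for knocked-in RGCs of homozygotes, 1/2 for
    heterozygotes, and 0 otherwise; only every second RGC is knocked in.

    Returns
    -------
    epha : (n_rgc,) float array
    labels : (n_rgc,) object array of ``"wt"`` / ``"ki"``
    """
    if n_rgc < 2:
        raise ValueError("n_rgc must be >= 2")
    if knockin_increment < 0 or epha4_unit < 0:
        raise ValueError("increments must be >= 0")
    x = rgc_positions(n_rgc)
    epha = wildtype_graded(x) + genotype.epha4_dosage * epha4_unit
    labels = knockin_labels(n_rgc, genotype)
    level = KNOCKIN_LEVELS[genotype.epha3_knockin]
    epha = epha + np.where(labels == "ki", level * knockin_increment, 0.0)
    return epha, labels


def apply_math5(
    genotype: Genotype,
    n_rgc_wildtype: int,
    seed: Optional[int] = None,
    mode: str = "systematic",
) -> np.ndarray:
    """Indices of surviving RGCs for a reduced-complement genotype.

    ``round(fraction * n)`` RGCs are kept.  The default ``"systematic"``
    mode spreads them evenly across the retinal axis (every k-th RGC,
    offset to centre the sample), matching "roughly evenly distributed";
    ``"random"`` draws a uniform subsample under ``seed``.
    """
    frac = genotype.rgc_survival_fraction
    n_keep = int(round(frac * n_rgc_wildtype))
    if n_keep < 1:
        raise ValueError(
            f"survival fraction {frac} of {n_rgc_wildtype} RGCs leaves none"
        )
    if mode == "systematic":
        # n_keep points at the centres of n_keep equal blocks of indices
        idx = np.floor((np.arange(n_keep) + 0.5) * n_rgc_wildtype / n_keep)
        return idx.astype(int)
    if mode == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(n_rgc_wildtype, size=n_keep, replace=False))
    raise ValueError(f"unknown subsampling mode {mode!r}")
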