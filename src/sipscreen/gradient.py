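"""Buoyant-density gradients and fraction handling for rRNA-SIP.

An isopycnic CsTFA gradient is collected as 13 fractions of decreasing
buoyant density (g ml^-1).  Incorporation of a heavy isotope shifts a
taxon's rRNA toward higher density, so downstream analysis compares a
representative "heavy" and "light" fraction per gradient.  This module
represents fractions and gradients, classifies fractions into the
heavy/light density windows, selects the representative fraction per
window, and computes the quantitative distribution of rRNA copies
(RT-qPCR) across a gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FractionRecord",
    "GradientMeta",
    "GradientSet",
    "DensityWindow",
    "HEAVY_WINDOW",
    "LIGHT_WINDOW",
    "WindowConfigError",
    "WindowEmptyError",
    "DegenerateGradientError",
    "classify_fraction",
    "select_representative",
    "copy_distribution",
]

TREATMENTS = ("C13", "C12", "control")
PREYS = ("E_coli", "P_putida", "none")
TARGETS = ("prok_16S", "euk_18S")


class WindowConfigError(ValueError):
    """Raised when density windows are mis-specified (e.g. overlap)."""


class WindowEmptyError(ValueError):
    """Raised when no fraction of a gradient falls inside a density window."""


class DegenerateGradientError(ValueError):
    """Raised when a gradient carries no rRNA copies at all."""


@dataclass(frozen=True)
class DensityWindow:
    """Closed buoyant-density interval [lo, hi] labelled heavy or light."""

    lo: float
    hi: float
    label: str

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise WindowConfigError(
                f"window lo must be < hi, got [{self.lo}, {self.hi}]"
            )
        if self.label not in ("heavy", "light"):
            raise WindowConfigError(f"unknown window label {self.label!r}")

    def contains(self, density: float) -> bool:
        # closed interval: printed density ranges are read inclusively
        return self.lo <= density <= self.hi

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: Default windows: the representative heavy fraction is drawn from
#: 1.851-1.872 g/ml and the light fraction from 1.805-1.819 g/ml.
HEAVY_WINDOW = DensityWindow(1.851, 1.872, "heavy")
LIGHT_WINDOW = DensityWindow(1.805, 1.819, "light")


@dataclass(frozen=True)
class FractionRecord:
    """One collected gradient fraction.

    Parameters
    ----------
    gradient_id : str
        Identifier of the parent gradient.
    fraction_index : int
        1-based collection order (13 fractions per gradient by convention).
    density : float
        Buoyant density in g/ml; must lie in the physically plausible
        open interval (1.70, 2.00).
    copies : float
        16S rRNA transcript copies from RT-qPCR (arbitrary but
        consistent units, >= 0).
    counts : mapping
        taxon id -> non-negative integer read count.
    """

    gradient_id: str
    fraction_index: int
    density: float
    copies: float
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1.70 < self.density < 2.00):
            raise ValueError(
                f"density {self.density} outside plausible range (1.70, 2.00) "
                f"for {self.gradient_id}:{self.fraction_index}"
            )
        if self.fraction_index < 1:
            raise ValueError("fraction_index must be >= 1")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        for taxon, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for taxon {taxon!r}")


@dataclass(frozen=True)
class GradientMeta:
    """Metadata of one gradient: treatment, prey, timepoint, amplicon target."""

    gradient_id: str
    treatment: str
    prey: str
    timepoint: str
    target: str = "prok_16S"

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.prey not in PREYS:
            raise ValueError(f"prey must be one of {PREYS}")
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        # control microcosms received no prey amendment, and vice versa
        if (self.prey == "none") != (self.treatment == "control"):
            raise ValueError(
                f"prey='none' iff treatment='control' violated for "
                f"{self.gradient_id} (treatment={self.treatment}, prey={self.prey})"
            )


@dataclass
class GradientSet:
    """All fractions of one gradient, with its metadata."""

    meta: GradientMeta
    fractions: list[FractionRecord]

    def __post_init__(self) -> None:
        idx = [f.fraction_index for f in self.fractions]
        if len(idx) != len(set(idx)):
            raise ValueError(
                f"duplicate fraction_index in gradient {self.meta.gradient_id}"
            )
        for f in self.fractions:
            if f.gradient_id != self.meta.gradient_id:
                raise ValueError(
                    f"fraction {f.gradient_id}:{f.fraction_index} does not "
                    f"belong to gradient {self.meta.gradient_id}"
                )


def _check_windows(heavy: DensityWindow, light: DensityWindow) -> None:
    if heavy.lo <= light.hi and light.lo <= heavy.hi:
        raise WindowConfigError(
            f"heavy {heavy.lo}-{heavy.hi} and light {light.lo}-{light.hi} "
            "windows overlap"
        )


def classify_fraction(
    f: FractionRecord,
    heavy: DensityWindow = HEAVY_WINDOW,
    light: DensityWindow = LIGHT_WINDOW,
) -> str:
    """Classify a fraction as ``'heavy'``, ``'light'`` or ``'neither'``.

    Membership is tested on closed intervals.  Overlapping windows raise
    :class:`WindowConfigError`.
    """
    _check_windows(heavy, light)
    if heavy.contains(f.density):
        return "heavy"
    if light.contains(f.density):
        return "light"
    return "neither"


def select_representative(
    fractions: list[FractionRecord],
    window: DensityWindow,
    policy: str = "max_copies",
) -> FractionRecord:
    """Select the representative fraction inside a density window.

    Policies
    --------
    ``max_copies`` (default)
        The in-window fraction carrying the most rRNA copies; ties broken
        by density closest to the window midpoint, then lowest
        fraction_index.  The fraction with the most rRNA is the most
        informative for sequencing.
    ``mid_density``
        The in-window fraction whose density is closest to the window
        midpoint (ties by lowest fraction_index); offered for sensitivity
        analysis.

    Raises
    ------
    WindowEmptyError
        If no fraction falls inside the window.
    """
    if policy not in ("max_copies", "mid_density"):
        raise ValueError(f"unknown policy {policy!r}")
    in_window = [f for f in fractions if window.contains(f.density)]
    if not in_window:
        gid = fractions[0].gradient_id if fractions else "<empty>"
        raise WindowEmptyError(
            f"no fraction of gradient {gid} falls in the {window.label} "
            f"window [{window.lo}, {window.hi}]"
        )
    mid = window.midpoint
    if policy == "max_copies":
        key = lambda f: (-f.copies, abs(f.density - mid), f.fraction_index)
    else:
        key = lambda f: (abs(f.density - mid), f.fraction_index)
    return min(in_window, key=key)


def copy_distribution(fractions: list[FractionRecord]) -> dict[int, float]:
    """Proportion of total rRNA copies per fraction, keyed by fraction_index.

    The result is ordered by fraction_index and sums to 1 (within 1e-12).
    An all-zero gradient raises :class:`DegenerateGradientError`.
    """
    ordered = sorted(fractions, key=lambda f: f.fraction_index)
    total = math.fsum(f.copies for f in ordered)
    if total <= 0:
        gid = ordered[0].gradient_id if ordered else "<empty>"
        raise DegenerateGradientError(
            f"gradient {gid} carries zero total rRNA copies"
        )
    return {f.fraction_index: f.copies / total for f in ordered}
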