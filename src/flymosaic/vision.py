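"""Categorical fly color-opponency model and detectability statistics.

Stimuli are mapped into a 2-D opponency plane built from two photoreceptor
pairs (R7p vs R8p and R7y vs R8y).  Each receptor's quantum catch is first
divided by its catch from the adapting background (von Kries adaptation), so
the background itself sits at the plane's origin; the hyperbolic excitation
transform e = q/(q+1) then bounds each coordinate in (-1, 1).  The four
quadrants of the plane act as discrete color categories, while Euclidean
distance from the origin measures detectability against the background and
distance between cloud centroids measures discriminability of two stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import AdaptationError, GridMismatchError, InputError
from .spectra import RECEPTOR_NAMES, ReceptorSet, Spectrum

#: Coordinates within this distance of an axis are labeled "boundary".
BOUNDARY_TOL = 1e-12

QUADRANTS = ("p+y+", "p+y-", "p-y+", "p-y-")

#: Minimum discrimination distances measured behaviorally for hoverflies,
#: available only for two quadrants; verdicts elsewhere are "unknown".
DEFAULT_THRESHOLDS: Dict[str, float] = {"p-y-": 0.021, "p+y-": 0.059}


@dataclass(frozen=True)
class QuantumCatches:
    """Relative photon catches of the four receptors."""

    q_R7p: float
    q_R7y: float
    q_R8p: float
    q_R8y: float

    def __post_init__(self) -> None:
        for name in RECEPTOR_NAMES:
            v = getattr(self, f"q_{name}")
            if not np.isfinite(v) or v < 0:
                raise InputError(f"quantum catch q_{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.q_R7p, self.q_R7y, self.q_R8p, self.q_R8y])


@dataclass(frozen=True)
class VisionPoint:
    """A stimulus in the opponency plane."""

    x: float
    y: float
    quadrant: str
    dist_origin: float


@dataclass
class SpeciesCloud:
    """All modeled points for one species (one per image/replicate)."""

    species: str
    points: List[VisionPoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise InputError(f"species cloud {self.species!r} is empty")

    @property
    def centroid(self) -> Tuple[float, float]:
        xs = np.array([p.x for p in self.points])
        ys = np.array([p.y for p in self.points])
        return float(xs.mean()), float(ys.mean())


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# Quantum catch integration
# ---------------------------------------------------------------------------

def quantum_catch(
    reflectance: Spectrum,
    illuminant: Spectrum,
    receptors: ReceptorSet,
) -> QuantumCatches:
    """Per-receptor catch Q_r = integral of R(l) I(l) S_r(l) dl (trapezoid).

    All spectra must already share one wavelength grid; there is no silent
    resampling.
    """
    grid = reflectance.grid
    if illuminant.grid != grid or receptors.grid != grid:
        raise GridMismatchError(
            "reflectance, illuminant, and receptor sensitivities must share a grid"
        )
    wl = grid.wavelengths
    base = reflectance.values * illuminant.values
    catches = {
        name: float(np.trapezoid(base * receptors[name].values, wl))
        for name in RECEPTOR_NAMES
    }
    return QuantumCatches(
        q_R7p=catches["R7p"], q_R7y=catches["R7y"],
        q_R8p=catches["R8p"], q_R8y=catches["R8y"],
    )


def mean_catches(catches: Sequence[QuantumCatches]) -> QuantumCatches:
    """Receptor-wise arithmetic mean of several catch sets."""
    if not catches:
        raise InputError("need at least one quantum-catch set")
    arr = np.mean([c.as_array() for c in catches], axis=0)
    return QuantumCatches(q_R7p=arr[0], q_R7y=arr[1], q_R8p=arr[2], q_R8y=arr[3])


# ---------------------------------------------------------------------------
# Opponency mapping
# ---------------------------------------------------------------------------

def classify_quadrant(x: float, y: float, tol: float = BOUNDARY_TOL) -> str:
    """Quadrant by coordinate signs; near-zero coordinates are "boundary"."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise InputError("coordinates must be finite")
    if abs(x) <= tol or abs(y) <= tol:
        return "boundary"
    return f"p{'+' if x > 0 else '-'}y{'+' if y > 0 else '-'}"


def troje_point(
    stimulus: QuantumCatches,
    background: QuantumCatches,
    transform: str = "hyperbolic",
) -> VisionPoint:
    """Map a stimulus into the opponency plane, adapted to ``background``.

    Relative catches q_r = Q_r(stimulus) / Q_r(background); excitations
    e_r = q_r / (q_r + 1); coordinates x = e_R7p - e_R8p, y = e_R7y - e_R8y.
    The background maps to (0, 0) exactly.  ``transform="linear"`` skips the
    hyperbolic step (x = q_R7p - q_R8p) for sensitivity analysis; it no longer
    bounds coordinates.
    """
    bg = background.as_array()
    if np.any(bg <= 0):
        raise AdaptationError("background quantum catches must all be positive")
    q = stimulus.as_array() / bg
    if transform == "hyperbolic":
        e = q / (q + 1.0)
    elif transform == "linear":
        e = q / 2.0  # scaled so the background still maps to the origin
    else:
        raise InputError(f"unknown excitation transform {transform!r}")
    # order in as_array: R7p, R7y, R8p, R8y
    x = float(e[0] - e[2])
    y = float(e[1] - e[3])
    return VisionPoint(x=x, y=y, quadrant=classify_quadrant(x, y),
                       dist_origin=float(np.hypot(x, y)))


def region_mean_point(
    region_spectra: Sequence[Spectrum],
    background: Spectrum,
    illuminant: Spectrum,
    receptors: ReceptorSet,
    transform: str = "hyperbolic",
) -> VisionPoint:
    """Model one image: catches per floret region, averaged, then adapted.

    Quantum catches are computed for each measured region of the ray florets,
    averaged per receptor across regions, and the mean catch is mapped against
    the background catch of the same image.
    """
    if not region_spectra:
        raise InputError("need at least one region spectrum")
    stim = mean_catches([quantum_catch(r, illuminant, receptors) for r in region_spectra])
    bg = quantum_catch(background, illuminant, receptors)
    return troje_point(stim, bg, transform=transform)


# ---------------------------------------------------------------------------
# Detectability and discriminability
# ---------------------------------------------------------------------------

def centroid_distance(a: SpeciesCloud, b: SpeciesCloud) -> float:
    """Euclidean distance between two species centroids in the plane."""
    ax, ay = a.centroid
    bx, by = b.centroid
    return float(np.hypot(ax - bx, ay - by))


def detectability_verdict(
    point: VisionPoint,
    thresholds: Dict[str, float] | None = None,
) -> str:
    """Compare distance-from-origin with the quadrant's threshold.

    Returns ``detectable`` when dist >= threshold, ``not_detectable`` when
    below, and ``unknown`` when no threshold exists for the point's quadrant
    (including boundary points).
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    thr = thresholds.get(point.quadrant)
    if thr is None:
        return "unknown"
    if thr <= 0:
        raise InputError(f"threshold for {point.quadrant} must be positive")
    return "detectable" if point.dist_origin >= thr else "not_detectable"


def welch_t(
    distances_a: Sequence[float],
    distances_b: Sequence[float],
    one_sided: bool = False,
) -> WelchResult:
    """Welch's unequal-variance t-test on two samples of distances.

    Two-sided by default; ``one_sided=True`` halves the p-value in the
    direction of ``mean(a) > mean(b)`` (used for the directional question of
    whether flowers contrast more against their native soil).
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("Welch's t-test needs at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise InputError("both samples have zero variance but different means")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    if one_sided:
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)
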