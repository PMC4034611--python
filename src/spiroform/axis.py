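"""The ontogeny axis: the unified arc-length reference frame of a shell.

The ontogeny axis is the 3D space curve traced by the aperture's point of
maximum growth (the anterior landmark) from the protoconch–teleoconch
boundary to the current lip.  Cumulative arc length *s* along this curve, in
millimetres, is the common coordinate onto which every other measurement —
growth increments, aperture perimeters and shapes, rotation angles, rib
positions — is projected.  The axis also carries the positions of the
commarginal ribs (serially homologous landmarks) and the boundaries of the
three whorl-growth phases: the regularly coiled *spire*, the narrowed
*constriction*, and the detached *tuba*.

Growth rate is measured by capture–mark–recapture: a rib is marked in the
field, the animal is released, and the arc length added between the mark and
the new lip over the experiment duration gives mm/day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

logger = logging.getLogger(__name__)

PHASE_SPIRE = "spire"
PHASE_CONSTRICTION = "constriction"
PHASE_TUBA = "tuba"


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative chordal arc length of an ordered 3D polyline.

    Parameters
    ----------
    points : (n, 3) array
        Ordered digitized coordinates in mm, ``n >= 2``.

    Returns
    -------
    (n,) array with ``s[0] = 0`` and ``s[i] - s[i-1]`` equal to the Euclidean
    chord between consecutive points, so ``s[-1]`` is the total length.

    Raises
    ------
    DegenerateGeometryError
        If consecutive points coincide (a degenerate digitization).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValidationError("need an (n, 3) array with n >= 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite coordinates in polyline")
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chords == 0.0):
        i = int(np.flatnonzero(chords == 0.0)[0])
        raise DegenerateGeometryError(
            f"duplicate consecutive points at index {i}/{i + 1}"
        )
    return np.concatenate([[0.0], np.cumsum(chords)])


def project_arc_length_2d(points: np.ndarray, view_direction: Sequence[float]) -> float:
    """Arc length of the polyline after orthographic projection.

    Emulates measuring whorl length on a photograph taken along
    ``view_direction``: points are projected onto the plane normal to the
    view vector and chord lengths are summed.  By the Cauchy projection
    inequality the result never exceeds the 3D arc length.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(view_direction, dtype=float)
    nv = np.linalg.norm(v)
    if not np.isfinite(nv) or nv == 0.0:
        raise ValidationError("view direction must be a non-zero vector")
    v = v / nv
    proj = pts - np.outer(pts @ v, v)
    chords = np.linalg.norm(np.diff(proj, axis=0), axis=1)
    return float(np.sum(chords))


@dataclass
class OntogenyAxis:
    """Ordered polyline with cumulative arc length, rib marks and phase bounds.

    Attributes
    ----------
    points : (n, 3) float array, mm.
    s : (n,) float array, cumulative arc length, ``s[0] = 0`` at the
        protoconch–teleoconch boundary.
    rib_positions : sorted arc-length coordinates (mm) of commarginal ribs.
    phase_bounds : ``(spire_end, constriction_end)`` in mm, or ``None``.
        Phases are half-open: spire ``[0, spire_end)``, constriction
        ``[spire_end, constriction_end)``, tuba ``[constriction_end, s[-1]]``.
    handedness : ``"dextral"`` or ``"sinistral"``.
    """

    points: np.ndarray
    s: np.ndarray = None  # type: ignore[assignment]
    rib_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    phase_bounds: tuple[float, float] | None = None
    handedness: str = "dextral"
    shell_id: str = "shell"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.s is None:
            self.s = cumulative_arc_length(self.points)
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape[0] != self.points.shape[0]:
            raise ValidationError("s and points must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValidationError("s must be strictly increasing")
        self.rib_positions = np.sort(np.asarray(self.rib_positions, dtype=float))
        if self.rib_positions.size and (
            self.rib_positions[0] < -1e-9
            or self.rib_positions[-1] > self.total_length + 1e-9
        ):
            raise ValidationError("rib positions outside [0, total length]")
        if self.handedness not in ("dextral", "sinistral"):
            raise ValidationError(f"unknown handedness {self.handedness!r}")
        if self.phase_bounds is not None:
            a, b = self.phase_bounds
            if not (0.0 < a < b):
                raise ValidationError("phase bounds must satisfy 0 < spire_end < constriction_end")

    @property
    def total_length(self) -> float:
        return float(self.s[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linearly interpolated axis point at arc-length coordinate ``s``."""
        s = float(np.clip(s, self.s[0], self.s[-1]))
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, self.s, self.points[:, k])
        return out

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit forward tangent at ``s`` from the bracketing chord."""
        i = int(np.clip(np.searchsorted(self.s, s), 1, len(self.s) - 1))
        d = self.points[i] - self.points[i - 1]
        return d / np.linalg.norm(d)

    def phase_of(self, s: float) -> str:
        if self.phase_bounds is None:
            raise ValidationError("axis has no phase bounds")
        spire_end, constriction_end = self.phase_bounds
        if s < spire_end:
            return PHASE_SPIRE
        if s < constriction_end:
            return PHASE_CONSTRICTION
        return PHASE_TUBA

    def mirrored(self, plane_normal: Sequence[float] = (0.0, 0.0, 1.0)) -> "OntogenyAxis":
        """Reflect the axis through a plane through the origin.

        Reflection swaps coiling handedness and negates torsion pointwise.
        """
        n = np.asarray(plane_normal, dtype=float)
        n = n / np.linalg.norm(n)
        pts = self.points - 2.0 * np.outer(self.points @ n, n)
        return replace(
            self,
            points=pts,
            s=self.s.copy(),
            handedness="sinistral" if self.handedness == "dextral" else "dextral",
        )


def position_of_mark(axis: OntogenyAxis, rib_index: int) -> float:
    """Arc-length coordinate of the ``rib_index``-th commarginal rib."""
    n = axis.rib_positions.size
    if not (0 <= rib_index < n):
        raise IndexError(f"rib index {rib_index} out of range for {n} ribs")
    return float(axis.rib_positions[rib_index])


def compute_growth_rate(s_start: float, s_end: float, duration: float) -> float:
    """Growth rate (mm/day) as arc length added over the experiment duration."""
    if not np.isfinite(duration) or duration <= 0:
        raise ValidationError("duration must be positive")
    if s_end < s_start:
        raise ValidationError(
            "negative arc-length increment (s_end < s_start): likely mark misidentification"
        )
    return (s_end - s_start) / duration


@dataclass(frozen=True)
class GrowthRecord:
    """One individual's mark–recapture growth increment."""

    individual_id: str
    s_start: float
    s_end: float
    duration: float
    plot_id: str = ""
    phase: str | None = None
    rate: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rate = compute_growth_rate(self.s_start, self.s_end, self.duration)
        if self.rate is None:
            object.__setattr__(self, "rate", rate)
        elif abs(self.rate - rate) > 1e-9 * max(1.0, rate):
            raise ValidationError("stored rate inconsistent with (s_end - s_start)/duration")


class PhasePartition(NamedTuple):
    spire: list[GrowthRecord]
    tuba: list[GrowthRecord]
    excluded: list[GrowthRecord]


def partition_by_phase(
    records: Sequence[GrowthRecord], phase_bounds: tuple[float, float]
) -> PhasePartition:
    """Split growth records into spire and tuba groups by pre-experiment position.

    Membership is decided by ``s_start`` (the mark position before the
    experiment).  Records starting inside the constriction interval belong to
    neither analysed phase and are returned in ``excluded`` (and logged);
    the two-phase correlation analysis uses only spire and tuba.
    """
    spire_end, constriction_end = phase_bounds
    if not spire_end < constriction_end:
        raise ValidationError("phase bounds must be ordered")
    spire, tuba, excluded = [], [], []
    for rec in records:
        if rec.s_start < spire_end:
            spire.append(rec)
        elif rec.s_start < constriction_end:
            excluded.append(rec)
        else:
            tuba.append(rec)
    if excluded:
        logger.warning(
            "excluded %d growth record(s) starting inside the constriction interval",
            len(excluded),
        )
    return PhasePartition(spire, tuba, excluded)
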