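"""Aperture growth trajectory: segment rotations and axis curvature/torsion.

Two complementary quantifications of how the animal reorients while
secreting shell:

*Discrete rotations.*  The shell is cut into segments between successive
commarginal ribs.  Each segment carries an anatomical frame (x̂
anteroposterior toward the anterior landmark, ẑ the aperture-plane normal
oriented along local growth, ŷ = ẑ × x̂).  For each consecutive pair the
scene is rigidly aligned so the NEW segment's frame coincides with the
global axes, the OLD segment is translated so the anterior landmarks meet,
and the relative reorientation is factored as sequential rotations about
the global x, then y, then z axes (degrees).  θx > 0 means the animal tilts
right (anterior view); θz > 0 anticlockwise rotation in dorsal view; θy is
the advance of the growth direction.

*Continuous curve geometry.*  Curvature κ ≥ 0 and signed torsion τ of the
ontogeny axis are estimated at every sample point by weighted local
polynomial fits (degree 2 for κ, degree 3 for τ) in the cumulative
chord-length parameter, with tricube weights over a window of up to
``window`` points per side (default 100).  κ = |r'×r''|/|r'|³ and
τ = (r'×r'')·r'''/|r'×r''|²; τ > 0 is right-handed (dextral) coiling,
κ = 0 an orthocone, τ = 0 planispiral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .axis import OntogenyAxis
from .efa import ApertureOutline
from .errors import DegenerateGeometryError, ValidationError

logger = logging.getLogger(__name__)

SUPPORT_FULL = "full"
SUPPORT_SHRUNKEN = "shrunken"
SUPPORT_LOW = "low"


@dataclass
class ShellSegment:
    """One inter-rib shell segment with its anatomical frame.

    ``frame`` has rows (x̂, ŷ, ẑ) — a right-handed orthonormal triad in
    world coordinates.  ``anterior_point`` is the anterior landmark of the
    leading (most recently grown) aperture of the segment.
    """

    segment_id: str
    points: np.ndarray
    anterior_point: np.ndarray
    frame: np.ndarray
    s_start: float
    s_end: float

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        self.anterior_point = np.asarray(self.anterior_point, dtype=float)
        if self.frame.shape != (3, 3):
            raise ValidationError("frame must be 3x3 with rows x,y,z")
        if not np.allclose(self.frame @ self.frame.T, np.eye(3), atol=1e-9):
            raise ValidationError("frame is not orthonormal to 1e-9")
        if np.linalg.det(self.frame) < 0:
            raise ValidationError("frame is left-handed")


@dataclass(frozen=True)
class RotationTriple:
    """Sequential rotation angles (degrees, about global x then y then z)
    carrying one segment's frame onto the next, after Fig-2-style alignment."""

    theta_x: float
    theta_y: float
    theta_z: float
    old_id: str
    new_id: str
    s_position: float
    gimbal_degenerate: bool = False


def build_frame(
    outline: ApertureOutline, reference_direction: Sequence[float]
) -> np.ndarray:
    """Anatomical frame of an aperture outline.

    x̂ points from the outline centroid to the anterior landmark; ẑ is the
    component of the outline-plane normal orthogonal to x̂, sign-matched to
    ``reference_direction`` (the local growth direction); ŷ = ẑ × x̂.
    """
    pts = outline.points
    centroid = pts.mean(axis=0)
    x = pts[outline.anterior_index] - centroid
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise DegenerateGeometryError("anterior landmark coincides with centroid")
    x = x / nx
    # plane normal = least-variance direction of the centred points
    _, svals, vh = np.linalg.svd(pts - centroid, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1.0):
        raise DegenerateGeometryError("outline is degenerate (collinear)")
    normal = vh[2]
    z = normal - (normal @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise DegenerateGeometryError("aperture normal parallel to anteroposterior axis")
    z = z / nz
    ref = np.asarray(reference_direction, dtype=float)
    if z @ ref < 0:
        z = -z
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def segment_shell(
    axis: OntogenyAxis, outlines: Sequence[ApertureOutline]
) -> list[ShellSegment]:
    """One segment per inter-rib interval, frames from each leading aperture.

    Outlines are assigned to intervals ``[r_i, r_{i+1})`` by their axis
    position (the last interval is closed above); the outline closest to the
    leading rib supplies the segment's aperture plane and anterior landmark.
    An interval containing no outline is an error — the sampling does not
    resolve that segment.
    """
    ribs = axis.rib_positions
    if ribs.size < 2:
        raise ValidationError("need at least 2 rib positions to segment the shell")
    for o in outlines:
        if o.s_position is None:
            raise ValidationError(f"outline {o.outline_id} has no s_position")
    s_pos = np.array([o.s_position for o in outlines])
    order = np.argsort(s_pos, kind="mergesort")
    segments = []
    for i in range(len(ribs) - 1):
        lo_s, hi_s = ribs[i], ribs[i + 1]
        last = i == len(ribs) - 2
        mask = (s_pos >= lo_s) & ((s_pos <= hi_s) if last else (s_pos < hi_s))
        members = [k for k in order if mask[k]]
        if not members:
            raise ValidationError(
                f"rib interval [{lo_s:.3f}, {hi_s:.3f}) contains no sample outline"
            )
        leading = outlines[members[-1]]
        growth_dir = axis.point_at(hi_s) - axis.point_at(lo_s)
        frame = build_frame(leading, growth_dir)
        pts = np.vstack([outlines[k].points for k in members])
        segments.append(
            ShellSegment(
                segment_id=f"seg{i:03d}",
                points=pts,
                anterior_point=leading.points[leading.anterior_index],
                frame=frame,
                s_start=float(lo_s),
                s_end=float(hi_s),
            )
        )
    return segments


def decompose_rotation(
    old: ShellSegment, new: ShellSegment, gimbal_tol_deg: float = 0.1
) -> RotationTriple:
    """Factor the OLD→NEW reorientation into x, then y, then z rotations.

    The scene is rigidly transformed so NEW's frame coincides with the
    global axes (the translation aligning the anterior landmarks has no
    effect on the angles).  The relative rotation M = E_oldᵀ E_new (frames
    as column matrices) is factored extrinsically as M = Rz(θz) Ry(θy)
    Rx(θx); re-composing the reported angles in x→y→z order carries OLD's
    frame onto NEW's.  Near θy = ±90° the factorization is degenerate: the
    triple is flagged and the x-angle pinned to 0 (the standard tie-break).
    """
    E_old = old.frame.T
    E_new = new.frame.T
    M = E_old.T @ E_new
    rot = Rotation.from_matrix(M)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock
        tx, ty, tz = rot.as_euler("xyz", degrees=True)
    gimbal = bool(abs(abs(ty) - 90.0) < gimbal_tol_deg)
    return RotationTriple(
        theta_x=float(tx),
        theta_y=float(ty),
        theta_z=float(tz),
        old_id=old.segment_id,
        new_id=new.segment_id,
        s_position=new.s_start,
        gimbal_degenerate=gimbal,
    )


def rotation_profile(segments: Sequence[ShellSegment]) -> list[RotationTriple]:
    """Rotation triples for every consecutive OLD→NEW segment pair."""
    if len(segments) < 2:
        raise ValidationError("need at least 2 segments")
    return [
        decompose_rotation(segments[i], segments[i + 1])
        for i in range(len(segments) - 1)
    ]


@dataclass
class CurvatureTorsionProfile:
    """Per-point curvature and torsion along the axis with support flags."""

    s: np.ndarray
    kappa: np.ndarray
    tau: np.ndarray
    support: np.ndarray          # strings: full / shrunken / low
    degenerate: np.ndarray       # True where |r'×r''| ~ 0 (tau reported 0)

    @property
    def full_support(self) -> np.ndarray:
        return self.support == SUPPORT_FULL


def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3


def estimate_curvature_torsion(
    axis: OntogenyAxis, window: int = 100, min_window: int = 10
) -> CurvatureTorsionProfile:
    """Weighted local-polynomial curvature and torsion of the ontogeny axis.

    At each sample point a window of up to ``window`` points per side is
    taken; each coordinate is fitted by weighted least squares in the local
    cumulative-chord parameter (tricube weights), degree 2 for curvature and
    degree 3 for torsion, and the centre derivatives give κ and τ.  Boundary
    points use shrunken (asymmetric) windows and are flagged; windows with
    fewer than ``min_window`` points on a side are flagged low-support.
    Collinear windows give κ = 0 and τ = 0 with the degeneracy flag set.
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    pts, s = axis.points, axis.s
    n = len(s)
    if n < 2 * min_window + 1:
        raise ValidationError("axis too short for the requested window")
    kappa = np.empty(n)
    tau = np.empty(n)
    support = np.empty(n, dtype=object)
    degenerate = np.zeros(n, dtype=bool)
    eps = np.finfo(float).eps
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        u = s[lo:hi] - s[i]
        span = max(-u[0], u[-1])
        w = np.sqrt(_tricube(u / (span * 1.000001)))
        P = pts[lo:hi] * w[:, None]
        V = np.vander(u, N=4, increasing=True) * w[:, None]  # [1, u, u^2, u^3]
        # quadratic fit -> curvature
        c2, *_ = np.linalg.lstsq(V[:, :3], P, rcond=None)
        r1q, r2q = c2[1], 2.0 * c2[2]
        crossq = np.cross(r1q, r2q)
        n1 = np.linalg.norm(r1q)
        kappa[i] = np.linalg.norm(crossq) / max(n1**3, eps)
        # cubic fit -> torsion
        c3, *_ = np.linalg.lstsq(V, P, rcond=None)
        r1, r2, r3 = c3[1], 2.0 * c3[2], 6.0 * c3[3]
        cross = np.cross(r1, r2)
        denom = cross @ cross
        scale = max(np.linalg.norm(r1), eps)
        if denom < (1e-10 * scale**2) ** 2:
            tau[i] = 0.0
            degenerate[i] = True
        else:
            tau[i] = float(cross @ r3) / denom
        left, right = i - lo, hi - 1 - i
        if left == window and right == window:
            support[i] = SUPPORT_FULL
        elif min(left, right) >= min_window:
            support[i] = SUPPORT_SHRUNKEN
        else:
            support[i] = SUPPORT_LOW
    n_low = int(np.sum(support == SUPPORT_LOW))
    if n_low:
        logger.info("%d low-support boundary points in curvature/torsion profile", n_low)
    return CurvatureTorsionProfile(
        s=s.copy(), kappa=kappa, tau=tau, support=np.asarray(support), degenerate=degenerate
    )


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Least-squares rotation aligning point cloud P onto Q (validation aid).

    Provided to cross-check the frame-based alignment on congruent point
    sets; segments of a real shell are not congruent, so frame alignment is
    the primary route.
    """
    P = np.asarray(P, float) - np.mean(P, axis=0)
    Q = np.asarray(Q, float) - np.mean(Q, axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T
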