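"""Synthetic shells with analytic ground truth.

Every downstream stage of the pipeline is exercised against data generated
here: a logarithmic helicospiral spire (Raup-style, closed-form curvature
and torsion), an optional constriction/tuba deformation that smoothly
reverses the torsion sign (mimicking the animal rotating in the opposite
direction during open coiling), aperture outline sequences with planted
perimeters and shapes, commarginal rib series following a planted spacing
trend, and capture–mark–recapture growth records from a planted rate
function.

Parametric spire.  With expansion rate ``alpha`` per radian, initial whorl
radius ``r0`` and translation factor ``c``, the dextral curve is::

    x = r0 e^(alpha t) cos t,  y = -r0 e^(alpha t) sin t,  z = -(c/alpha) e^(alpha t)

(for ``alpha = 0`` a circular helix with ``z = -c t``; sinistral flips the
sign of y).  Speed, arc length and the Frenet apparatus follow in closed
form, so the truth callbacks are exact functions of arc length s.

All randomness flows from one integer seed; sub-generators draw from
documented child streams so partial pipelines stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .axis import GrowthRecord, OntogenyAxis, cumulative_arc_length
from .efa import ApertureOutline, perimeter as _perimeter
from .errors import ValidationError
from .stats import RibSeries

__all__ = [
    "HelicospiralParams",
    "PhaseSchedule",
    "SyntheticShellTruth",
    "generate_helicospiral",
    "apply_phase_schedule",
    "generate_aperture_sequence",
    "generate_rib_positions",
    "simulate_cmr",
    "draw_growth_records",
    "simulate_study",
    "SimulatedStudy",
]


@dataclass(frozen=True)
class HelicospiralParams:
    """Parameters of the logarithmic helicospiral spire.

    Defaults are illustrative, chosen to give a ~17 mm ontogeny axis over
    ~5 whorls with whorl radius growing to ~1 mm — the general scale of a
    3 x 3.5 mm diplommatinid shell.  They are not species measurements.
    """

    r0: float = 0.2         # initial whorl radius, mm
    alpha: float = 0.05     # exponential expansion rate per radian
    c: float = 0.0175       # translation factor per radian, mm at theta = 0
    theta_max: float = 33.5  # total rotation, radians
    ds: float = 0.01        # target arc-length sampling step, mm
    handedness: str = "dextral"

    def __post_init__(self) -> None:
        vals = (self.r0, self.alpha, self.c, self.theta_max, self.ds)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("non-finite helicospiral parameter")
        if self.r0 <= 0 or self.ds <= 0 or self.theta_max <= 0:
            raise ValidationError("r0, ds and theta_max must be positive")
        if self.alpha < 0 or self.c < 0:
            raise ValidationError("alpha and c must be non-negative")
        if self.handedness not in ("dextral", "sinistral"):
            raise ValidationError(f"unknown handedness {self.handedness!r}")

    # -- closed-form kinematics -------------------------------------------
    @property
    def _h(self) -> float:
        """Sign of the y coordinate: -1 dextral (right-handed), +1 sinistral."""
        return -1.0 if self.handedness == "dextral" else 1.0

    @property
    def _speed0(self) -> float:
        """|dp/dtheta| at theta = 0 (speed grows as e^(alpha theta))."""
        if self.alpha > 0:
            w = self.c / self.alpha
            return float(np.sqrt(self.alpha**2 * (self.r0**2 + w**2) + self.r0**2))
        return float(np.sqrt(self.r0**2 + self.c**2))

    def arc_length(self, theta: np.ndarray | float) -> np.ndarray | float:
        if self.alpha > 0:
            return self._speed0 * (np.expm1(self.alpha * np.asarray(theta, float))) / self.alpha
        return self._speed0 * np.asarray(theta, float)

    def theta_of_s(self, s: np.ndarray | float) -> np.ndarray | float:
        if self.alpha > 0:
            return np.log1p(self.alpha * np.asarray(s, float) / self._speed0) / self.alpha
        return np.asarray(s, float) / self._speed0

    def derivatives(self, theta: np.ndarray | float):
        """Position and first three theta-derivatives, each (..., 3)."""
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        r0, al, h = self.r0, self.alpha, self._h
        ct, st = np.cos(th), np.sin(th)
        if al > 0:
            w = -self.c / al
            e = np.exp(al * th)[:, None]
            f0 = np.stack([r0 * ct, h * r0 * st, np.full_like(th, w)], axis=1)
            f1 = np.stack([-r0 * st, h * r0 * ct, np.zeros_like(th)], axis=1)
            f2 = np.stack([-r0 * ct, -h * r0 * st, np.zeros_like(th)], axis=1)
            f3 = -f1
            p = e * f0
            p1 = e * (al * f0 + f1)
            p2 = e * (al**2 * f0 + 2 * al * f1 + f2)
            p3 = e * (al**3 * f0 + 3 * al**2 * f1 + 3 * al * f2 + f3)
        else:
            cc = self.c
            p = np.stack([r0 * ct, h * r0 * st, -cc * th], axis=1)
            p1 = np.stack([-r0 * st, h * r0 * ct, np.full_like(th, -cc)], axis=1)
            p2 = np.stack([-r0 * ct, -h * r0 * st, np.zeros_like(th)], axis=1)
            p3 = np.stack([r0 * st, -h * r0 * ct, np.zeros_like(th)], axis=1)
        return p, p1, p2, p3


def _like_input(out: np.ndarray, s) -> np.ndarray | float:
    """Return a scalar for scalar input, the array otherwise."""
    if np.ndim(s) == 0:
        return float(np.asarray(out).ravel()[0])
    return np.asarray(out)


def _frenet_from_derivs(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """kappa, tau and (T, N, B) from parametric derivatives (vectorized)."""
    cross = np.cross(p1, p2)
    n1 = np.linalg.norm(p1, axis=-1)
    nc = np.linalg.norm(cross, axis=-1)
    kappa = nc / n1**3
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(nc > 0, np.einsum("...i,...i", cross, p3) / nc**2, 0.0)
    T = p1 / n1[..., None]
    B = np.where(nc[..., None] > 0, cross / np.where(nc[..., None] > 0, nc[..., None], 1.0), 0.0)
    N = np.cross(B, T)
    return kappa, tau, T, N, B


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase bounds and aperture-perimeter program along the ontogeny axis.

    Defaults follow the three-phase structure of the study species: spire
    0–13 mm, constriction 13–14 mm, tuba 14 mm to the end; perimeter grows
    linearly on the spire (slope 0.166 mm/mm, intercept 0.457 mm), dips by
    ``constriction_perimeter_dip`` across the constriction and regrows at the
    spire slope along the tuba.
    """

    spire_end_s: float = 13.0
    constriction_end_s: float = 14.0
    tuba_end_s: float = 17.0
    constriction_perimeter_dip: float = 0.35
    tuba_rotation_reversal: bool = True
    spire_perimeter_slope: float = 0.166
    spire_perimeter_intercept: float = 0.457

    def __post_init__(self) -> None:
        if not 0.0 < self.spire_end_s < self.constriction_end_s < self.tuba_end_s:
            raise ValidationError("need 0 < spire_end < constriction_end < tuba_end")
        if not 0.0 < self.constriction_perimeter_dip < 1.0:
            raise ValidationError("perimeter dip fraction must be in (0, 1)")

    @property
    def phase_bounds(self) -> tuple[float, float]:
        return (self.spire_end_s, self.constriction_end_s)

    def perimeter_at(self, s: np.ndarray | float) -> np.ndarray | float:
        """Planted aperture perimeter (mm) at ontogeny-axis position s."""
        s = np.asarray(s, dtype=float)
        a, b = self.spire_perimeter_slope, self.spire_perimeter_intercept
        p0 = a * self.spire_end_s + b
        dip_to = (1.0 - self.constriction_perimeter_dip) * p0
        u = np.clip(
            (s - self.spire_end_s) / (self.constriction_end_s - self.spire_end_s), 0.0, 1.0
        )
        ramp = 0.5 * (1.0 - np.cos(np.pi * u))  # 0 -> 1, C1 at both ends
        out = np.where(
            s < self.spire_end_s,
            a * s + b,
            np.where(
                s < self.constriction_end_s,
                p0 + (dip_to - p0) * ramp,
                dip_to + a * (s - self.constriction_end_s),
            ),
        )
        return out if out.ndim else float(out)

    def torsion_ramp(self, s: np.ndarray | float) -> np.ndarray | float:
        """Multiplier applied to spire torsion: +1 on the spire, cosine ramp
        to -1 across the constriction, -1 on the tuba (the rotation reversal)."""
        if not self.tuba_rotation_reversal:
            return np.ones_like(np.asarray(s, dtype=float))
        s = np.asarray(s, dtype=float)
        u = np.clip(
            (s - self.spire_end_s) / (self.constriction_end_s - self.spire_end_s), 0.0, 1.0
        )
        out = np.cos(np.pi * u)
        return out if out.ndim else float(out)


@dataclass
class SyntheticShellTruth:
    """Analytic ground truth attached to a generated shell."""

    axis: OntogenyAxis
    kappa_true: Callable[[np.ndarray], np.ndarray]
    tau_true: Callable[[np.ndarray], np.ndarray]
    frenet_frame: Callable[[float], tuple[np.ndarray, np.ndarray, np.ndarray]]
    schedule: PhaseSchedule | None = None
    outline_truth: dict | None = None
    rib_truth: Callable[[np.ndarray], np.ndarray] | None = None
    growth_truth: Callable[[np.ndarray], np.ndarray] | None = None

    def mirrored(self, plane_normal: Sequence[float] = (0.0, 0.0, 1.0)) -> "SyntheticShellTruth":
        """Truth for the mirrored axis: curvature unchanged, torsion negated."""
        kap, tau = self.kappa_true, self.tau_true
        return replace(
            self,
            axis=self.axis.mirrored(plane_normal),
            kappa_true=kap,
            tau_true=lambda s, _t=tau: -np.asarray(_t(s)),
        )


def generate_helicospiral(
    params: HelicospiralParams = HelicospiralParams(),
) -> tuple[OntogenyAxis, SyntheticShellTruth]:
    """Sample the helicospiral at ~uniform arc-length steps with exact truth.

    The curve is sampled at parameter values obtained from the closed-form
    inverse of arc length, so realized chord steps deviate from ``ds`` only
    by the chord-vs-arc correction (well under 10% for smooth settings).
    """
    total = float(params.arc_length(params.theta_max))
    n_steps = int(round(total / params.ds))
    if n_steps < 3:
        raise ValidationError("theta_max too small: fewer than 4 sample points")
    s_grid = np.linspace(0.0, total, n_steps + 1)
    theta = params.theta_of_s(s_grid)
    p, p1, p2, p3 = params.derivatives(theta)
    axis = OntogenyAxis(
        points=p,
        s=cumulative_arc_length(p),
        handedness=params.handedness,
        shell_id="synthetic",
    )

    def kappa_true(s, _p=params):
        k, *_ = _frenet_from_derivs(*_p.derivatives(_p.theta_of_s(np.asarray(s, float)))[1:])
        return _like_input(k, s)

    def tau_true(s, _p=params):
        _, t, *_ = _frenet_from_derivs(*_p.derivatives(_p.theta_of_s(np.asarray(s, float)))[1:])
        return _like_input(t, s)

    def frenet_frame(s, _p=params):
        _, _, T, N, B = _frenet_from_derivs(
            *_p.derivatives(_p.theta_of_s(np.atleast_1d(float(s))))[1:]
        )
        return T[0], N[0], B[0]

    return axis, SyntheticShellTruth(
        axis=axis, kappa_true=kappa_true, tau_true=tau_true, frenet_frame=frenet_frame
    )


def _truncate_axis(axis: OntogenyAxis, s_max: float) -> OntogenyAxis:
    n = int(np.searchsorted(axis.s, s_max + 1e-12, side="right"))
    return replace(
        axis,
        points=axis.points[:n].copy(),
        s=axis.s[:n].copy(),
        rib_positions=axis.rib_positions[axis.rib_positions <= axis.s[n - 1] + 1e-12],
    )


def apply_phase_schedule(
    axis: OntogenyAxis,
    schedule: PhaseSchedule,
    truth: SyntheticShellTruth | None = None,
) -> tuple[OntogenyAxis, SyntheticShellTruth]:
    """Impose phase bounds and (optionally) the tuba rotation reversal.

    Without ``tuba_rotation_reversal`` the geometry is untouched; phase
    bounds are recorded and the axis truncated at ``tuba_end_s``.  With the
    reversal, the axis beyond ``spire_end_s`` is regrown by integrating the
    Frenet–Serret equations with the original curvature but torsion
    multiplied by a cosine ramp from +1 to -1 across the constriction: a C1
    continuation whose torsion changes sign mid-constriction and stays
    reversed along the tuba.
    """
    if schedule.tuba_end_s > axis.total_length + 1e-9:
        raise ValidationError(
            f"schedule tuba_end_s={schedule.tuba_end_s} exceeds axis length "
            f"{axis.total_length:.3f}"
        )
    if truth is None:
        raise ValidationError("apply_phase_schedule requires the generator truth")
    base_kappa, base_tau, base_frame = truth.kappa_true, truth.tau_true, truth.frenet_frame

    def tau_new(s, _t=base_tau, _sch=schedule):
        return _like_input(np.asarray(_t(s)) * np.asarray(_sch.torsion_ramp(s)), s)

    axis2 = _truncate_axis(axis, schedule.tuba_end_s)
    if not schedule.tuba_rotation_reversal:
        axis2 = replace(axis2, phase_bounds=schedule.phase_bounds)
        return axis2, replace(
            truth, axis=axis2, tau_true=tau_new, schedule=schedule
        )

    s = axis2.s
    k0 = int(np.searchsorted(s, schedule.spire_end_s, side="right"))
    k0 = min(max(k0, 1), len(s) - 1)
    pts = axis2.points.copy()
    T, N, B = base_frame(s[k0 - 1])
    p = pts[k0 - 1].copy()
    # fixed-step RK4 on (p, T, N, B); orthonormalized after every step
    frames_s = [s[k0 - 1]]
    frames = [(T.copy(), N.copy(), B.copy())]
    for i in range(k0, len(s)):
        h_total = s[i] - s[i - 1]
        nsub = 4
        h = h_total / nsub
        si = s[i - 1]
        for _ in range(nsub):
            p, T, N, B = _rk4_frenet(p, T, N, B, si, h, base_kappa, tau_new)
            si += h
            # re-orthonormalize (Gram–Schmidt) to kill drift
            T = T / np.linalg.norm(T)
            N = N - (N @ T) * T
            N = N / np.linalg.norm(N)
            B = np.cross(T, N)
        pts[i] = p
        frames_s.append(s[i])
        frames.append((T.copy(), N.copy(), B.copy()))
    frames_s_arr = np.array(frames_s)
    frames_arr = np.array([np.vstack(f) for f in frames])  # (m, 3, 3) rows T,N,B

    def frenet_frame2(ss, _fs=frames_s_arr, _fr=frames_arr, _base=base_frame, _cut=s[k0 - 1]):
        if ss <= _cut:
            return _base(ss)
        j = int(np.clip(np.searchsorted(_fs, ss), 0, len(_fs) - 1))
        Tj, Nj, Bj = _fr[j]
        return Tj, Nj, Bj

    axis3 = OntogenyAxis(
        points=pts,
        s=cumulative_arc_length(pts),
        rib_positions=axis2.rib_positions,
        phase_bounds=schedule.phase_bounds,
        handedness=axis2.handedness,
        shell_id=axis2.shell_id,
    )
    return axis3, SyntheticShellTruth(
        axis=axis3,
        kappa_true=base_kappa,
        tau_true=tau_new,
        frenet_frame=frenet_frame2,
        schedule=schedule,
        rib_truth=truth.rib_truth,
        growth_truth=truth.growth_truth,
    )


def _rk4_frenet(p, T, N, B, s, h, kappa, tau):
    def f(state, ss):
        p_, T_, N_, B_ = state
        k = float(np.asarray(kappa(ss)).ravel()[0])
        t = float(np.asarray(tau(ss)).ravel()[0])
        return (T_, k * N_, -k * T_ + t * B_, -t * N_)

    y = (p, T, N, B)
    k1 = f(y, s)
    k2 = f(tuple(a + 0.5 * h * b for a, b in zip(y, k1)), s + 0.5 * h)
    k3 = f(tuple(a + 0.5 * h * b for a, b in zip(y, k2)), s + 0.5 * h)
    k4 = f(tuple(a + h * b for a, b in zip(y, k3)), s + h)
    return tuple(
        a + (h / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
        for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
    )


# ---------------------------------------------------------------------------
# aperture outlines

def _template_shape(phi: np.ndarray, morph: float) -> np.ndarray:
    """Planar template morphing from a rounded diamond (0) to an ovate (1).

    Both templates are symmetric about the template x axis (the
    anteroposterior axis); the anterior vertex is at phi = 0.
    """
    c, s = np.cos(phi), np.sin(phi)
    # slightly anisotropic so the first-harmonic ellipse is non-degenerate
    diamond = np.stack(
        [1.15 * np.sign(c) * np.abs(c) ** 1.4, 0.95 * np.sign(s) * np.abs(s) ** 1.4], axis=1
    )
    ovate = np.stack([1.2 * c + 0.15 * np.cos(2 * phi), 0.8 * s], axis=1)
    m = float(np.clip(morph, 0.0, 1.0))
    return (1.0 - m) * diamond + m * ovate


def _discrete_frenet_frames(axis: OntogenyAxis, idx: np.ndarray):
    """Tangent/normal/binormal at selected axis indices by central differences."""
    pts, s = axis.points, axis.s
    frames = []
    prev_N = None
    for i in idx:
        i = int(np.clip(i, 1, len(s) - 2))
        d1 = (pts[i + 1] - pts[i - 1]) / (s[i + 1] - s[i - 1])
        d2 = (pts[i + 1] - 2 * pts[i] + pts[i - 1]) / (
            (0.5 * (s[i + 1] - s[i - 1])) ** 2
        )
        T = d1 / np.linalg.norm(d1)
        nvec = d2 - (d2 @ T) * T
        nn = np.linalg.norm(nvec)
        if nn > 1e-10:
            N = nvec / nn
            prev_N = N
        elif prev_N is not None:  # near-straight stretch: parallel transport
            N = prev_N - (prev_N @ T) * T
            N = N / np.linalg.norm(N)
        else:
            pivot = np.zeros(3)
            pivot[int(np.argmin(np.abs(T)))] = 1.0
            N = np.cross(T, pivot)
            N = N / np.linalg.norm(N)
        B = np.cross(T, N)
        frames.append((T, N, B))
    return frames


def generate_aperture_sequence(
    axis: OntogenyAxis,
    schedule: PhaseSchedule,
    n_outlines: int = 33,
    shape_morph: float | Callable[[float], float] | None = None,
    seed: int = 0,
    *,
    s_positions: np.ndarray | None = None,
    noise_frac: float = 0.0,
    n_points: int = 120,
    truth: SyntheticShellTruth | None = None,
) -> tuple[list[ApertureOutline], SyntheticShellTruth | dict]:
    """Closed outlines centred on the axis, normal to the local tangent.

    Perimeters follow ``schedule.perimeter_at`` (optionally with fractional
    Gaussian noise); the in-plane frame is the local Frenet frame of the
    axis (truth frame when available), so the planted twist of successive
    apertures carries the torsion sign; the anterior landmark (point of
    maximal local growth) is outline point 0, placed along the local
    curvature normal.  ``shape_morph`` is a constant in [0, 1] or a callable
    of s; the default ramps from rounded-diamond (spire) to ovate (tuba)
    across the constriction.
    """
    if n_outlines < 3:
        raise ValidationError("need n_outlines >= 3")
    L = axis.total_length
    if s_positions is None:
        lo = min(5.0, 0.3 * L)
        s_positions = np.linspace(lo, L - 1e-6, n_outlines)
    s_positions = np.asarray(s_positions, dtype=float)
    if np.any(s_positions < 0) or np.any(s_positions > L + 1e-9):
        raise ValidationError("outline positions outside axis range")

    if shape_morph is None:
        def shape_morph(s, _sch=schedule):
            lo, hi = _sch.spire_end_s, _sch.constriction_end_s
            return float(np.clip((s - lo) / (hi - lo), 0.0, 1.0))
    if not callable(shape_morph):
        const_m = float(shape_morph)
        shape_morph = lambda s: const_m  # noqa: E731

    rng = np.random.default_rng(seed)
    phi = 2.0 * np.pi * np.arange(n_points) / n_points
    idx = np.searchsorted(axis.s, s_positions)
    if truth is not None:
        frames = [truth.frenet_frame(sp) for sp in s_positions]
    else:
        frames = _discrete_frenet_frames(axis, idx)

    outlines: list[ApertureOutline] = []
    planted_perims = np.empty(len(s_positions))
    morphs = np.empty(len(s_positions))
    for j, sp in enumerate(s_positions):
        m = shape_morph(sp)
        morphs[j] = m
        tmpl = _template_shape(phi, m)
        target = float(np.asarray(schedule.perimeter_at(sp)))
        if noise_frac > 0:
            target *= 1.0 + noise_frac * rng.standard_normal()
        planted_perims[j] = target
        scale = target / _perimeter(
            np.concatenate([tmpl, np.zeros((len(tmpl), 1))], axis=1)
        )
        T, N, B = frames[j]
        centre = axis.point_at(sp)
        pts = centre[None, :] + scale * (np.outer(tmpl[:, 0], N) + np.outer(tmpl[:, 1], B))
        outlines.append(
            ApertureOutline(
                points=pts,
                anterior_index=0,
                s_position=float(sp),
                outline_id=f"ap{j:03d}",
                shell_id=axis.shell_id,
            )
        )
    outline_truth = {
        "s": s_positions.copy(),
        "perimeter": planted_perims,
        "perimeter_clean": np.asarray(schedule.perimeter_at(s_positions), dtype=float),
        "morph": morphs,
    }
    if truth is not None:
        truth = replace(truth, outline_truth=outline_truth, schedule=schedule)
        return outlines, truth
    return outlines, outline_truth


# ---------------------------------------------------------------------------
# ribs and growth

def generate_rib_positions(
    axis: OntogenyAxis,
    trend: Callable[[float], float],
    jitter_sd: float = 0.0,
    seed: int = 0,
    *,
    shell_id: str | None = None,
    constriction_s: float | None = None,
    max_retries: int = 100,
) -> RibSeries:
    """Rib arc positions s_0 = 0 < s_1 < ... with spacing trend g(s) + noise.

    ``s_{i+1} = s_i + g(s_i) + eps`` (eps ~ N(0, jitter_sd)), truncated at
    the axis end.  Draws yielding a non-positive spacing are resampled up to
    ``max_retries`` times, then an error is raised (jitter too large for the
    trend).
    """
    total = axis.total_length
    rng = np.random.default_rng(seed)
    pos = [0.0]
    while True:
        s = pos[-1]
        g = float(trend(s))
        if g <= 0:
            raise ValidationError(f"spacing trend must be positive (g({s:.3f}) = {g:.4f})")
        step = g
        if jitter_sd > 0:
            for attempt in range(max_retries + 1):
                step = g + jitter_sd * rng.standard_normal()
                if step > 0:
                    break
            else:
                raise ValidationError("jitter too large: spacing <= 0 after bounded retries")
            if step <= 0:
                raise ValidationError("jitter too large: spacing <= 0 after bounded retries")
        nxt = s + step
        if nxt > total + 1e-9:
            break
        pos.append(nxt)
    if constriction_s is None:
        constriction_s = axis.phase_bounds[1] if axis.phase_bounds else total
    return RibSeries(
        shell_id=shell_id or axis.shell_id,
        positions=np.array(pos),
        constriction_s=float(constriction_s),
        total_axis_length=total,
    )


def simulate_cmr(
    population: Sequence[OntogenyAxis],
    rate: Callable[[float], float],
    duration: float | Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    plot_id: str = "plot1",
) -> list[GrowthRecord]:
    """Mark–recapture growth records from a planted rate function v(s).

    Each individual's mark sits on its most recently grown rib; the
    increment is ``duration * (v(s_start) + eps)`` clipped below at zero
    (``eps ~ N(0, noise_sd)``).  Phase labels come from the axis phase
    bounds where available.
    """
    if len(population) == 0:
        raise ValidationError("empty population")
    durations = np.broadcast_to(np.asarray(duration, dtype=float), (len(population),))
    if np.any(durations <= 0):
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i, (ax, dur) in enumerate(zip(population, durations)):
        if ax.rib_positions.size == 0:
            raise ValidationError(f"individual {i} has no rib marks")
        s_start = float(ax.rib_positions[-1])
        v = float(rate(s_start))
        if v < 0:
            raise ValidationError("rate function must be non-negative")
        eps = noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0
        s_end = max(s_start, s_start + float(dur) * (v + eps))
        records.append(
            GrowthRecord(
                individual_id=f"ind{i:03d}",
                plot_id=plot_id,
                s_start=s_start,
                s_end=s_end,
                duration=float(dur),
                phase=ax.phase_of(s_start) if ax.phase_bounds else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# the full synthetic study

def default_rib_trend(s: float, schedule: PhaseSchedule | None = None) -> float:
    """Pooled rib-spacing trend g(s), mm: rises to ~8 mm, dips toward the
    tuba detachment (~10 mm), peaks at the constriction (~13 mm), drops
    across it and stays flat along the tuba."""
    knots_s = np.array([0.0, 8.0, 10.0, 13.0, 14.0, 30.0])
    knots_g = np.array([0.08, 0.28, 0.20, 0.32, 0.16, 0.16])
    return float(np.interp(s, knots_s, knots_g))


def default_growth_rate(s: float, schedule: PhaseSchedule = PhaseSchedule()) -> float:
    """Planted growth rate v(s), mm/day: 0.2 + 0.05 s on the spire, maximal
    through the constriction, declining along the tuba."""
    a, b = schedule.spire_end_s, schedule.constriction_end_s
    v_top = 0.2 + 0.05 * a
    if s < a:
        return 0.2 + 0.05 * s
    if s < b:
        return v_top
    return max(v_top - 0.12 * (s - b), 0.05)


def draw_growth_records(
    axis: OntogenyAxis,
    rib_positions: np.ndarray,
    schedule: PhaseSchedule,
    *,
    n_spire: int = 30,
    n_tuba: int = 35,
    noise_sd: float = 0.1,
    seed: int = 0,
    rate: Callable[[float], float] | None = None,
) -> list[GrowthRecord]:
    """One replicate of the mark–recapture experiment on a reference shell.

    Juvenile individuals are emulated by truncating the reference axis at a
    marked rib drawn in the requested phase (``n_spire`` marks on the spire,
    ``n_tuba`` on the tuba); growth then follows the planted rate function
    (default :func:`default_growth_rate`) with Gaussian rate noise.
    """
    rng = np.random.default_rng(seed)
    spire_marks = rng.uniform(1.0, schedule.spire_end_s - 0.5, n_spire)
    tuba_marks = rng.uniform(
        schedule.constriction_end_s + 0.1, axis.total_length - 0.3, n_tuba
    )
    population = []
    for mark in np.concatenate([spire_marks, tuba_marks]):
        rib_idx = int(np.clip(np.searchsorted(rib_positions, mark), 1, len(rib_positions) - 1))
        juvenile = _truncate_axis(axis, rib_positions[rib_idx] + 1e-9)
        population.append(replace(juvenile, phase_bounds=schedule.phase_bounds))
    durations = rng.choice([2.0, 3.0, 4.0, 11.0, 13.0], size=len(population))
    v = rate or (lambda s: default_growth_rate(s, schedule))
    return simulate_cmr(
        population, v, durations, noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )


@dataclass
class SimulatedStudy:
    """Bundle of everything one synthetic field study produces."""

    axis: OntogenyAxis
    truth: SyntheticShellTruth
    schedule: PhaseSchedule
    outlines: list[ApertureOutline]
    trajectory_outlines: list[ApertureOutline]
    growth_records: list[GrowthRecord]
    rib_series: list[RibSeries]
    seed: int


def simulate_study(
    seed: int = 0,
    *,
    params: HelicospiralParams = HelicospiralParams(),
    schedule: PhaseSchedule = PhaseSchedule(),
    n_spire_records: int = 30,
    n_tuba_records: int = 35,
    n_rib_shells: int = 35,
    n_spire_outlines: int = 22,
    n_post_spire_outlines: int = 11,
    outline_noise_frac: float = 0.01,
    growth_noise_sd: float = 0.1,
    rib_jitter_sd: float = 0.02,
    spire_regression_range: tuple[float, float] = (5.0, 11.0),
) -> SimulatedStudy:
    """Generate one complete synthetic study at the reference conditions.

    Sample sizes mirror the field study this emulates: 30 spire + 35 tuba
    growth records, 35 rib series, 22 outlines inside the spire regression
    window plus 11 beyond it (33 apertures).  Child seeds are split from
    ``seed`` with fixed offsets so each sub-generator has its own stream.
    """
    base_axis, base_truth = generate_helicospiral(params)
    axis, truth = apply_phase_schedule(base_axis, schedule, base_truth)

    # outlines for the form analysis (perimeter + shape)
    lo, hi = spire_regression_range
    s_form = np.concatenate(
        [
            np.linspace(lo, hi, n_spire_outlines),
            np.linspace(hi + 0.3, axis.total_length - 0.05, n_post_spire_outlines),
        ]
    )
    outlines, truth = generate_aperture_sequence(
        axis, schedule, n_outlines=len(s_form), seed=seed * 9973 + 1,
        s_positions=s_form, noise_frac=outline_noise_frac, truth=truth,
    )

    # the main rib series on the reference shell, then dense per-interval
    # outlines for the rotation analysis
    trend = lambda s: default_rib_trend(s, schedule)  # noqa: E731
    main_ribs = generate_rib_positions(
        axis, trend, jitter_sd=rib_jitter_sd, seed=seed * 9973 + 2
    )
    axis = replace(axis, rib_positions=main_ribs.positions)
    truth = replace(truth, axis=axis, rib_truth=trend)
    mids = 0.5 * (main_ribs.positions[:-1] + main_ribs.positions[1:])
    traj_outlines, _ = generate_aperture_sequence(
        axis, schedule, n_outlines=len(mids), seed=seed * 9973 + 3,
        s_positions=mids, noise_frac=0.0, truth=truth,
    )

    # growth records: juveniles truncated at marked ribs in each phase
    v = lambda s: default_growth_rate(s, schedule)  # noqa: E731
    records = draw_growth_records(
        axis, main_ribs.positions, schedule,
        n_spire=n_spire_records, n_tuba=n_tuba_records,
        noise_sd=growth_noise_sd, seed=seed * 9973 + 4, rate=v,
    )
    truth = replace(truth, growth_truth=v)

    # rib series across shells: per-shell density multiplier, variable length
    rib_series = [main_ribs]
    rng_r = np.random.default_rng(seed * 9973 + 6)
    for j in range(1, n_rib_shells):
        mult = rng_r.uniform(0.8, 1.3)
        L_j = rng_r.uniform(schedule.tuba_end_s - 1.5, schedule.tuba_end_s)
        shell_axis = replace(_truncate_axis(axis, L_j), shell_id=f"shell{j:02d}")
        rib_series.append(
            generate_rib_positions(
                shell_axis,
                lambda s, _m=mult: _m * trend(s),
                jitter_sd=rib_jitter_sd,
                seed=seed * 9973 + 100 + j,
                shell_id=f"shell{j:02d}",
                constriction_s=schedule.constriction_end_s,
            )
        )

    return SimulatedStudy(
        axis=axis,
        truth=truth,
        schedule=schedule,
        outlines=outlines,
        trajectory_outlines=traj_outlines,
        growth_records=records,
        rib_series=rib_series,
        seed=seed,
    )
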