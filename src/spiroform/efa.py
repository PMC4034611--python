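"""3D elliptic Fourier analysis (EFA) of closed aperture outlines.

A digitized aperture outline is a closed 3D polygon with a flagged anterior
landmark.  Each coordinate is expanded in a Fourier series against the
chord-length parameter (period = polygon perimeter), with coefficients
computed in closed form from the piecewise-linear-velocity integrals
(the classical elliptic Fourier construction, extended from two to three
coordinates).  Truncating at K harmonics smooths digitization noise;
reconstruction at 100 uniformly spaced parameter values yields the smoothed
outline whose chord sum is the aperture perimeter.

Shape is summarized by similarity-invariant normalized coefficients: the
constant terms are dropped (translation), the coefficients are rotated into
the canonical frame of the first-harmonic ellipse and divided by its
semi-major axis length (rotation and size), and the parameter phase is
shifted so the first harmonic starts at the semi-major vertex.  A PCA of the
6K normalized coefficients (30 at K = 5) gives shape scores per outline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from sklearn.decomposition import PCA

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "ApertureOutline",
    "HarmonicSet",
    "NormalizedHarmonicSet",
    "ShapePCAResult",
    "efa_decompose",
    "efa_reconstruct",
    "perimeter",
    "normalize_harmonics",
    "shape_pca",
]


@dataclass
class ApertureOutline:
    """Closed 3D aperture outline with an anterior landmark.

    ``points`` are ordered mm coordinates (the closing chord back to the
    first point is implicit).  ``anterior_index`` flags the anterior landmark
    (the point of maximum local growth, through which the ontogeny axis
    runs); ``standardized`` outlines start at this landmark.  ``s_position``
    is the outline's coordinate on the ontogeny axis, if known.
    """

    points: np.ndarray
    anterior_index: int = 0
    orientation: str = "clockwise"
    s_position: float | None = None
    outline_id: str = "outline"
    shell_id: str = "shell"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 3:
            raise ValidationError("outline needs an (n, 3) array with n >= 3")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("non-finite outline coordinates")
        if not (0 <= self.anterior_index < len(self.points)):
            raise ValidationError("anterior index out of range")
        centred = self.points - self.points.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(centred).max())) < 2:
            raise DegenerateGeometryError("outline points are collinear")

    def standardized(self) -> "ApertureOutline":
        """Return a copy rolled so the anterior landmark is the first point."""
        pts = np.roll(self.points, -self.anterior_index, axis=0)
        return ApertureOutline(
            points=pts,
            anterior_index=0,
            orientation=self.orientation,
            s_position=self.s_position,
            outline_id=self.outline_id,
            shell_id=self.shell_id,
        )


@dataclass
class HarmonicSet:
    """Raw elliptic Fourier representation of one outline.

    ``a`` and ``b`` are (3, K) cosine/sine coefficient arrays (rows x, y, z),
    ``const`` the (3,) constant terms, ``T`` the chord-length period
    (= polygon perimeter used for parameterization).
    """

    a: np.ndarray
    b: np.ndarray
    const: np.ndarray
    T: float
    outline_id: str = "outline"
    shell_id: str = "shell"
    s_position: float | None = None

    @property
    def K(self) -> int:
        return self.a.shape[1]


@dataclass
class NormalizedHarmonicSet:
    """Similarity-invariant coefficients (6K values at K harmonics).

    ``coeffs`` is ordered (a1x, a1y, a1z, b1x, b1y, b1z, a2x, ...).  After
    normalization the first cosine harmonic is the unit vector (1, 0, 0).
    """

    a: np.ndarray
    b: np.ndarray
    outline_id: str = "outline"
    shell_id: str = "shell"
    s_position: float | None = None

    @property
    def K(self) -> int:
        return self.a.shape[1]

    @property
    def coeffs(self) -> np.ndarray:
        out = np.empty(6 * self.K)
        for k in range(self.K):
            out[6 * k : 6 * k + 3] = self.a[:, k]
            out[6 * k + 3 : 6 * k + 6] = self.b[:, k]
        return out

    @staticmethod
    def coefficient_names(K: int) -> list[str]:
        names = []
        for k in range(1, K + 1):
            names += [f"a{k}_{q}" for q in "xyz"] + [f"b{k}_{q}" for q in "xyz"]
        return names


def _closed_deltas(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chord deltas/lengths of the closed polygon, zero-length chords dropped."""
    closed = np.vstack([points, points[:1]])
    dp = np.diff(closed, axis=0)
    dt = np.linalg.norm(dp, axis=1)
    keep = dt > 0.0
    dp, dt = dp[keep], dt[keep]
    if dt.size < 3 or dt.sum() == 0.0:
        raise DegenerateGeometryError("outline has (near-)zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return dp, dt, t


def perimeter(outline: ApertureOutline | np.ndarray) -> float:
    """Perimeter as the chord sum of the closed outline (closing chord included)."""
    pts = outline.points if isinstance(outline, ApertureOutline) else np.asarray(outline, float)
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def efa_decompose(outline: ApertureOutline, K: int = 5) -> HarmonicSet:
    """Elliptic Fourier coefficients of a closed outline, K harmonics.

    Uses the chord-length parameterization t with period T = polygon
    perimeter; the piecewise-linear velocity makes the Fourier integrals
    exact sums over edges.  The outline is standardized so the parameter
    origin is the anterior landmark.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    std = outline.standardized()
    dp, dt, t = _closed_deltas(std.points)
    T = t[-1]
    k = np.arange(1, K + 1)
    w = 2.0 * np.pi * k[:, None] / T  # (K, 1)
    cos1, cos0 = np.cos(w * t[1:]), np.cos(w * t[:-1])
    sin1, sin0 = np.sin(w * t[1:]), np.sin(w * t[:-1])
    slope = dp / dt[:, None]  # (m, 3) velocity per edge
    pref = T / (2.0 * np.pi**2 * k**2)  # (K,)
    # a[q, k] = pref_k * sum_i slope[i, q] * (cos(w_k t_i) - cos(w_k t_{i-1}))
    a = pref[None, :] * (slope.T @ (cos1 - cos0).T)
    b = pref[None, :] * (slope.T @ (sin1 - sin0).T)
    # constant term: mean of the piecewise-linear curve over one period
    closed = np.vstack([std.points, std.points[:1]])
    keep = np.linalg.norm(np.diff(closed, axis=0), axis=1) > 0.0
    mids = 0.5 * (closed[:-1] + closed[1:])[keep]
    const = (mids * dt[:, None]).sum(axis=0) / T
    return HarmonicSet(
        a=a, b=b, const=const, T=T,
        outline_id=outline.outline_id, shell_id=outline.shell_id,
        s_position=outline.s_position,
    )


def efa_reconstruct(h: HarmonicSet, n_points: int = 100) -> ApertureOutline:
    """Sample the truncated Fourier series at n uniformly spaced parameters.

    The first sample is at parameter 0, i.e. the anterior-landmark phase of
    the decomposition; the curve is closed (the closing chord is implicit).
    """
    if n_points < 3:
        raise ValidationError("n_points must be >= 3")
    t = np.linspace(0.0, h.T, n_points, endpoint=False)
    k = np.arange(1, h.K + 1)
    ang = 2.0 * np.pi * np.outer(t, k) / h.T  # (n, K)
    pts = h.const[None, :] + np.cos(ang) @ h.a.T + np.sin(ang) @ h.b.T
    return ApertureOutline(
        points=pts, anterior_index=0,
        s_position=h.s_position, outline_id=h.outline_id, shell_id=h.shell_id,
    )


def smoothed_perimeter(outline: ApertureOutline, K: int = 5, n_points: int = 100) -> float:
    """Perimeter measured the standard way: decompose(K) -> reconstruct(n) -> chord sum."""
    return perimeter(efa_reconstruct(efa_decompose(outline, K=K), n_points=n_points))


def _first_harmonic_phase(A: np.ndarray, B: np.ndarray) -> float:
    """Parameter phase of the first-harmonic ellipse's semi-major vertex.

    Among the two opposite semi-major vertices the one closest in parameter
    to the anterior landmark (phase 0) is chosen, which also resolves the
    circular-degenerate case (any direction extremal -> phase 0).
    """
    num = 2.0 * float(A @ B)
    den = float(A @ A - B @ B)
    phi = 0.5 * np.arctan2(num, den)
    # extrema of |A cos(phi) + B sin(phi)| are at phi and phi + pi/2
    cands = [phi, phi + 0.5 * np.pi]
    amps = [np.linalg.norm(A * np.cos(c) + B * np.sin(c)) for c in cands]
    if abs(amps[0] - amps[1]) <= 1e-6 * max(amps):
        # circular-degenerate first harmonic: every direction is extremal and
        # the phase above is numerically arbitrary; anchor at the anterior
        # landmark for a deterministic result
        return 0.0
    best = cands[int(np.argmax(amps))]
    # semi-major direction ambiguity (best vs best + pi): anchor at anterior
    two = [best, best + np.pi]
    wrapped = [(c + np.pi) % (2.0 * np.pi) - np.pi for c in two]
    return float(wrapped[int(np.argmin(np.abs(wrapped)))])


def normalize_harmonics(h: HarmonicSet, tol: float = 1e-12) -> NormalizedHarmonicSet:
    """Size/rotation/translation/phase-invariant coefficients.

    Constant terms are dropped; the parameter phase is shifted so the first
    harmonic starts at its semi-major vertex; all coefficient vectors are
    rotated into the first-harmonic ellipse frame (semi-major axis -> x,
    ellipse-plane normal -> z) and divided by the semi-major axis length.
    """
    A, B = h.a[:, 0].copy(), h.b[:, 0].copy()
    if np.linalg.norm(A) + np.linalg.norm(B) < tol:
        raise DegenerateGeometryError("degenerate first harmonic")
    phi = _first_harmonic_phase(A, B)
    k = np.arange(1, h.K + 1)
    c, s = np.cos(k * phi), np.sin(k * phi)
    a = h.a * c[None, :] + h.b * s[None, :]
    b = -h.a * s[None, :] + h.b * c[None, :]
    major = a[:, 0]
    lam = np.linalg.norm(major)
    if lam < tol:
        raise DegenerateGeometryError("degenerate first harmonic (zero semi-major axis)")
    e1 = major / lam
    n = np.cross(a[:, 0], b[:, 0])
    nn = np.linalg.norm(n)
    if nn < tol * lam * lam:
        # flat (line-like) first harmonic: pick a deterministic normal
        pivot = np.zeros(3)
        pivot[int(np.argmin(np.abs(e1)))] = 1.0
        n = np.cross(e1, pivot)
        nn = np.linalg.norm(n)
    e3 = n / nn
    e2 = np.cross(e3, e1)
    R = np.vstack([e1, e2, e3])
    return NormalizedHarmonicSet(
        a=(R @ a) / lam, b=(R @ b) / lam,
        outline_id=h.outline_id, shell_id=h.shell_id, s_position=h.s_position,
    )


@dataclass
class ShapePCAResult:
    """PCA of the normalized-coefficient matrix (covariance-based by default)."""

    scores: np.ndarray              # (n, n_components)
    variance_fractions: np.ndarray  # descending, sums to 1
    loadings: np.ndarray            # (n_components, 6K)
    pc1_coefficient_r: np.ndarray   # (6K,), nan for constant coefficients
    pc1_coefficient_p: np.ndarray
    alpha: float = 0.05
    coefficient_names: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        """Coefficients significantly correlated with PC1 scores (two-sided)."""
        valid = ~np.isnan(self.pc1_coefficient_p)
        return int(np.sum(self.pc1_coefficient_p[valid] < self.alpha))


def shape_pca(
    coeff_matrix: np.ndarray, *, method: str = "covariance", alpha: float = 0.05
) -> ShapePCAResult:
    """Principal components of n_outlines x 6K normalized coefficients.

    ``method="covariance"`` (default) runs PCA on the mean-centred matrix;
    ``"correlation"`` additionally scales columns to unit variance (constant
    columns, e.g. the pinned first cosine harmonic, are left unscaled).
    Also reports the Pearson correlation (with two-sided p) of PC1 scores
    with each coefficient.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError("need at least 3 outlines (rows)")
    if method not in ("covariance", "correlation"):
        raise ValidationError("method must be 'covariance' or 'correlation'")
    sd = X.std(axis=0, ddof=1)
    work = X.copy()
    if method == "correlation":
        nz = sd > 0
        work[:, nz] = (X[:, nz] - X[:, nz].mean(axis=0)) / sd[nz]
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(work)
    r = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    pc1 = scores[:, 0]
    # columns pinned by the normalization (e.g. the unit first cosine
    # harmonic) are constant up to rounding; exclude them from correlation
    informative = sd > 1e-9 * (np.abs(X).max(axis=0) + 1.0)
    for j in range(X.shape[1]):
        if informative[j] and pc1.std() > 0:
            res = _sps.pearsonr(pc1, X[:, j])
            r[j], p[j] = res.statistic, res.pvalue
    K = X.shape[1] // 6
    return ShapePCAResult(
        scores=scores,
        variance_fractions=pca.explained_variance_ratio_,
        loadings=pca.components_,
        pc1_coefficient_r=r,
        pc1_coefficient_p=p,
        alpha=alpha,
        coefficient_names=NormalizedHarmonicSet.coefficient_names(K) if X.shape[1] == 6 * K else [],
    )
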