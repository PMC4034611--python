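"""Statistical layer: correlations, regression, rib counts and spacing trends.

Mirrors the analyses applied to the growth and form data: Spearman rank
correlation of growth rate against pre-experiment position (separately for
spire and tuba), ordinary least squares of aperture perimeter on axis
position over the spire window, Pearson correlations of rib counts, and the
pooled rib-spacing trend along the common ontogeny axis.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .axis import GrowthRecord, partition_by_phase
from .errors import ValidationError

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "RibSeries",
    "spearman_correlation",
    "pearson_correlation",
    "linear_regression",
    "count_ribs_split",
    "pool_rib_spacings",
    "binned_spacing_trend",
    "run_study_analyses",
    "AnalysisReport",
]

EXACT_SPEARMAN_MAX_N = 8  # full permutation p only up to 8! orderings


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError("correlation outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in input")
    return x, y


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p: exact by full permutation of one margin for n <= 8,
    t-approximation otherwise (the convention of common statistical
    software).
    """
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        num = pc @ rxc
        den = np.sqrt((rxc @ rxc) * np.einsum("ij,ij->i", pc, pc))
        r_perm = num / den
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(method="spearman", r=r, n=n, p=min(p, 1.0))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product–moment correlation; two-sided p via t with n-2 df."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Pearson correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        method="pearson", r=float(res.statistic), n=x.size, p=float(res.pvalue)
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the F test of the slope.

    ``F = (n - 2) R^2 / (1 - R^2)`` with df (1, n - 2); its p equals the
    two-sided t test of the slope.
    """
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0:
        raise ValidationError("regression undefined for constant x")
    fit = sps.linregress(x, y)
    n = x.size
    r2 = float(fit.rvalue**2)
    F = float(np.inf) if r2 >= 1.0 else (n - 2) * r2 / (1.0 - r2)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        F=F,
        df=(1, n - 2),
        p=float(fit.pvalue),
    )


@dataclass
class RibSeries:
    """Commarginal rib arc positions of one shell, split at the constriction."""

    shell_id: str
    positions: np.ndarray
    constriction_s: float
    total_axis_length: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("rib positions must be strictly increasing")
        if self.positions.size and self.positions[-1] > self.total_axis_length + 1e-9:
            raise ValidationError("rib position beyond axis end")

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.positions)

    @property
    def n_before(self) -> int:
        return count_ribs_split(self)[0]

    @property
    def n_after(self) -> int:
        return count_ribs_split(self)[1]


def count_ribs_split(ribs: RibSeries) -> tuple[int, int]:
    """Rib counts strictly before vs at-or-after the constriction."""
    if not 0.0 < ribs.constriction_s:
        raise ValidationError("constriction position must be positive")
    before = int(np.sum(ribs.positions < ribs.constriction_s))
    return before, int(ribs.positions.size - before)


def pool_rib_spacings(series: Sequence[RibSeries]) -> pd.DataFrame:
    """Pool inter-rib spacings over shells onto the common ontogeny axis.

    One row per inter-rib interval with the interval midpoint as its axis
    coordinate; pooling is order-invariant (rows sorted by midpoint, then
    shell).
    """
    if len(series) == 0:
        raise ValidationError("need at least one rib series")
    frames = []
    for rs in series:
        if rs.positions.size < 2:
            continue
        mids = 0.5 * (rs.positions[:-1] + rs.positions[1:])
        frames.append(
            pd.DataFrame(
                {"shell_id": rs.shell_id, "s_mid_mm": mids, "spacing_mm": rs.spacings}
            )
        )
    if not frames:
        raise ValidationError("no inter-rib intervals to pool")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["s_mid_mm", "shell_id"], kind="mergesort").reset_index(drop=True)


def binned_spacing_trend(pooled: pd.DataFrame, bin_width: float = 0.5) -> pd.DataFrame:
    """Mean spacing per axis bin — the empirical pooled spacing trend."""
    edges = np.arange(0.0, pooled["s_mid_mm"].max() + bin_width, bin_width)
    idx = np.digitize(pooled["s_mid_mm"], edges) - 1
    g = pooled.groupby(idx)["spacing_mm"].mean()
    return pd.DataFrame(
        {"s_bin_mm": edges[g.index] + 0.5 * bin_width, "mean_spacing_mm": g.values}
    )


@dataclass
class AnalysisReport:
    """Structured output of the combined growth-and-form analysis."""

    growth_spire: CorrelationResult | None = None
    growth_tuba: CorrelationResult | None = None
    perimeter_regression: RegressionResult | None = None
    pca_variance_fractions: np.ndarray | None = None
    pca_n_significant_pc1: int | None = None
    rib_count_correlation: CorrelationResult | None = None
    ribs_vs_length: CorrelationResult | None = None
    pooled_spacings: pd.DataFrame | None = None
    not_run: dict[str, str] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["Growth-and-form analysis report", "=" * 34]
        def corr(tag, c):
            if c is not None:
                lines.append(f"{tag}: {c.method} r = {c.r:+.3f}, n = {c.n}, p = {c.p:.4g}")
        corr("Spire growth rate vs position", self.growth_spire)
        corr("Tuba growth rate vs position", self.growth_tuba)
        if self.perimeter_regression is not None:
            m = self.perimeter_regression
            lines.append(
                "Spire perimeter ~ position: slope = "
                f"{m.slope:.4f} mm/mm, intercept = {m.intercept:.4f} mm, "
                f"R^2 = {m.r_squared:.3f}, F({m.df[0]}, {m.df[1]}) = {m.F:.1f}, p = {m.p:.4g}"
            )
        if self.pca_variance_fractions is not None:
            top = ", ".join(f"{v:.1%}" for v in self.pca_variance_fractions[:3])
            lines.append(f"Shape PCA variance fractions (PC1-3): {top}")
        if self.pca_n_significant_pc1 is not None:
            lines.append(
                f"Coefficients significantly correlated with PC1: {self.pca_n_significant_pc1}"
            )
        corr("Ribs before vs after constriction", self.rib_count_correlation)
        corr("Total ribs vs total axis length", self.ribs_vs_length)
        if self.pooled_spacings is not None:
            lines.append(f"Pooled inter-rib spacings: {len(self.pooled_spacings)} intervals")
        for k, v in self.not_run.items():
            lines.append(f"[not run] {k}: {v}")
        return "\n".join(lines)


def run_study_analyses(
    records: Sequence[GrowthRecord] | None = None,
    perimeter_profile: pd.DataFrame | None = None,
    rib_series: Sequence[RibSeries] | None = None,
    coeff_matrix: np.ndarray | None = None,
    *,
    phase_bounds: tuple[float, float] | None = None,
    spire_range: tuple[float, float] = (5.0, 11.0),
    alpha: float = 0.05,
) -> AnalysisReport:
    """Run the combined growth-and-form analysis on whatever inputs exist.

    ``perimeter_profile`` is a DataFrame with columns ``s_mm`` and
    ``perimeter_mm``.  Analyses whose inputs are missing or too small are
    marked "not run" in the report rather than failing; errors inside an
    analysis are re-raised naming the failing analysis.
    """
    if all(v is None for v in (records, perimeter_profile, rib_series, coeff_matrix)):
        raise ValidationError("no inputs: provide at least one data kind")
    rep = AnalysisReport()

    def _guard(name: str, fn: Callable):
        try:
            return fn()
        except ValidationError as exc:
            raise ValidationError(f"analysis {name!r} failed: {exc}") from exc

    if records is not None:
        if phase_bounds is None:
            raise ValidationError("phase_bounds required with growth records")
        part = partition_by_phase(records, phase_bounds)
        for tag, group in (("spire", part.spire), ("tuba", part.tuba)):
            if len(group) >= 3:
                res = _guard(
                    f"growth_{tag}",
                    lambda g=group: spearman_correlation(
                        [r.s_start for r in g], [r.rate for r in g]
                    ),
                )
                setattr(rep, f"growth_{tag}", res)
            else:
                rep.not_run[f"growth_{tag}"] = f"only {len(group)} records"

    if perimeter_profile is not None:
        lo, hi = spire_range
        sel = perimeter_profile[
            (perimeter_profile["s_mm"] >= lo) & (perimeter_profile["s_mm"] <= hi)
        ]
        if len(sel) >= 3:
            rep.perimeter_regression = _guard(
                "perimeter_regression",
                lambda: linear_regression(sel["s_mm"].values, sel["perimeter_mm"].values),
            )
        else:
            rep.not_run["perimeter_regression"] = (
                f"only {len(sel)} perimeters inside the spire window {spire_range}"
            )

    if coeff_matrix is not None:
        from .efa import shape_pca  # local import to avoid cycle at module load

        if np.asarray(coeff_matrix).shape[0] >= 3:
            pca = _guard("shape_pca", lambda: shape_pca(coeff_matrix, alpha=alpha))
            rep.pca_variance_fractions = pca.variance_fractions
            rep.pca_n_significant_pc1 = pca.n_significant
        else:
            rep.not_run["shape_pca"] = "fewer than 3 outlines"

    if rib_series is not None and len(rib_series) > 0:
        counts = [count_ribs_split(rs) for rs in rib_series]
        before = np.array([c[0] for c in counts], dtype=float)
        after = np.array([c[1] for c in counts], dtype=float)
        total = before + after
        lengths = np.array([rs.total_axis_length for rs in rib_series])
        if len(rib_series) >= 3 and np.ptp(before) > 0 and np.ptp(after) > 0:
            rep.rib_count_correlation = _guard(
                "rib_count_correlation", lambda: pearson_correlation(before, after)
            )
        else:
            rep.not_run["rib_count_correlation"] = "too few shells or constant counts"
        if len(rib_series) >= 3 and np.ptp(total) > 0 and np.ptp(lengths) > 0:
            rep.ribs_vs_length = _guard(
                "ribs_vs_length", lambda: pearson_correlation(total, lengths)
            )
        else:
            rep.not_run["ribs_vs_length"] = "too few shells or constant values"
        rep.pooled_spacings = pool_rib_spacings(rib_series)

    return rep
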