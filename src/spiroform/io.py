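"""File formats: PLY meshes, axis/outline/rib CSV, growth and result TSV.

Conventions: coordinates in millimetres, indices 0-based, CSV inputs are
comma-separated UTF-8 with a mandatory header and '.' decimals; result
tables are TSV.  Column headers carry units (``x_mm``, ``rate_mm_per_day``,
``theta_x_deg``...).  Every writer/reader pair round-trips at the printed
precision (full float repr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .axis import GrowthRecord, OntogenyAxis
from .efa import ApertureOutline, HarmonicSet, NormalizedHarmonicSet
from .errors import ValidationError
from .stats import RibSeries
from .trajectory import CurvatureTorsionProfile, RotationTriple

logger = logging.getLogger(__name__)

AXIS_COLUMNS = ["shell_id", "point_index", "x_mm", "y_mm", "z_mm"]
OUTLINE_COLUMNS = ["shell_id", "outline_id", "point_index", "x_mm", "y_mm", "z_mm", "is_anterior"]
GROWTH_COLUMNS = [
    "individual_id", "plot_id", "s_start_mm", "s_end_mm",
    "duration_days", "phase", "rate_mm_per_day",
]
RIB_COLUMNS = ["shell_id", "rib_index", "s_mm", "constriction_s_mm", "total_length_mm"]


@dataclass
class MeshModel:
    """Triangle mesh: vertices in mm, faces as vertex index triples."""

    vertices: np.ndarray
    faces: np.ndarray


def read_ply(path: str | Path) -> MeshModel:
    """Load an ASCII or binary little-endian PLY triangle mesh.

    Extra vertex/face properties are ignored (with a logged notice);
    degenerate repeated-index faces are dropped at load time; an
    out-of-range face index is reported with its face number.
    """
    from trimesh.exchange.ply import load_ply

    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = load_ply(fh)
    except Exception as exc:  # malformed header / truncated body
        raise ValidationError(f"malformed PLY file {path.name}: {exc}") from exc
    vertices = np.asarray(data["vertices"], dtype=float)
    faces = np.asarray(data["faces"])
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValidationError(f"{path.name}: only triangle faces are supported")
    bad = np.flatnonzero((faces < 0) | (faces >= len(vertices)))
    if bad.size:
        face_idx = int(bad[0] // 3)
        raise ValidationError(
            f"{path.name}: face {face_idx} references vertex "
            f"{int(faces.flat[bad[0]])} but only {len(vertices)} vertices exist"
        )
    degen = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 0] == faces[:, 2])
    if np.any(degen):
        logger.warning("%s: dropped %d degenerate face(s)", path.name, int(degen.sum()))
        faces = faces[~degen]
    extras = set(data.keys()) - {"vertices", "faces", "metadata"}
    if extras:
        logger.info("%s: ignored extra PLY properties: %s", path.name, sorted(extras))
    return MeshModel(vertices=vertices, faces=faces.astype(np.int64))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")


# -- ontogeny axis ----------------------------------------------------------

def write_axis_csv(axis: OntogenyAxis, path: str | Path) -> None:
    pd.DataFrame(
        {
            "shell_id": axis.shell_id,
            "point_index": np.arange(len(axis.points)),
            "x_mm": axis.points[:, 0],
            "y_mm": axis.points[:, 1],
            "z_mm": axis.points[:, 2],
        }
    ).to_csv(path, index=False)


def write_axis_sidecar_csv(axis: OntogenyAxis, path: str | Path) -> None:
    """Rib positions plus phase bounds and handedness for one shell."""
    rows = [
        {"shell_id": axis.shell_id, "kind": f"rib_{i}", "value_mm": float(v)}
        for i, v in enumerate(axis.rib_positions)
    ]
    if axis.phase_bounds is not None:
        rows.append({"shell_id": axis.shell_id, "kind": "spire_end", "value_mm": axis.phase_bounds[0]})
        rows.append({"shell_id": axis.shell_id, "kind": "constriction_end", "value_mm": axis.phase_bounds[1]})
    rows.append({"shell_id": axis.shell_id, "kind": "handedness", "value_mm": 1.0 if axis.handedness == "dextral" else -1.0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_axis_csv(path: str | Path, sidecar: str | Path | None = None) -> OntogenyAxis:
    df = pd.read_csv(path)
    _require_columns(df, AXIS_COLUMNS, path)
    shells = df["shell_id"].unique()
    if len(shells) != 1:
        raise ValidationError(f"{path}: expected a single shell, found {list(shells)}")
    df = df.sort_values("point_index")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    ribs: np.ndarray = np.empty(0)
    bounds = None
    handed = "dextral"
    if sidecar is not None:
        sc = pd.read_csv(sidecar)
        _require_columns(sc, ["shell_id", "kind", "value_mm"], sidecar)
        ribs = sc[sc["kind"].str.startswith("rib_")]["value_mm"].to_numpy(dtype=float)
        se = sc[sc["kind"] == "spire_end"]["value_mm"]
        ce = sc[sc["kind"] == "constriction_end"]["value_mm"]
        if len(se) and len(ce):
            bounds = (float(se.iloc[0]), float(ce.iloc[0]))
        hd = sc[sc["kind"] == "handedness"]["value_mm"]
        if len(hd):
            handed = "dextral" if float(hd.iloc[0]) > 0 else "sinistral"
    return OntogenyAxis(
        points=pts,
        rib_positions=np.sort(ribs),
        phase_bounds=bounds,
        handedness=handed,
        shell_id=str(shells[0]),
    )


# -- aperture outlines ------------------------------------------------------

def write_outline_csv(outlines: Sequence[ApertureOutline], path: str | Path) -> None:
    frames = []
    for o in outlines:
        n = len(o.points)
        flags = np.zeros(n, dtype=int)
        flags[o.anterior_index] = 1
        frames.append(
            pd.DataFrame(
                {
                    "shell_id": o.shell_id,
                    "outline_id": o.outline_id,
                    "point_index": np.arange(n),
                    "x_mm": o.points[:, 0],
                    "y_mm": o.points[:, 1],
                    "z_mm": o.points[:, 2],
                    "is_anterior": flags,
                    "s_mm": np.nan if o.s_position is None else o.s_position,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_outline_csv(path: str | Path) -> list[ApertureOutline]:
    """Outlines grouped by (shell_id, outline_id), points in file order.

    Requires exactly one ``is_anterior = 1`` flag and at least 3 points per
    outline; non-numeric coordinates are a schema error.
    """
    df = pd.read_csv(path)
    _require_columns(df, OUTLINE_COLUMNS, path)
    for col in ("x_mm", "y_mm", "z_mm"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            raise ValidationError(f"{path}: non-numeric values in column {col}")
    outlines = []
    for (shell, oid), grp in df.groupby(["shell_id", "outline_id"], sort=False):
        grp = grp.sort_values("point_index")
        if len(grp) < 3:
            raise ValidationError(f"{path}: outline {oid} has fewer than 3 points")
        flags = np.flatnonzero(grp["is_anterior"].to_numpy() == 1)
        if flags.size != 1:
            raise ValidationError(
                f"{path}: outline {oid} has {flags.size} anterior flags (need exactly 1)"
            )
        s_val = grp["s_mm"].iloc[0] if "s_mm" in grp.columns else np.nan
        outlines.append(
            ApertureOutline(
                points=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                anterior_index=int(flags[0]),
                s_position=None if pd.isna(s_val) else float(s_val),
                outline_id=str(oid),
                shell_id=str(shell),
            )
        )
    return outlines


# -- growth records ---------------------------------------------------------

def write_growth_tsv(records: Sequence[GrowthRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "plot_id": [r.plot_id for r in records],
            "s_start_mm": [r.s_start for r in records],
            "s_end_mm": [r.s_end for r in records],
            "duration_days": [r.duration for r in records],
            "phase": [r.phase or "" for r in records],
            "rate_mm_per_day": [r.rate for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_growth_tsv(path: str | Path) -> list[GrowthRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, GROWTH_COLUMNS, path)
    return [
        GrowthRecord(
            individual_id=str(row.individual_id),
            plot_id="" if pd.isna(row.plot_id) else str(row.plot_id),
            s_start=float(row.s_start_mm),
            s_end=float(row.s_end_mm),
            duration=float(row.duration_days),
            phase=None if pd.isna(row.phase) or row.phase == "" else str(row.phase),
        )
        for row in df.itertuples()
    ]


# -- rib series -------------------------------------------------------------

def write_rib_csv(series: Sequence[RibSeries], path: str | Path) -> None:
    frames = []
    for rs in series:
        frames.append(
            pd.DataFrame(
                {
                    "shell_id": rs.shell_id,
                    "rib_index": np.arange(rs.positions.size),
                    "s_mm": rs.positions,
                    "constriction_s_mm": rs.constriction_s,
                    "total_length_mm": rs.total_axis_length,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rib_csv(path: str | Path) -> list[RibSeries]:
    df = pd.read_csv(path)
    _require_columns(df, RIB_COLUMNS, path)
    out = []
    for shell, grp in df.groupby("shell_id", sort=False):
        grp = grp.sort_values("rib_index")
        out.append(
            RibSeries(
                shell_id=str(shell),
                positions=grp["s_mm"].to_numpy(dtype=float),
                constriction_s=float(grp["constriction_s_mm"].iloc[0]),
                total_axis_length=float(grp["total_length_mm"].iloc[0]),
            )
        )
    return out


# -- result tables ----------------------------------------------------------

def write_harmonics_tsv(
    sets: Sequence[NormalizedHarmonicSet | HarmonicSet], path: str | Path
) -> None:
    """Coefficient table: one row per outline, 6K coefficient columns."""
    rows = []
    for h in sets:
        if isinstance(h, HarmonicSet):
            from .efa import normalize_harmonics

            h = normalize_harmonics(h)
        row = {"shell_id": h.shell_id, "outline_id": h.outline_id,
               "s_mm": np.nan if h.s_position is None else h.s_position}
        row.update(zip(NormalizedHarmonicSet.coefficient_names(h.K), h.coeffs))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_perimeters_tsv(profile: pd.DataFrame, path: str | Path) -> None:
    profile.rename(
        columns={"s_mm": "s_mm", "perimeter_mm": "perimeter_mm"}
    ).to_csv(path, sep="\t", index=False)


def write_rotation_tsv(triples: Sequence[RotationTriple], path: str | Path) -> None:
    pd.DataFrame(
        {
            "s_mm": [t.s_position for t in triples],
            "theta_x_deg": [t.theta_x for t in triples],
            "theta_y_deg": [t.theta_y for t in triples],
            "theta_z_deg": [t.theta_z for t in triples],
            "old_id": [t.old_id for t in triples],
            "new_id": [t.new_id for t in triples],
            "gimbal_degenerate": [t.gimbal_degenerate for t in triples],
        }
    ).to_csv(path, sep="\t", index=False)


def write_curvature_tsv(profile: CurvatureTorsionProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "s_mm": profile.s,
            "kappa_per_mm": profile.kappa,
            "tau_per_mm": profile.tau,
            "support": profile.support,
            "degenerate": profile.degenerate,
        }
    ).to_csv(path, sep="\t", index=False)
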