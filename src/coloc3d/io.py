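"""File formats and the end-to-end measurement pipeline.

Conventions: nanometers everywhere internally; pixels only at I/O
boundaries with an explicit geometry.  CSV tables are comma-separated UTF-8
with mandatory headers.  Summary JSON files round floats to 6 significant
digits and carry a ``schema_version`` field; per-record CSVs keep full
precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ca_calibration import (
    CACalibration,
    CAGradient,
    CentroidPair,
    compute_ca_stats,
    correct_displacement,
    fit_ca_gradient,
    select_measurement_region,
)
from .separation_analysis import (
    DEFAULT_ML_FLOOR,
    SeparationSummary,
    delta_pair,
    separation_record,
    summarize,
)

SCHEMA_VERSION = "1.0"

_NM_COLS = ["Xg", "Yg", "Zg", "Xr", "Yr", "Zr"]
_PX_COLS = [c + "_px" for c in _NM_COLS]
_META_COLS = ["cell_id", "pair_id", "sister_id"]

__all__ = [
    "read_centroid_table",
    "write_centroid_table",
    "write_calibration_json",
    "read_calibration_json",
    "RunConfig",
    "run_pipeline",
]


def read_centroid_table(path, geometry=None) -> list[CentroidPair]:
    """Read a centroid-pair CSV into :class:`CentroidPair` records.

    Coordinate columns are either ``Xg..Zr`` (nm) or ``Xg_px..Zr_px``
    (pixels; requires ``geometry`` for the nm conversion, lateral by
    dx/dy and axial by dz).  A table carrying both sets is rejected as
    mixed-unit.  ``x_px``/``y_px`` field-position columns are optional.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    has_nm = [c for c in _NM_COLS if c in df.columns]
    has_px = [c for c in _PX_COLS if c in df.columns]
    if has_nm and has_px:
        raise ValueError("mixed units: table has both nm (Xg..Zr) and px (Xg_px..Zr_px) columns")
    if has_px:
        missing = [c for c in _PX_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {', '.join(missing)}")
        if geometry is None:
            raise ValueError("pixel-unit table requires a StackGeometry for nm conversion")
        scale = {"X": geometry.dx, "Y": geometry.dy, "Z": geometry.dz}
        for nm_col, px_col in zip(_NM_COLS, _PX_COLS):
            df[nm_col] = df[px_col] * scale[nm_col[0]]
    else:
        missing = [c for c in _NM_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {', '.join(missing)}")

    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            CentroidPair(
                Xg=float(row["Xg"]),
                Yg=float(row["Yg"]),
                Zg=float(row["Zg"]),
                Xr=float(row["Xr"]),
                Yr=float(row["Yr"]),
                Zr=float(row["Zr"]),
                x_px=float(row["x_px"]) if "x_px" in df.columns and not _isna(row["x_px"]) else None,
                y_px=float(row["y_px"]) if "y_px" in df.columns and not _isna(row["y_px"]) else None,
                cell_id=str(row["cell_id"]) if "cell_id" in df.columns else "",
                pair_id=str(row["pair_id"]) if "pair_id" in df.columns else "",
                sister_id=str(row["sister_id"]) if "sister_id" in df.columns else "",
            )
        )
    return pairs


def _isna(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def write_centroid_table(pairs: list[CentroidPair], path) -> None:
    rows = []
    for p in pairs:
        rows.append(
            dict(
                cell_id=p.cell_id,
                pair_id=p.pair_id,
                sister_id=p.sister_id,
                Xg=p.Xg,
                Yg=p.Yg,
                Zg=p.Zg,
                Xr=p.Xr,
                Yr=p.Yr,
                Zr=p.Zr,
                x_px=p.x_px,
                y_px=p.y_px,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _round_sig(x, sig: int = 6):
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, float):
        if not math.isfinite(x):
            return None
        return float(f"{x:.{sig}g}")
    if isinstance(x, (np.floating,)):
        return _round_sig(float(x), sig)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def write_calibration_json(calib: CACalibration, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "means": {"x": calib.CAmx, "y": calib.CAmy, "z": calib.CAmz},
        "sds": {"x": calib.CAsd_x, "y": calib.CAsd_y, "z": calib.CAsd_z},
        "n": calib.n,
        "gradients": {
            ax: {"slope": g.slope, "intercept": g.intercept, "residual_sd": g.residual_sd}
            for ax, g in calib.gradients.items()
        },
    }
    Path(path).write_text(json.dumps(_round_sig(payload), indent=2, sort_keys=True) + "\n")


def read_calibration_json(path) -> CACalibration:
    d = json.loads(Path(path).read_text())
    calib = CACalibration(
        CAmx=d["means"]["x"],
        CAmy=d["means"]["y"],
        CAmz=d["means"]["z"],
        CAsd_x=d["sds"]["x"],
        CAsd_y=d["sds"]["y"],
        CAsd_z=d["sds"]["z"],
        n=int(d["n"]),
    )
    for ax, g in d.get("gradients", {}).items():
        calib.gradients[ax] = CAGradient(
            axis=ax, slope=g["slope"], intercept=g["intercept"], residual_sd=g["residual_sd"]
        )
    return calib


@dataclass
class RunConfig:
    """Configuration of one end-to-end measurement run."""

    centroid_csv: str
    calibration: str  # calibration CSV (computed) or calibration JSON (precomputed)
    out_dir: str
    ml_floor: float = DEFAULT_ML_FLOOR
    correction_mode: str = "mean"  # or "gradient"
    region: tuple[float, float, float, float] | None = None  # x_min, x_max, y_min, y_max
    axis_channel: str = "green"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_calibration(source: str, correction_mode: str) -> CACalibration:
    path = Path(source)
    if path.suffix.lower() == ".json":
        return read_calibration_json(path)
    pairs = read_centroid_table(path)
    calib = compute_ca_stats(pairs)
    if correction_mode == "gradient":
        calib.gradients["x"] = fit_ca_gradient(pairs, "x")
        calib.gradients["y"] = fit_ca_gradient(pairs, "y")
    return calib


def _group_sisters(pairs: list[CentroidPair]):
    """Yield (sister1, sister2) tuples and the list of unpaired records."""
    groups: dict[tuple[str, str], list[CentroidPair]] = {}
    unpaired = []
    for p in pairs:
        if p.pair_id and p.sister_id:
            groups.setdefault((p.cell_id, p.pair_id), []).append(p)
        else:
            unpaired.append(p)
    sisters = []
    for key, members in groups.items():
        if len(members) == 2:
            sisters.append(tuple(sorted(members, key=lambda m: m.sister_id)))
        else:
            unpaired.extend(members)
    return sisters, unpaired


def summary_to_dict(summary: SeparationSummary) -> dict:
    out = {
        "n": summary.n,
        "s2d_mean": summary.s2d_mean,
        "s2d_sd": summary.s2d_sd,
        "s3d_mean": summary.s3d_mean,
        "s3d_sd": summary.s3d_sd,
        "alpha_mean": summary.alpha_mean,
        "alpha_sd": summary.alpha_sd,
        "beta_mean": summary.beta_mean,
        "beta_sd": summary.beta_sd,
        "z_offset": summary.z_offset,
        "zs3d_mean": summary.zs3d_mean,
        "zs3d_sd": summary.zs3d_sd,
        "delta_mean": summary.delta_mean,
        "delta_sd": summary.delta_sd,
    }
    for name in ("ml2d", "ml3d"):
        fit = getattr(summary, name)
        if fit is not None:
            out[name] = {
                "mu_hat": fit.mu_hat,
                "sigma_hat": fit.sigma_hat,
                "raw_sd": fit.raw_sd,
                "at_boundary": fit.at_boundary,
                "applicable": getattr(summary, f"{name}_applicable"),
            }
        else:
            out[name] = None
    return out


def run_pipeline(config: RunConfig) -> SeparationSummary:
    """Run calibration -> correction -> separation analysis on centroid tables.

    Writes ``records.csv`` (per-spot corrected vectors and observables),
    ``summary.json`` and ``run.log`` into ``config.out_dir``.  Deterministic
    given inputs: identical runs produce byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs = read_centroid_table(config.centroid_csv)
    if config.region is not None:
        x0, x1, y0, y1 = config.region
        pairs = select_measurement_region(pairs, (x0, x1), (y0, y1))
    if len(pairs) < 2:
        raise ValueError("fewer than 2 usable centroid records")

    calib = _load_calibration(config.calibration, config.correction_mode)
    if calib.n < 2:
        raise ValueError("calibration requires at least 2 records")

    sisters, unpaired = _group_sisters(pairs)
    records = []
    deltas = []
    for s1, s2 in sisters:
        delta, u = delta_pair(s1, s2, axis_channel=config.axis_channel)
        deltas.append(delta)
        kk_xy = (u[0], u[1]) if (u[0], u[1]) != (0.0, 0.0) else (1.0, 0.0)
        for member in (s1, s2):
            sx, sy, sz = correct_displacement(member, calib, mode=config.correction_mode)
            records.append(
                separation_record(
                    sx, sy, sz, kk_axis=kk_xy, pair_id=member.pair_id, sister_id=member.sister_id
                )
            )
    for p in unpaired:
        sx, sy, sz = correct_displacement(p, calib, mode=config.correction_mode)
        records.append(separation_record(sx, sy, sz, pair_id=p.pair_id, sister_id=p.sister_id))

    summary = summarize(records, delta_values=deltas or None, ml_floor=config.ml_floor)

    rec_df = pd.DataFrame(
        [
            dict(
                pair_id=r.pair_id,
                sister_id=r.sister_id,
                Sx=r.Sx,
                Sy=r.Sy,
                Sz=r.Sz,
                s2d=r.s2d,
                s3d=r.s3d,
                alpha=r.alpha,
                beta=r.beta,
            )
            for r in records
        ]
    )
    rec_df.to_csv(out_dir / "records.csv", index=False)

    payload = {"schema_version": SCHEMA_VERSION, "seed": config.seed}
    payload.update(summary_to_dict(summary))
    (out_dir / "summary.json").write_text(
        json.dumps(_round_sig(payload), indent=2, sort_keys=True) + "\n"
    )

    log_lines = [
        f"schema_version: {SCHEMA_VERSION}",
        f"config_hash: {config.config_hash()}",
        f"seed: {config.seed}",
        f"n_records: {summary.n}",
        f"n_sister_pairs: {len(sisters)}",
        f"calibration_n: {calib.n}",
        f"correction_mode: {config.correction_mode}",
        f"s3d_mean_nm: {summary.s3d_mean:.6g}",
        f"ml3d_mu_nm: {summary.ml3d.mu_hat:.6g}" if summary.ml3d else "ml3d_mu_nm: n/a",
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
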