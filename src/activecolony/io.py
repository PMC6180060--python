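"""Track tables, field containers, configuration and the analysis pipeline.

Conventions: coordinates in micrometres with y up, angles in radians from the
+x axis folded to ``[0, pi)``, frame times in minutes.  Track tables are
CSV/TSV with columns ``frame, time_min, cell_id, x_um, y_um, length_um,
width_um, angle_rad`` (``parent_id`` optional); fields are stored in HDF5.
Every output carries the configuration hash and the seed so reruns are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ColonyFrame, ColonyTimeSeries, fold_angle

__all__ = [
    "TrackParseError",
    "AnalysisConfig",
    "read_tracks",
    "write_tracks",
    "write_fields_hdf5",
    "read_fields_hdf5",
    "config_hash",
    "run_pipeline",
]

log = logging.getLogger("activecolony")

REQUIRED_COLUMNS = [
    "frame",
    "time_min",
    "cell_id",
    "x_um",
    "y_um",
    "length_um",
    "width_um",
    "angle_rad",
]


class TrackParseError(ValueError):
    """Malformed track table; the message names the offending column or row."""


@dataclass
class AnalysisConfig:
    """Configuration of the track-analysis pipeline."""

    input_path: str
    output_dir: str
    grid_spacing: float = 0.3  # um
    sigma: float = 0.9  # coarse-graining length, um
    velocity_bin_width: float = 2.0  # um, radial-velocity binning
    anchoring_bin_deg: float = 10.0
    defect_peak_rel_threshold: float = 0.1
    corr_r_max: float = 12.0  # um
    seed: int = 0
    log_level: str = "INFO"
    write_fields: bool = False

    def __post_init__(self):
        for name in (
            "grid_spacing",
            "sigma",
            "velocity_bin_width",
            "anchoring_bin_deg",
            "defect_peak_rel_threshold",
            "corr_r_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not Path(self.input_path).exists():
            raise FileNotFoundError(f"input path does not exist: {self.input_path}")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def config_hash(config: AnalysisConfig) -> str:
    """Stable short hash of the configuration (for output provenance)."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_tracks(path) -> ColonyTimeSeries:
    """Read and validate a cell-track table into a :class:`ColonyTimeSeries`.

    Rejects malformed input explicitly: missing columns, duplicate
    ``(frame, cell_id)`` pairs and non-monotonic frame times raise
    :class:`TrackParseError` naming the offending row.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"missing required column(s): {', '.join(missing)}")
    for col in REQUIRED_COLUMNS:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise TrackParseError(f"missing value in column '{col}' at row {row}")
    dup = df.duplicated(subset=["frame", "cell_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise TrackParseError(f"duplicate (frame, cell_id) at row {row}")

    has_parent = "parent_id" in df.columns
    frames = []
    lineage: dict[int, int] = {}
    prev_time = None
    for fidx in sorted(df["frame"].unique()):
        sub = df[df["frame"] == fidx]
        times = sub["time_min"].unique()
        if len(times) > 1:
            row = int(sub.index[1])
            raise TrackParseError(f"inconsistent time_min within frame {fidx} (row {row})")
        t = float(times[0])
        if prev_time is not None and t <= prev_time:
            row = int(sub.index[0])
            raise TrackParseError(f"non-monotonic time_min at frame {fidx} (row {row})")
        prev_time = t
        parents = (
            sub["parent_id"].fillna(-1).to_numpy(int) if has_parent else np.full(len(sub), -1)
        )
        frame = ColonyFrame(
            time=t,
            ids=sub["cell_id"].to_numpy(int),
            x=sub["x_um"].to_numpy(float),
            y=sub["y_um"].to_numpy(float),
            length=sub["length_um"].to_numpy(float),
            width=sub["width_um"].to_numpy(float),
            angle=fold_angle(sub["angle_rad"].to_numpy(float)),
            parent_ids=parents,
        )
        frames.append(frame)
        for cid, pid in zip(frame.ids, parents):
            if pid >= 0:
                lineage[int(cid)] = int(pid)
    return ColonyTimeSeries(frames=frames, lineage=lineage)


def write_tracks(series: ColonyTimeSeries, path) -> None:
    """Write a series as a CSV/TSV track table (round-trips with read_tracks)."""
    rows = []
    for fidx, frame in enumerate(series):
        parents = frame.parent_ids if frame.parent_ids is not None else np.full(frame.n_cells, -1)
        for i in range(frame.n_cells):
            rows.append(
                {
                    "frame": fidx,
                    "time_min": frame.time,
                    "cell_id": int(frame.ids[i]),
                    "x_um": frame.x[i],
                    "y_um": frame.y[i],
                    "length_um": frame.length[i],
                    "width_um": frame.width[i],
                    "angle_rad": frame.angle[i],
                    "parent_id": int(parents[i]),
                }
            )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# field containers
# ---------------------------------------------------------------------------


def write_fields_hdf5(path, fields: dict, attrs: dict | None = None) -> None:
    """Write named fields to HDF5.

    ``fields`` maps names to :class:`~activecolony.fields.ScalarField`,
    :class:`~activecolony.fields.QTensorField` or plain arrays; grid metadata
    is stored as dataset attributes and ``attrs`` (e.g. config hash, seed) as
    file attributes.
    """
    import h5py

    from .fields import QTensorField, ScalarField

    with h5py.File(path, "w") as fh:
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v
        for name, fld in fields.items():
            if isinstance(fld, ScalarField):
                ds = fh.create_dataset(name, data=fld.values)
                _grid_attrs(ds, fld.grid)
            elif isinstance(fld, QTensorField):
                grp = fh.create_group(name)
                for comp in ("Qxx", "Qxy"):
                    grp.create_dataset(comp, data=getattr(fld, comp))
                _grid_attrs(grp, fld.grid)
            else:
                fh.create_dataset(name, data=np.asarray(fld))


def _grid_attrs(obj, grid) -> None:
    for k in ("x0", "y0", "h", "nx", "ny"):
        obj.attrs[k] = getattr(grid, k)


def read_fields_hdf5(path) -> dict:
    """Read fields written by :func:`write_fields_hdf5`."""
    import h5py

    from .fields import Grid, QTensorField, ScalarField

    out: dict = {"_attrs": {}}
    with h5py.File(path, "r") as fh:
        out["_attrs"] = dict(fh.attrs)
        for name, node in fh.items():
            if isinstance(node, h5py.Group):
                grid = Grid(**{k: node.attrs[k] for k in ("x0", "y0", "h", "nx", "ny")})
                out[name] = QTensorField(grid=grid, Qxx=node["Qxx"][()], Qxy=node["Qxy"][()])
            elif all(k in node.attrs for k in ("x0", "y0", "h", "nx", "ny")):
                grid = Grid(**{k: node.attrs[k] for k in ("x0", "y0", "h", "nx", "ny")})
                out[name] = ScalarField(grid=grid, values=node[()])
            else:
                out[name] = node[()]
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _analyze_frame(frame, config: AnalysisConfig, frame_index: int) -> dict:
    from .defects import detect_defects
    from .fields import GrainParams, Grid, q_tensor_field
    from .order import aspect_ratio, boundary_anchoring, global_order

    summary: dict = {
        "frame": frame_index,
        "time_min": frame.time,
        "n_cells": int(frame.n_cells),
        "global_order": global_order(frame),
    }
    if frame.n_cells >= 2:
        shape = aspect_ratio(frame)
        summary["aspect_ratio"] = shape.aspect_ratio
    if frame.n_cells >= 6:
        try:
            anch = boundary_anchoring(frame)
            summary["psi_median_deg"] = float(anch.median_psi)
            summary["psi_hist"] = [int(c) for c in anch.hist_counts]
        except Exception as exc:  # degenerate boundaries
            log.warning("anchoring skipped for frame %d: %s", frame_index, exc)
    gp = GrainParams(sigma=config.sigma)
    grid = Grid.for_frame(frame, h=config.grid_spacing, sigma=config.sigma)
    qf = q_tensor_field(frame, grid, gp)
    dets = detect_defects(qf, frame=frame_index, peak_rel_threshold=config.defect_peak_rel_threshold)
    summary["n_defects_plus"] = sum(1 for d in dets if d.charge > 0)
    summary["n_defects_minus"] = sum(1 for d in dets if d.charge < 0)
    return summary, qf, dets


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run coarse-graining, order metrics and defect analysis per frame.

    Writes per-frame JSON summaries, a defect CSV and (optionally) field
    HDF5 files under ``config.output_dir``; returns the bundle as a dict.
    All outputs carry the config hash and seed.  Raises with the failing
    stage named in the log on any error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    stage = "read_tracks"
    try:
        series = read_tracks(config.input_path)
        frame_summaries = []
        defect_rows = []
        for i, frame in enumerate(series):
            stage = f"analyze_frame[{i}]"
            summary, qf, dets = _analyze_frame(frame, config, i)
            frame_summaries.append(summary)
            for d in dets:
                defect_rows.append(
                    {
                        "frame": i,
                        "time_min": frame.time,
                        "x_um": d.x,
                        "y_um": d.y,
                        "charge": d.charge,
                        "q_peak": d.q_peak,
                        "pol_x": d.polarity[0] if d.polarity is not None else np.nan,
                        "pol_y": d.polarity[1] if d.polarity is not None else np.nan,
                    }
                )
            if config.write_fields:
                stage = f"write_fields[{i}]"
                write_fields_hdf5(
                    outdir / f"fields_{i:04d}.h5",
                    {"Q": qf},
                    attrs={"config_hash": chash, "seed": config.seed},
                )

        stage = "expansion_fit"
        hubble = None
        if len(series) >= 2 and series[-1].n_cells >= 20:
            from .order import radial_velocity_profile

            try:
                fit = radial_velocity_profile(
                    series, len(series) - 1, bin_width=config.velocity_bin_width
                )
                hubble = {"H_per_min": fit.H, "intercept": fit.intercept}
            except Exception as exc:
                log.warning("expansion fit skipped: %s", exc)

        stage = "write_outputs"
        bundle = {
            "config_hash": chash,
            "seed": config.seed,
            "frames": frame_summaries,
            "hubble_fit": hubble,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        pd.DataFrame(
            defect_rows,
            columns=["frame", "time_min", "x_um", "y_um", "charge", "q_peak", "pol_x", "pol_y"],
        ).to_csv(outdir / "defects.csv", index=False)
        return bundle
    except Exception:
        log.error("pipeline failed at stage %s", stage)
        raise
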