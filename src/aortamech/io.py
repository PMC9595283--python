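"""Delimited-text file formats and run configuration.

All tables are UTF-8 comma-separated text with a header row and '.' decimal
point.  The curve table has one row per sample point
(``specimen_id, region, direction, stretch, stress_MPa``); stress carries
its unit in the column name because the constitutive literature rarely
states one.  Ground truth and fit results serialize to tidy long/wide
tables.  Run configuration is a flat ``key = value`` text file with unknown
keys rejected.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aortamech import __version__ as _pkg_version
from aortamech.curves import REGIONS, StressStretchCurve
from aortamech.fitting import FitResult, ParameterDistribution
from aortamech.models import MODEL_PARAM_CLASSES, LoadingDirection
from aortamech.pairing import SpecimenSet
from aortamech.synthetic import GroundTruth, SyntheticConfig

__all__ = [
    "CurveTableError",
    "CURVE_COLUMNS",
    "read_curves",
    "write_curves",
    "write_ground_truth",
    "write_fit_results",
    "fits_to_frame",
    "distributions_to_frame",
    "RunConfig",
    "log_run",
]

CURVE_COLUMNS = ["specimen_id", "region", "direction", "stretch", "stress_MPa"]


class CurveTableError(ValueError):
    """Malformed curve table; the message names the offending row."""


def write_curves(sets: list[SpecimenSet], path) -> None:
    """Serialize specimen sets to the curve-table CSV format."""
    rows = []
    for s in sets:
        for curve in list(s.circumferential) + list(s.longitudinal):
            rows.append(pd.DataFrame({
                "specimen_id": curve.specimen_id,
                "region": curve.region,
                "direction": curve.direction.code,
                "stretch": curve.stretch,
                "stress_MPa": curve.stress,
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.17g")


def read_curves(path) -> list[SpecimenSet]:
    """Read and validate a curve table, grouped by region and direction.

    Validation failures (missing columns, non-numeric values, unknown region
    codes, non-monotone stretch within a specimen) raise
    :class:`CurveTableError` naming the file row (1-based, header = row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"specimen_id": str},
                         float_precision="round_trip")
    except Exception as e:
        raise CurveTableError(f"{path}: cannot parse CSV: {e}") from e
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveTableError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise CurveTableError(f"{path}: no data rows")

    for col in ("stretch", "stress_MPa"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise CurveTableError(
                f"{path} row {bad[0] + 2}: non-numeric {col!r} value "
                f"{df[col].iloc[bad[0]]!r}")
        df[col] = vals
    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        i = int(np.flatnonzero(bad_region.to_numpy())[0])
        raise CurveTableError(
            f"{path} row {i + 2}: unknown region code {df['region'].iloc[i]!r}")

    by_region: dict[str, dict[str, list]] = {r: {"C": [], "L": []} for r in REGIONS}
    for (region, code, sid), g in df.groupby(
            ["region", "direction", "specimen_id"], sort=False):
        try:
            direction = LoadingDirection.from_code(str(code))
        except ValueError as e:
            raise CurveTableError(f"{path} specimen {sid}: {e}") from e
        stretch = g["stretch"].to_numpy()
        dec = np.flatnonzero(np.diff(stretch) <= 0)
        if dec.size:
            row = int(g.index[dec[0] + 1]) + 2
            raise CurveTableError(
                f"{path} row {row}: non-increasing stretch within specimen {sid}")
        try:
            curve = StressStretchCurve(stretch, g["stress_MPa"].to_numpy(),
                                       region, direction, str(sid))
        except ValueError as e:
            raise CurveTableError(f"{path} specimen {sid}: {e}") from e
        by_region[region][direction.code].append(curve)

    sets = []
    for region in REGIONS:
        circ, long_ = by_region[region]["C"], by_region[region]["L"]
        if circ or long_:
            sets.append(SpecimenSet(region, circ, long_))
    return sets


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Ground truth as a tidy table (level, region, direction, index, param, value)."""
    rows = []
    for region, p in gt.region_params.items():
        for name in type(p).param_names():
            rows.append(("region", region, "", "", name, getattr(p, name)))
    for (region, code, idx), p in gt.specimen_params.items():
        for name in type(p).param_names():
            rows.append(("specimen", region, code, idx, name, getattr(p, name)))
    pd.DataFrame(rows, columns=["level", "region", "direction", "index",
                                "parameter", "value"]).to_csv(
        path, index=False, float_format="%.17g")


def fits_to_frame(fits: list, meta: list[dict] | None = None) -> pd.DataFrame:
    """Wide per-fit table: metadata + parameter columns + diagnostics."""
    rows = []
    meta = meta or [{} for _ in fits]
    for fr, m in zip(fits, meta):
        row = dict(m)
        row["model"] = fr.model
        if fr.params is not None:
            for name in type(fr.params).param_names():
                row[name] = getattr(fr.params, name)
        row["r2_circ"], row["r2_long"] = fr.per_direction_R2
        row["residual_norm"] = fr.residual_norm
        row["converged"] = fr.converged
        row["tolerance_used"] = fr.tolerance_used
        row["fallback"] = fr.fallback
        rows.append(row)
    return pd.DataFrame(rows)


def distributions_to_frame(dists: list[ParameterDistribution]) -> pd.DataFrame:
    """Min/1Q/median/3Q/max summary layout, one row per (region, parameter)."""
    return pd.DataFrame([dataclasses.asdict(d) for d in dists])


def write_fit_results(fits, meta, dists, out_dir, model: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fits_to_frame(fits, meta).to_csv(out_dir / f"fits_{model}.csv", index=False)
    distributions_to_frame(dists).to_csv(
        out_dir / f"distributions_{model}.csv", index=False)


# ---------------------------------------------------------------------------
# Run configuration and logging
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat run configuration shared by the command-line pipeline."""

    seed: int = 0
    model: str = "holzapfel"
    noise_sd_fraction: float = 0.02
    points_per_curve: int = 80
    jitter_sd: float = 0.08
    n_starts: int = 8
    joint_starts: int = 4
    r2_floor: float = 0.9
    min_window: int = 5
    derivative_fit: str = "linear"
    max_pairs: int = 0  # 0 = all pairs
    correlation_method: str = "spearman"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path} line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path} line {lineno}: unknown key {key!r}")
            default = getattr(cls(), key)
            kwargs[key] = type(default)(value) if not isinstance(default, str) else value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            seed=self.seed, model=self.model,
            noise_sd_fraction=self.noise_sd_fraction,
            points_per_curve=self.points_per_curve,
            jitter_sd=self.jitter_sd,
        )


def log_run(out_dir, command: str, config: RunConfig) -> None:
    """Append one reproducibility line (timestamp, version, seed, config)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    fields = " ".join(f"{f.name}={getattr(config, f.name)}"
                      for f in dataclasses.fields(config))
    with open(out_dir / "run.log", "a") as fh:
        fh.write(f"{stamp} aortamech={_pkg_version} command={command} {fields}\n")
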