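"""File ingestion, pipeline orchestration, and the summary report.

``read_values`` pulls one numeric column out of delimited text, counting
(never silently dropping) unparseable rows.  ``run_pipeline`` chains grid →
sweep → selection → network → mode/spread/outliers into an :class:`NBReport`
plus a per-value table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    IngestionError,
    UndefinedIndexError,
)
from .metrics import ModeResult, SpreadMetrics, mode_estimate, shortest_paths_interval
from .network import Sample, SimilarityNetwork, build_network_fast, giant_cluster_proportion
from .outliers import OutlierReport, detect_outliers, subsample
from .selection import (
    ZetaSelection,
    ZetaSweep,
    default_grid,
    homogeneity_index,
    select_zeta,
    sweep_zeta,
)

__all__ = [
    "NBReport",
    "PipelineConfig",
    "PipelineResult",
    "read_values",
    "run_pipeline",
    "parse_config_file",
]

#: Column order of the summary table, matching the method's canonical layout.
REPORT_COLUMNS = ["V", "E", "zeta_s", "M", "H", "p_g", "D", "L_avg",
                  "outlier_count", "stable", "boundary_flag"]


@dataclass(frozen=True)
class NBReport:
    """Summary of one analysis run.

    ``H`` is always ``zeta_s / M`` when M is nonzero; ``D``/``L_avg``/``H``
    are ``None`` when not computable (edgeless network, zero mode).
    """

    V: int
    E: int
    zeta_s: float
    M: float
    H: Optional[float]
    p_g: float
    D: Optional[int]
    L_avg: Optional[float]
    outlier_count: int
    stable: bool
    boundary_flag: bool
    max_degree: int = 0
    scale: str = "raw"
    label: str = ""

    def to_dict(self) -> Dict[str, Any]:
        """Full-precision mapping (JSON-ready; None for not-computable)."""
        return {
            "V": self.V,
            "E": self.E,
            "zeta_s": self.zeta_s,
            "M": self.M,
            "H": self.H,
            "p_g": self.p_g,
            "D": self.D,
            "L_avg": self.L_avg,
            "outlier_count": self.outlier_count,
            "stable": self.stable,
            "boundary_flag": self.boundary_flag,
            "max_degree": self.max_degree,
            "scale": self.scale,
            "label": self.label,
        }

    def summary_row(self) -> Dict[str, Any]:
        """Display-rounded row: M and L_avg to 2 decimals, H to 4."""
        return {
            "V": self.V,
            "E": self.E,
            "zeta_s": round(self.zeta_s, 4),
            "M": round(self.M, 2),
            "H": None if self.H is None else round(self.H, 4),
            "p_g": round(self.p_g, 4),
            "D": self.D,
            "L_avg": None if self.L_avg is None else round(self.L_avg, 2),
            "outlier_count": self.outlier_count,
            "stable": self.stable,
            "boundary_flag": self.boundary_flag,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.summary_row()], columns=REPORT_COLUMNS)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the analysis pipeline; defaults mirror the method's own."""

    zeta_min_frac: float = 0.01
    zeta_max_frac: float = 0.10
    zeta_steps: int = 10
    window_frac: float = 0.30
    min_pg: Optional[float] = None
    with_paths: bool = True
    sample_fraction: Optional[float] = None
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass(frozen=True)
class PipelineResult:
    """Report plus the per-value table and intermediate diagnostics."""

    report: NBReport
    values_table: pd.DataFrame
    network: SimilarityNetwork
    mode: ModeResult
    spread: SpreadMetrics
    outliers: OutlierReport
    sweep: Optional[ZetaSweep] = None
    selection: Optional[ZetaSelection] = None


_CONFIG_CASTS = {
    "zeta_min_frac": float,
    "zeta_max_frac": float,
    "zeta_steps": int,
    "window_frac": float,
    "min_pg": float,
    "with_paths": None,   # bool, handled below
    "sample_fraction": float,
    "seed": int,
    "column": None,       # str-or-int, handled below
    "delimiter": str,
    "log_transform": None,
}

_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


def _parse_bool(raw: str, key: str) -> bool:
    low = raw.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ConfigurationError(f"config key {key!r}: cannot parse {raw!r} as a boolean")


def parse_config_file(path: Union[str, Path]) -> Dict[str, Any]:
    """Parse a plain ``key = value`` config file ('#' starts a comment)."""
    out: Dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in stripped.split("=", 1))
        if key not in _CONFIG_CASTS:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        if key in ("with_paths", "log_transform"):
            out[key] = _parse_bool(raw, key)
        elif key == "column":
            out[key] = int(raw) if raw.lstrip("+-").isdigit() else raw
        elif key == "min_pg" and raw.lower() in ("none", ""):
            out[key] = None
        else:
            out[key] = _CONFIG_CASTS[key](raw)
    return out


def read_values(
    path: Union[str, Path],
    column: Union[str, int] = 0,
    delimiter: Optional[str] = None,
    log_transform: bool = False,
) -> Sample:
    """Read one numeric column from delimited text into a :class:`Sample`.

    A string ``column`` selects by header name (the first row is the
    header); an integer selects by position with no header row, so a header
    line in such a file simply counts as one rejected row.  Rows that fail
    numeric parsing are tallied in ``meta['rejected_rows']``.  With
    ``log_transform``, non-positive values are excluded
    (``meta['nonpositive_excluded']``) and the natural log is applied; the
    analysis then proceeds on the log scale, recorded in ``meta['scale']``.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if isinstance(column, str):
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
        if column not in frame.columns:
            raise ConfigurationError(
                f"column {column!r} not found in {path.name}; "
                f"available: {list(frame.columns)}"
            )
        raw = frame[column]
    else:
        frame = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                            keep_default_na=False)
        if not -frame.shape[1] <= column < frame.shape[1]:
            raise ConfigurationError(
                f"column index {column} out of range for {path.name} "
                f"({frame.shape[1]} columns)"
            )
        raw = frame.iloc[:, column]

    # python float() is correctly rounded, so written values round-trip
    # exactly (pandas' fast to_numeric parser can be off by one ulp)
    def _to_float(token: str) -> float:
        try:
            return float(token)
        except ValueError:
            return float("nan")

    numeric = np.array([_to_float(tok) for tok in raw], dtype=float)
    finite = np.isfinite(numeric)
    rejected = int((~finite).sum())
    values = numeric[finite]

    meta: Dict[str, Any] = {
        "source": str(path),
        "column": column,
        "rejected_rows": rejected,
        "scale": "raw",
    }
    if log_transform:
        nonpos = int((values <= 0).sum())
        values = np.log(values[values > 0])
        meta["nonpositive_excluded"] = nonpos
        meta["scale"] = "log"
    if values.size == 0:
        raise IngestionError(f"no parseable numeric values in {path.name}")
    return Sample(values, label=f"{path.name}[{column}]", meta=meta)


def run_pipeline(
    sample: Sample,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Full analysis: grid → sweep → select zeta_s → network → report.

    Constant samples (including n = 1) skip the sweep: every duplicate pair
    is adjacent at any zeta, so the network at zeta = 0 is already final and
    is reported with ``zeta_s = 0``.
    """
    cfg = config or PipelineConfig()
    if cfg.sample_fraction is not None:
        sample = subsample(sample, cfg.sample_fraction, cfg.seed)

    sweep: Optional[ZetaSweep] = None
    selection: Optional[ZetaSelection] = None
    if sample.max == sample.min:
        net = build_network_fast(sample, 0.0)
        zeta_s = 0.0
        stable = True
    else:
        grid = default_grid(sample, cfg.zeta_min_frac, cfg.zeta_max_frac, cfg.zeta_steps)
        sweep = sweep_zeta(sample, grid, with_paths=cfg.with_paths)
        selection = select_zeta(sweep, cfg.window_frac, cfg.min_pg)
        zeta_s = selection.zeta_s
        stable = selection.stable
        net = build_network_fast(sample, zeta_s)

    mode = mode_estimate(net)
    try:
        h: Optional[float] = homogeneity_index(zeta_s, mode.mode_value)
    except UndefinedIndexError:
        h = None
    spread = shortest_paths_interval(net) if net.edge_count else SpreadMetrics(None, None)
    outliers = detect_outliers(net)
    if selection is not None:
        selection = replace(selection, homogeneity=h)

    report = NBReport(
        V=sample.n,
        E=net.edge_count,
        zeta_s=zeta_s,
        M=mode.mode_value,
        H=h,
        p_g=giant_cluster_proportion(net),
        D=spread.diameter,
        L_avg=spread.avg_path_length,
        outlier_count=outliers.outlier_count,
        stable=stable,
        boundary_flag=mode.boundary_flag,
        max_degree=mode.max_degree,
        scale=str(sample.meta.get("scale", "raw")),
        label=sample.label,
    )
    table = pd.DataFrame({
        "value": sample.values,
        "degree": net.degrees,
        "cluster": net.cluster_labels,
        "is_outlier": ~net.giant_mask,
        "is_mode_tied": net.degrees == mode.max_degree,
    })
    return PipelineResult(
        report=report,
        values_table=table,
        network=net,
        mode=mode,
        spread=spread,
        outliers=outliers,
        sweep=sweep,
        selection=selection,
    )
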