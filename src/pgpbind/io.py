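"""CSV/JSON readers and writers for assay tables and fit results.

File conventions: comma-separated, '.' decimal, UTF-8, mandatory header row;
concentrations are in uM in files and converted to molar at this boundary.
Output JSON embeds the configuration hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import DoseResponsePoint, FitResult, ScanResult
from .titration import TitrationDataset


def read_titration_csv(path: str | Path, amphiphile_id: str = "") -> TitrationDataset:
    """Read a titration table with columns ``membrane``, ``membrane_unit``, ``signal``."""
    df = pd.read_csv(path)
    _require_columns(df, ["membrane", "membrane_unit", "signal"], path)
    units = df["membrane_unit"].unique()
    if len(units) != 1:
        raise ValueError(f"{path}: mixed membrane units {list(units)}")
    return TitrationDataset(
        membrane_amount=df["membrane"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        membrane_unit=str(units[0]),
        amphiphile_id=amphiphile_id,
    )


def write_titration_csv(path: str | Path, data: TitrationDataset) -> None:
    pd.DataFrame(
        {
            "membrane": data.membrane_amount,
            "membrane_unit": data.membrane_unit,
            "signal": data.signal,
        }
    ).to_csv(path, index=False)


def read_dose_response_csv(path: str | Path) -> list[DoseResponsePoint]:
    """Read a dose-response table with columns ``l_total_uM``, ``response_percent``."""
    df = pd.read_csv(path)
    _require_columns(df, ["l_total_uM", "response_percent"], path)
    sds = df["sd_percent"] if "sd_percent" in df.columns else [None] * len(df)
    return [
        DoseResponsePoint(
            l_total=float(lt) * 1e-6,
            response=float(r),
            sd=float(s) if s is not None and np.isfinite(s) else None,
        )
        for lt, r, s in zip(df["l_total_uM"], df["response_percent"], sds)
    ]


def write_dose_response_csv(path: str | Path, points: Sequence[DoseResponsePoint]) -> None:
    pd.DataFrame(
        {
            "l_total_uM": [p.l_total * 1e6 for p in points],
            "response_percent": [p.response for p in points],
            "sd_percent": [p.sd if p.sd is not None else np.nan for p in points],
        }
    ).to_csv(path, index=False)


def write_scan_csv(path: str | Path, scan: ScanResult) -> None:
    """Write the per-n scan table (columns n, chi2, kd_uM, kp_beta1)."""
    out = scan.table.copy()
    out["kd_uM"] = out.pop("kd") * 1e6
    out[["n", "chi2", "kd_uM", "kp_beta1", "success"]].to_csv(path, index=False)


def config_hash(config: Any) -> str:
    """Stable short hash of a (nested) configuration object."""
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_fit_json(
    path: str | Path,
    fit: FitResult,
    config: Optional[Any] = None,
    seed: Optional[int] = None,
) -> None:
    """Serialise a fit result with its provenance block."""
    doc = {
        "params": fit.params,
        "stderr": fit.stderr,
        "chi2": fit.chi2,
        "n_sites": fit.n_sites,
        "ndata": fit.ndata,
        "nfree": fit.nfree,
        "success": fit.success,
        "kd_uM": fit.kd * 1e6,
        "kp_from_beta1": fit.kp_from_beta1,
        "ci75": {k: list(v) for k, v in fit.ci75.items()},
        "provenance": {
            "config_hash": config_hash(config) if config is not None else None,
            "config": _jsonable(config) if config is not None else None,
            "seed": seed,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if hasattr(obj, "model_dump"):
        return _jsonable(obj.model_dump())
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
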