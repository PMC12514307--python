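"""Readers/writers for the plain-text formats the workflow touches.

Weights: one weight per line, N lines, line order = frame order.
Observable blocks: delimited tables handled in :mod:`idpreweight.forward`.
Scan traces and overlap matrices: TSV.  Configuration: flat YAML.
All numeric output is written at full double precision so that a write/read
round trip is bit-faithful.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import CalibrationResult

__all__ = [
    "read_weights",
    "write_weights",
    "write_scan_trace",
    "read_scan_trace",
    "write_overlap_matrix",
    "read_embedding_table",
    "write_calibration_report",
    "load_config",
    "write_provenance",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


def read_weights(path) -> np.ndarray:
    w = np.loadtxt(path, dtype=float, ndmin=1)
    if w.ndim != 1:
        raise ValueError(f"{path}: weights file must hold one number per line")
    return w


def write_weights(path, weights) -> None:
    np.savetxt(path, np.asarray(weights, dtype=float), fmt=FLOAT_FMT)


def write_scan_trace(path, trace) -> None:
    """Trace rows: (sigma, kish, {data_type: rmse})."""
    if not trace:
        pd.DataFrame(columns=["sigma", "kish"]).to_csv(path, sep="\t", index=False)
        return
    types = sorted(trace[0][2])
    rows = [
        {"sigma": s, "kish": k, **{f"rmse_{t}": r[t] for t in types}}
        for s, k, r in sorted(trace)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_scan_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_overlap_matrix(path, S, labels) -> None:
    pd.DataFrame(np.asarray(S), index=labels, columns=labels).to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


def read_embedding_table(path):
    """Table with columns frame, x1, x2[, label] -> (points, labels or None)."""
    from .forward import _read_table

    df = _read_table(path)
    for col in ("frame", "x1", "x2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("frame")
    pts = df[["x1", "x2"]].to_numpy(dtype=float)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return pts, labels


def write_calibration_report(path, result: CalibrationResult) -> None:
    """Human-readable structured text report of a calibration run."""
    lines = [
        "# calibration report",
        f"kish_target\t{result.kish_target:.4g}",
        f"final_kish\t{result.final.kish:.4g}",
        f"effective_size\t{result.final.kish * result.final.weights.size:.4g}",
        f"sigma_reg_global\t{result.sigma_reg_global:.4g}",
        f"converged\t{result.final.lambda_state.converged}",
        "",
        "# per-type sigma_reg",
    ]
    for t, s in result.per_type_sigma_reg.items():
        lines.append(f"{t}\t{s:.4g}")
    lines += ["", "# per-type rmse (final)"]
    for t, r in result.final.per_block_rmse.items():
        lines.append(f"{t}\t{r:.4g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> dict:
    """Flat key-value configuration (YAML-compatible subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def write_provenance(path, config: dict, inputs: dict[str, str] | None = None) -> None:
    """Record config, seeds, library versions and input digests for auditability."""
    import hashlib

    import scipy
    import sklearn

    record = {
        "config": config,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "inputs": {},
    }
    for name, p in (inputs or {}).items():
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        record["inputs"][name] = {"path": str(p), "sha256": digest}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
    log.info("provenance written to %s", path)
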