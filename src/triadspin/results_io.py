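"""Result serialization: long-format CSV, JSON with provenance, optional HDF5."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .yields import RateMap, YieldResult

__all__ = ["results_frame", "write_results", "map_frame"]

_COLUMNS = [
    "B_uT",
    "kX_us",
    "kSigma_us",
    "phiX",
    "Y",
    "chi",
    "effect_pct",
    "orientation_policy",
]


def _provenance(config_raw: dict | None) -> dict:
    blob = json.dumps(config_raw or {}, sort_keys=True).encode()
    return {
        "package": "triadspin",
        "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def results_frame(results: Sequence[YieldResult]) -> pd.DataFrame:
    """Long-format table of yield results (one row per evaluation)."""
    rows = [
        {
            "B_uT": r.magnitude_ut,
            "kX_us": r.k_X,
            "kSigma_us": r.k_sigma,
            "phiX": r.phi_X,
            "Y": r.Y,
            "chi": r.chi,
            "effect_pct": r.effect_pct,
            "orientation_policy": r.orientation_policy,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def map_frame(rate_map: RateMap) -> pd.DataFrame:
    """Long-format table of a rate map (one row per grid point)."""
    rows = []
    for i, kx in enumerate(rate_map.k_x_values):
        for j, ks in enumerate(rate_map.k_sigma_values):
            chi = rate_map.chi[i, j]
            rows.append(
                {
                    "B_uT": rate_map.field_ut,
                    "kX_us": float(kx),
                    "kSigma_us": float(ks),
                    "phiX": float(rate_map.phi_x[i, j]),
                    "Y": float(rate_map.phi_x[i, j]),
                    "chi": float(chi),
                    "effect_pct": float(100.0 * (chi - 1.0)),
                    "orientation_policy": rate_map.orientation_policy,
                }
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_results(
    frame: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    config_raw: dict | None = None,
) -> Path:
    """Write a results table as CSV, JSON (with provenance header) or HDF5.

    CSV keeps full floating precision; rounding happens only at
    presentation.  Raises on empty input rather than writing a bare header.
    """
    if frame.empty:
        raise ValueError("refusing to write empty results")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config_raw)
    if fmt == "csv":
        with open(path, "w") as fh:
            for key, val in prov.items():
                fh.write(f"# {key}: {val}\n")
            frame.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {"provenance": prov, "results": frame.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as h5:
            for key, val in prov.items():
                h5.attrs[key] = val
            for col in frame.columns:
                data = frame[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                h5.create_dataset(col, data=data)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
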