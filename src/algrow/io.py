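"""Campaign readers/writers binding the pipeline stages together.

On disk, a campaign is a directory with one on-line CSV per experiment
(``time_d, od_nir_au, temp_c, ph``), a companion off-line CSV
(``time_d, c_x_gpl, replicate``) and a YAML manifest listing the
experiment files with their cycle times and metadata.  All files are
comma-separated UTF-8 with '.' decimals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataprep import ExperimentTimeSeries

__all__ = ["read_campaign", "write_campaign", "export_trajectory"]

_ONLINE_COLS = ["time_d", "od_nir_au", "temp_c", "ph"]
_OFFLINE_COLS = ["time_d", "c_x_gpl", "replicate"]


def _read_csv(path: Path, required: list) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"campaign file missing: {path}")
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_campaign(manifest_path) -> list:
    """Load and validate a campaign from its YAML manifest.

    Raises with the offending file (and first offending line for
    non-monotone time axes) on malformed input.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    experiments = []
    for entry in manifest["experiments"]:
        online = _read_csv(base / entry["online"], _ONLINE_COLS)
        offline = _read_csv(base / entry["offline"], _OFFLINE_COLS)
        t = online["time_d"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"{base / entry['online']}: non-monotone time at line "
                f"{bad[0] + 3}"  # +1 header, +1 1-based, +1 second row of pair
            )
        experiments.append(
            ExperimentTimeSeries(
                experiment_id=str(entry["id"]),
                times=t,
                od_nir=online["od_nir_au"].to_numpy(dtype=float),
                temperature=online["temp_c"].to_numpy(dtype=float),
                ph=online["ph"].to_numpy(dtype=float),
                offline_samples=offline,
                t_cyc=float(entry["t_cyc_d"]),
                c_X0=entry.get("c_x0_gpl"),
                meta=entry.get("meta", {}),
            )
        )
    return experiments


def write_campaign(experiments: list, directory) -> Path:
    """Write a campaign directory (per-experiment CSVs + manifest).

    Returns the manifest path; the layout round-trips through
    :func:`read_campaign`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for e in experiments:
        online_name = f"experiment_{e.experiment_id}_online.csv"
        offline_name = f"experiment_{e.experiment_id}_offline.csv"
        pd.DataFrame(
            {
                "time_d": e.times,
                "od_nir_au": e.od_nir,
                "temp_c": e.temperature,
                "ph": e.ph,
            }
        ).to_csv(directory / online_name, index=False)
        e.offline_samples[_OFFLINE_COLS].to_csv(directory / offline_name, index=False)
        entry = {
            "id": e.experiment_id,
            "online": online_name,
            "offline": offline_name,
            "t_cyc_d": float(e.t_cyc),
        }
        if e.c_X0 is not None:
            entry["c_x0_gpl"] = float(e.c_X0)
        if e.meta:
            entry["meta"] = {k: float(v) for k, v in e.meta.items()}
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"experiments": entries}, fh, sort_keys=False)
    return manifest


def export_trajectory(result, path) -> None:
    """Write a simulated trajectory as CSV (time_d, c_X_gpl, q_ph, mu, T_C)."""
    result.to_frame().to_csv(path, index=False)
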