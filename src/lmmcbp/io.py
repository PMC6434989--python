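"""File formats: HDF5 containers, long-format CSV export, config files.

The epoch container travels either as a single HDF5 file (amplitudes plus
axis metadata, covariates as typed columns) or as the long-format
delimited text used for interoperability: one row per (trial, electrode,
time sample) carrying the amplitude and the full covariate vector,
trial-major / electrode-minor / time-innermost, so the round trip is
lossless and deterministic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, check_alignment
from .fit import TermStatMap

_STR = h5py.string_dtype(encoding="utf-8")


# ---------------------------------------------------------------------------
# HDF5 containers


def save_epochs(path, epochs: EpochSet, table: pd.DataFrame | None = None) -> None:
    """Write an EpochSet (and optionally its covariate table) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=epochs.amplitudes)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("electrodes", data=np.array(epochs.electrodes, dtype=_STR))
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids, dtype=np.int64))
        if table is not None:
            check_alignment(epochs, table)
            grp = f.create_group("covariates")
            for col in table.columns:
                vals = table[col].to_numpy()
                if vals.dtype.kind in ("O", "U"):
                    grp.create_dataset(col, data=vals.astype(str).astype(_STR))
                else:
                    grp.create_dataset(col, data=vals)


def load_epochs(path) -> tuple[EpochSet, pd.DataFrame | None]:
    with h5py.File(path, "r") as f:
        epochs = EpochSet(
            amplitudes=f["amplitudes"][()],
            times=f["times"][()],
            electrodes=[s.decode() if isinstance(s, bytes) else s for s in f["electrodes"][()]],
            trial_ids=f["trial_ids"][()],
        )
        table = None
        if "covariates" in f:
            data = {}
            for col in f["covariates"]:
                vals = f["covariates"][col][()]
                if vals.dtype.kind in ("S", "O"):
                    vals = np.array([v.decode() for v in vals])
                data[col] = vals
            table = pd.DataFrame(data)
            # restore stable column order: trial_id first if present
            if "trial_id" in table.columns:
                cols = ["trial_id"] + [c for c in table.columns if c != "trial_id"]
                table = table[cols]
    return epochs, table


def save_stats(path, stats: TermStatMap, provenance: dict | None = None) -> None:
    """Write a fitted TermStatMap (per-term matrices + axis metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("terms", data=np.array(stats.terms, dtype=_STR))
        f.create_dataset("estimates", data=stats.estimates)
        f.create_dataset("se", data=stats.se)
        f.create_dataset("t", data=stats.t)
        f.create_dataset("status", data=stats.status)
        f.create_dataset("electrodes", data=np.array(stats.electrodes, dtype=_STR))
        f.create_dataset("times", data=stats.times)
        if stats.sigma2 is not None:
            f.create_dataset("sigma2", data=stats.sigma2)
        for name, arr in stats.variance_components.items():
            f.create_dataset(f"vc/{name}", data=arr)
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def load_stats(path) -> TermStatMap:
    with h5py.File(path, "r") as f:
        vc = {}
        if "vc" in f:
            for name in f["vc"]:
                vc[name] = f["vc"][name][()]
        return TermStatMap(
            terms=[s.decode() if isinstance(s, bytes) else s for s in f["terms"][()]],
            estimates=f["estimates"][()],
            se=f["se"][()],
            t=f["t"][()],
            status=f["status"][()],
            electrodes=[s.decode() if isinstance(s, bytes) else s for s in f["electrodes"][()]],
            times=f["times"][()],
            sigma2=f["sigma2"][()] if "sigma2" in f else None,
            variance_components=vc,
        )


# ---------------------------------------------------------------------------
# long-format delimited text


def export_long(
    epochs: EpochSet,
    table: pd.DataFrame,
    path,
    per_time_sample: bool = False,
) -> list[Path]:
    """Export to long-format CSV (one row per trial × electrode × time).

    The default is a single combined file with a ``time_ms`` column;
    ``per_time_sample=True`` writes one file per time sample instead
    (suffix ``_t<index>``), each with trials × electrodes rows.  Row order
    is trial-major, electrode-minor, time-innermost; amplitudes keep full
    precision (hexadecimal-free ``repr`` via float formatting ``%.17g``).
    """
    check_alignment(epochs, table)
    path = Path(path)
    n_tr, n_el, n_ti = epochs.amplitudes.shape

    def frame_for(t_indices) -> pd.DataFrame:
        k = len(t_indices)
        rows = {
            "trial_id": np.repeat(epochs.trial_ids, n_el * k),
            "electrode": np.tile(np.repeat(epochs.electrodes, k), n_tr),
            "time_ms": np.tile(epochs.times[t_indices], n_tr * n_el),
            "amplitude_uv": epochs.amplitudes[:, :, t_indices].reshape(-1),
        }
        df = pd.DataFrame(rows)
        merged = df.merge(table, on="trial_id", how="left", suffixes=("", "_cov"))
        return merged

    written = []
    if per_time_sample:
        for ti in range(n_ti):
            p = path.with_name(f"{path.stem}_t{ti:03d}{path.suffix or '.csv'}")
            frame_for([ti]).to_csv(p, index=False, float_format="%.17g")
            written.append(p)
    else:
        frame_for(list(range(n_ti))).to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    return written


def import_long(path) -> tuple[EpochSet, pd.DataFrame]:
    """Read the combined long-format CSV back into aligned containers."""
    try:
        # round_trip parsing: %.17g-formatted doubles come back bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed long-format file {path}: {err}") from err
    needed = ["trial_id", "electrode", "time_ms", "amplitude_uv"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"long-format file missing columns: {missing}")
    trial_ids = df["trial_id"].drop_duplicates().to_numpy()
    electrodes = df["electrode"].drop_duplicates().tolist()
    times = np.sort(df["time_ms"].unique())
    n_tr, n_el, n_ti = len(trial_ids), len(electrodes), len(times)
    if len(df) != n_tr * n_el * n_ti:
        raise ValueError(
            f"ragged long-format file: {len(df)} rows != "
            f"{n_tr} trials x {n_el} electrodes x {n_ti} times"
        )
    amps = df["amplitude_uv"].to_numpy().reshape(n_tr, n_el, n_ti)
    cov_cols = [c for c in df.columns if c not in ("electrode", "time_ms", "amplitude_uv")]
    table = df.iloc[:: n_el * n_ti][cov_cols].reset_index(drop=True)
    epochs = EpochSet(
        amplitudes=amps, times=times, electrodes=electrodes, trial_ids=trial_ids
    )
    return epochs, table


def save_covariates(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# config and provenance


DEFAULT_CONFIG = {
    "formula": "amplitude ~ frequency + predictability:sentence_type "
    "+ position:sentence_type + (1|subject_id) + (1|word_form)",
    "baseline_window_ms": [-100.0, 0.0],
    "n400_window_ms": [300.0, 450.0],
    "roi_electrodes": None,
    "t_th": 2.0,
    "n_permutations": 500,
    "alpha": 0.05,
    "scheme": "both",
    "seed": 0,
    "n_jobs": 1,
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return {**DEFAULT_CONFIG, **user}


def save_config(path, config: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def provenance_block(config: dict, inputs: list | None = None) -> dict:
    import lmmcbp

    return {
        "package_version": lmmcbp.__version__,
        "config": config,
        "input_digests": {str(p): file_digest(p) for p in (inputs or [])},
    }
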