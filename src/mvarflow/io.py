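"""Readers and writers for the package's data objects.

Three input routes are supported:

* the package **container** — a zip archive of ``.npy`` payloads plus a
  ``meta.json`` sidecar describing shape, sampling rate, time axis and
  labels.  Archive entries carry a fixed timestamp so identical objects
  serialize to identical bytes (reruns are byte-reproducible);
* **delimited text** — one file per trial, channels as columns, a header row
  of channel labels;
* **EDF/EDF+** recordings (read through MNE), epoched on import given event
  latencies.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import EpochedTimeSeries
from .exceptions import InvalidArgumentError
from .measures import ConnectivityResult
from .var import VARModel

__all__ = [
    "save_container",
    "load_container",
    "read_delimited",
    "write_delimited",
    "read_edf",
    "connectivity_to_frame",
    "frame_to_connectivity",
]

_EPOCH_STAMP = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp => deterministic bytes


def _zip_write(zf: zipfile.ZipFile, name: str, payload: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_EPOCH_STAMP)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, payload)


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr))
    return buf.getvalue()


def save_container(obj, path: str | Path) -> None:
    """Serialize an EpochedTimeSeries, VARModel (or list of them), or
    ConnectivityResult to the package container format."""
    path = Path(path)
    with zipfile.ZipFile(path, "w") as zf:
        if isinstance(obj, EpochedTimeSeries):
            meta = {
                "kind": "timeseries",
                "srate": obj.srate,
                "channel_labels": obj.channel_labels,
                "condition": obj.condition,
                "shape": list(obj.data.shape),
            }
            _zip_write(zf, "meta.json", json.dumps(meta, indent=2).encode())
            _zip_write(zf, "data.npy", _npy_bytes(obj.data))
            _zip_write(zf, "times.npy", _npy_bytes(obj.times))
        elif isinstance(obj, VARModel) or (
            isinstance(obj, list) and all(isinstance(o, VARModel) for o in obj)
        ):
            models = [obj] if isinstance(obj, VARModel) else obj
            meta = {
                "kind": "varmodels",
                "orders": [m.order for m in models],
                "srate": models[0].srate if models else None,
                "n_obs": [m.n_obs for m in models],
                "window_centers": [m.window_center for m in models],
            }
            _zip_write(zf, "meta.json", json.dumps(meta, indent=2).encode())
            for i, m in enumerate(models):
                _zip_write(zf, f"coeffs_{i}.npy", _npy_bytes(m.coeffs))
                _zip_write(zf, f"noise_cov_{i}.npy", _npy_bytes(m.noise_cov))
                if m.regressor_cov is not None:
                    _zip_write(zf, f"regressor_cov_{i}.npy", _npy_bytes(m.regressor_cov))
        elif isinstance(obj, ConnectivityResult):
            meta = {"kind": "connectivity", "measure": obj.measure}
            _zip_write(zf, "meta.json", json.dumps(meta, indent=2).encode())
            _zip_write(zf, "values.npy", _npy_bytes(obj.values))
            _zip_write(zf, "freqs.npy", _npy_bytes(obj.freqs))
            _zip_write(zf, "window_centers.npy", _npy_bytes(obj.window_centers))
            _zip_write(zf, "model_orders.npy", _npy_bytes(obj.model_orders))
        else:
            raise InvalidArgumentError(
                f"cannot serialize object of type {type(obj).__name__}"
            )


def _load_npy(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    with zf.open(name) as fh:
        return np.load(_io.BytesIO(fh.read()))


def load_container(path: str | Path):
    """Load whatever object a container file holds."""
    path = Path(path)
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json").decode())
        kind = meta["kind"]
        if kind == "timeseries":
            return EpochedTimeSeries(
                data=_load_npy(zf, "data.npy"),
                srate=meta["srate"],
                times=_load_npy(zf, "times.npy"),
                channel_labels=meta["channel_labels"],
                condition=meta.get("condition"),
            )
        if kind == "varmodels":
            models = []
            names = set(zf.namelist())
            for i, order in enumerate(meta["orders"]):
                rc_name = f"regressor_cov_{i}.npy"
                models.append(VARModel(
                    order=order,
                    coeffs=_load_npy(zf, f"coeffs_{i}.npy"),
                    noise_cov=_load_npy(zf, f"noise_cov_{i}.npy"),
                    srate=meta["srate"],
                    n_obs=meta["n_obs"][i],
                    regressor_cov=_load_npy(zf, rc_name) if rc_name in names else None,
                    window_center=meta["window_centers"][i],
                ))
            return models if len(models) != 1 else models[0]
        if kind == "connectivity":
            return ConnectivityResult(
                measure=meta["measure"],
                values=_load_npy(zf, "values.npy"),
                freqs=_load_npy(zf, "freqs.npy"),
                window_centers=_load_npy(zf, "window_centers.npy"),
                model_orders=_load_npy(zf, "model_orders.npy"),
            )
        raise InvalidArgumentError(f"unknown container kind {kind!r}")


def read_delimited(
    paths: list[str | Path],
    srate: float,
    t0: float = 0.0,
    sep: str = "\t",
    condition: str | None = None,
) -> EpochedTimeSeries:
    """Read one delimited-text file per trial (channels as columns).

    The header row supplies channel labels; all trials must agree on shape
    and labels.
    """
    if not paths:
        raise InvalidArgumentError("no input files given")
    frames = [pd.read_csv(p, sep=sep) for p in paths]
    labels = list(frames[0].columns)
    for p, f in zip(paths, frames):
        if list(f.columns) != labels or f.shape != frames[0].shape:
            raise InvalidArgumentError(f"trial file {p} does not match the first trial")
    data = np.stack([f.to_numpy(dtype=float).T for f in frames], axis=2)
    n = data.shape[1]
    times = t0 + np.arange(n) / srate
    return EpochedTimeSeries(data=data, srate=srate, times=times,
                             channel_labels=labels, condition=condition)


def write_delimited(ts: EpochedTimeSeries, directory: str | Path,
                    sep: str = "\t", stem: str = "trial") -> list[Path]:
    """Write one delimited-text file per trial; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for tr in range(ts.n_trials):
        frame = pd.DataFrame(ts.data[:, :, tr].T, columns=ts.channel_labels)
        p = directory / f"{stem}_{tr:04d}.tsv"
        frame.to_csv(p, sep=sep, index=False, float_format="%.17g")
        out.append(p)
    return out


def read_edf(
    path: str | Path,
    event_latencies_s: list[float] | None = None,
    epoch_window_s: tuple[float, float] = (-0.5, 1.0),
    channels: list[str] | None = None,
) -> EpochedTimeSeries:
    """Read an EDF/EDF+ recording and epoch it around event latencies.

    Without ``event_latencies_s`` the whole recording becomes a single
    "trial" with the time axis starting at 0.  With latencies, a window
    ``epoch_window_s`` (seconds, relative to each event) is cut around each
    one; events whose window does not fit are dropped.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    data = raw.get_data()  # (n_channels, n_samples)
    srate = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    if event_latencies_s is None:
        n = data.shape[1]
        return EpochedTimeSeries(
            data=data[:, :, None], srate=srate,
            times=np.arange(n) / srate, channel_labels=labels,
        )
    lo, hi = epoch_window_s
    if hi <= lo:
        raise InvalidArgumentError("epoch window must have positive length")
    n_lo = int(round(lo * srate))
    n_hi = int(round(hi * srate))
    win = n_hi - n_lo
    trials = []
    for lat in event_latencies_s:
        s = int(round(lat * srate)) + n_lo
        if s < 0 or s + win > data.shape[1]:
            continue
        trials.append(data[:, s:s + win])
    if not trials:
        raise InvalidArgumentError("no event window fits inside the recording")
    times = (n_lo + np.arange(win)) / srate
    return EpochedTimeSeries(
        data=np.stack(trials, axis=2), srate=srate, times=times,
        channel_labels=labels,
    )


def connectivity_to_frame(cr: ConnectivityResult) -> pd.DataFrame:
    """Long-format table: window_center, freq, sink, source, measure, value."""
    m, _, nf, nw = cr.values.shape
    sink, source, fi, wi = np.meshgrid(
        np.arange(m), np.arange(m), np.arange(nf), np.arange(nw), indexing="ij"
    )
    return pd.DataFrame({
        "window_center": cr.window_centers[wi.ravel()],
        "freq": cr.freqs[fi.ravel()],
        "sink": sink.ravel(),
        "source": source.ravel(),
        "measure": cr.measure,
        "value": cr.values.ravel(),
    })


def frame_to_connectivity(frame: pd.DataFrame) -> ConnectivityResult:
    """Rebuild a ConnectivityResult from the long-format table."""
    freqs = np.sort(frame["freq"].unique())
    centers = np.sort(frame["window_center"].unique())
    m = int(frame["sink"].max()) + 1
    values = np.full((m, m, freqs.size, centers.size), np.nan)
    fi = np.searchsorted(freqs, frame["freq"].to_numpy())
    wi = np.searchsorted(centers, frame["window_center"].to_numpy())
    values[frame["sink"].to_numpy(), frame["source"].to_numpy(), fi, wi] = \
        frame["value"].to_numpy()
    return ConnectivityResult(
        measure=str(frame["measure"].iloc[0]), values=values, freqs=freqs,
        window_centers=centers, model_orders=np.full(centers.size, -1),
    )
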