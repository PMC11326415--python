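"""NetCDF reading/writing with deterministic on-disk bytes.

Writes go through the NETCDF3_64BIT format: it is plain and byte-stable, so
re-running a pipeline with the same configuration and seed reproduces files
bit for bit (which the pipeline's content-hash cache relies on).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import xarray as xr


def write_dataset(ds: xr.Dataset, path: str | Path) -> Path:
    """Write ``ds`` to ``path`` as NETCDF3_64BIT (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    encoding = {}
    for name in ds.coords:
        if ds[name].dtype.kind == "M":  # datetimes: fixed epoch, no dtype guessing
            encoding[name] = {
                "units": "seconds since 1970-01-01T00:00:00",
                "dtype": "int64",
            }
    ds.to_netcdf(path, format="NETCDF3_64BIT", engine="scipy", encoding=encoding)
    return path


def read_dataset(path: str | Path) -> xr.Dataset:
    """Open a dataset and load it fully into memory (file handle released)."""
    with xr.open_dataset(path) as ds:
        return ds.load()


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
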