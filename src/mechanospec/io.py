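"""HDF5 phantom container and CSV interchange.

The map container mirrors the data model: /brillouin/raw holds the per-point
CCD spectra, /raman/raw the co-localized Raman spectra (line maps only), and
/truth the generator ground truth.  CSV files are the report format; every
table is written with provenance header lines (version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .brillouin import BrillouinRawSpectrum
from .raman import RamanSpectrum
from .synthetic import PhantomConfig, SpectralMap, spheroid_profiles

__all__ = ["write_phantom", "read_phantom", "write_table", "config_hash",
           "truth_frame"]


_PATH_KEYS = {"out_dir", "input_path"}


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping.

    Input/output paths are excluded so the hash identifies the analysis,
    not where its results were written.
    """
    if hasattr(config, "__dict__"):
        config = {k: v for k, v in vars(config).items()
                  if isinstance(v, (int, float, str, bool, tuple, list))
                  and k not in _PATH_KEYS}
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def truth_frame(smap: SpectralMap) -> pd.DataFrame:
    """Ground-truth table: one row per point."""
    return pd.DataFrame({
        "point": np.arange(smap.n_points),
        "x_um": smap.x_um, "y_um": smap.y_um,
        "class": smap.labels,
        "nu_B_true": smap.nu_B_true,
        "gamma_B_true": smap.gamma_B_true,
    })


def write_phantom(smap: SpectralMap, path) -> None:
    """Write a SpectralMap to an HDF5 container."""
    cfg = smap.config
    with h5py.File(path, "w") as f:
        f.attrs["mechanospec_version"] = _version
        f.attrs["config_yaml"] = yaml.safe_dump(_config_dict(cfg))
        gb = f.create_group("brillouin")
        gb.create_dataset("raw", data=np.vstack(
            [s.intensity for s in smap.brillouin]))
        gb.create_dataset("reference_pixels", data=np.array(
            [s.metadata["reference_pixels"] for s in smap.brillouin]))
        gb.create_dataset("sample_pixels", data=np.array(
            [s.metadata["sample_pixels"] for s in smap.brillouin]))
        gb.attrs["rayleigh_fwhm"] = cfg.rayleigh_fwhm
        if smap.raman is not None:
            gr = f.create_group("raman")
            gr.create_dataset("raw", data=np.vstack(
                [s.intensity for s in smap.raman]))
            gr.create_dataset("wavenumber", data=smap.raman[0].wavenumber)
        gt = f.create_group("truth")
        gt.create_dataset("x_um", data=smap.x_um)
        gt.create_dataset("y_um", data=smap.y_um)
        gt.create_dataset("class", data=np.array(smap.labels, dtype="S"))
        gt.create_dataset("nu_B_true", data=smap.nu_B_true)
        gt.create_dataset("gamma_B_true", data=smap.gamma_B_true)


def _config_dict(cfg: PhantomConfig) -> dict:
    return {k: v for k, v in vars(cfg).items()
            if isinstance(v, (int, float, str, bool, tuple, list))}


def read_phantom(path) -> SpectralMap:
    """Read a phantom container back into a SpectralMap.

    The stored configuration is restored for scalar fields; class profiles
    fall back to the default registry (they are not needed to re-analyse an
    existing map).
    """
    with h5py.File(path, "r") as f:
        cfg_raw = yaml.safe_load(f.attrs["config_yaml"])
        cfg_kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in cfg_raw.items()}
        cfg = PhantomConfig(class_profiles=spheroid_profiles(), **{
            k: v for k, v in cfg_kwargs.items()
            if k in PhantomConfig.__dataclass_fields__
            and k != "class_profiles"})
        raw = f["brillouin/raw"][...]
        refs = f["brillouin/reference_pixels"][...]
        samps = f["brillouin/sample_pixels"][...]
        rayleigh = float(f["brillouin"].attrs["rayleigh_fwhm"])
        x_um = f["truth/x_um"][...]
        y_um = f["truth/y_um"][...]
        labels = [s.decode() for s in f["truth/class"][...]]
        nu_true = f["truth/nu_B_true"][...]
        ga_true = f["truth/gamma_B_true"][...]
        raman = None
        if "raman" in f:
            wn = f["raman/wavenumber"][...]
            raman = [RamanSpectrum(wn, row, state="raw", label=lab)
                     for row, lab in zip(f["raman/raw"][...], labels)]
    pixel = np.arange(raw.shape[1], dtype=float)
    brillouin = [
        BrillouinRawSpectrum(pixel, row, metadata={
            "reference_pixels": tuple(refs[i]),
            "sample_pixels": tuple(samps[i]),
            "rayleigh_fwhm": rayleigh,
            "position_um": (float(x_um[i]), float(y_um[i])),
        }) for i, row in enumerate(raw)]
    return SpectralMap(config=cfg, x_um=x_um, y_um=y_um, labels=labels,
                       nu_B_true=nu_true, gamma_B_true=ga_true,
                       brillouin=brillouin, raman=raman)


def write_table(df: pd.DataFrame, path, seed=None, config=None,
                index: bool = False) -> None:
    """Write a CSV report table with provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# mechanospec {_version}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=index)
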