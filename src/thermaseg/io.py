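"""Reading and writing thermograms, sidecars, masks and temperature matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .core import RadiometricMeta, ThermalMatrix, Thermogram

_SIDECAR_KEYS = ("t_min_c", "t_max_c", "emissivity", "distance_m", "ifov_mrad")


def load_sidecar(path: str | Path) -> RadiometricMeta:
    """Radiometric sidecar: flat YAML with t_min_c, t_max_c, emissivity, ..."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"sidecar {path} is not a key/value mapping")
    missing = [k for k in ("t_min_c", "t_max_c") if k not in data]
    if missing:
        raise ValueError(f"sidecar {path} missing keys: {missing}")
    kwargs = {k: float(data[k]) for k in _SIDECAR_KEYS if k in data}
    return RadiometricMeta(**kwargs)


def save_sidecar(meta: RadiometricMeta, path: str | Path) -> None:
    data = {
        "t_min_c": float(meta.t_min_c),
        "t_max_c": float(meta.t_max_c),
        "emissivity": float(meta.emissivity),
        "distance_m": float(meta.distance_m),
        "ifov_mrad": float(meta.ifov_mrad),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_thermogram(image_path: str | Path, sidecar_path: str | Path) -> Thermogram:
    """8-bit grayscale image + YAML sidecar; other depths are normalized to 8-bit."""
    img = Image.open(image_path).convert("L")
    pixels = np.asarray(img, dtype=np.uint8).astype(int)
    return Thermogram(pixels=pixels, meta=load_sidecar(sidecar_path))


def save_gray_png(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(path)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    save_gray_png(np.where(np.asarray(mask, bool), 255, 0), path)


def load_thermal_csv(path: str | Path, meta: RadiometricMeta) -> ThermalMatrix:
    """Temperature matrix CSV: comma-separated °C values, row-major, no header."""
    temps = np.loadtxt(path, delimiter=",", ndmin=2)
    return ThermalMatrix(temps=temps, meta=meta)


def save_thermal_csv(thermal: ThermalMatrix, path: str | Path) -> None:
    np.savetxt(path, thermal.temps, delimiter=",", fmt="%.4f")
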