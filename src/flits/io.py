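"""File I/O: multi-page TIFF stacks with JSON sidecars, float map images,
CSV tables and JSON parameter files.

Phase stacks are written as multi-page 32-bit float TIFF with the frame
order equal to the phase-step index (ascending), plus a ``.json`` sidecar
holding the instrument configuration.  Derived maps (G, S, lifetimes,
intensity, concentration) are single-page 32-bit float TIFF; masks are
8-bit TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .instrument import InstrumentConfig
from .phasor import LifetimeImage, PhaseStack, PhasorImage

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "write_mask",
    "read_mask",
    "write_phasor_image",
    "write_lifetime_image",
    "write_json",
    "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: PhaseStack) -> None:
    """Write a phase stack as multi-page float32 TIFF + config sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    with open(_sidecar(path), "w") as fh:
        json.dump(dataclasses.asdict(stack.config), fh, indent=2)


def read_stack(path, config: InstrumentConfig | None = None) -> PhaseStack:
    """Read a phase stack; the config comes from the sidecar unless given."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if config is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no instrument config: pass one explicitly or provide {sidecar}"
            )
        with open(sidecar) as fh:
            config = InstrumentConfig(**json.load(fh))
    return PhaseStack(frames=frames, config=config)


def write_map(path, image: np.ndarray) -> None:
    """Write a float image map as single-page float32 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))) > 0


def write_phasor_image(prefix, ph: PhasorImage) -> None:
    """Write G, S, intensity maps and the valid mask under a path prefix."""
    prefix = Path(prefix)
    write_map(prefix.with_name(prefix.name + "_g.tif"), ph.g)
    write_map(prefix.with_name(prefix.name + "_s.tif"), ph.s)
    write_map(prefix.with_name(prefix.name + "_intensity.tif"), ph.intensity)
    write_mask(prefix.with_name(prefix.name + "_valid.tif"), ph.valid_mask)


def write_lifetime_image(prefix, lt: LifetimeImage) -> None:
    """Write tau_phi, tau_mod, intensity maps and the valid mask."""
    prefix = Path(prefix)
    write_map(prefix.with_name(prefix.name + "_tau_phi.tif"), lt.tau_phi)
    write_map(prefix.with_name(prefix.name + "_tau_mod.tif"), lt.tau_mod)
    write_map(prefix.with_name(prefix.name + "_intensity.tif"), lt.intensity)
    write_mask(prefix.with_name(prefix.name + "_valid.tif"), lt.valid_mask)


def write_json(path, obj: dict) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2)


def read_json(path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
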