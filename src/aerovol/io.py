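"""Reading and writing of hologram stacks and reconstruction caches.

Hologram stacks travel as multi-page grayscale TIFF (8 or 16 bit) with a
sidecar JSON metadata file; reconstructed stacks can be cached as HDF5 with
per-frame amplitude and phase datasets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np
import tifffile

from .holography import ComplexFrame, HologramStack

__all__ = [
    "write_hologram_stack",
    "read_hologram_stack",
    "write_reconstruction_cache",
    "read_reconstruction_cache",
]


def _sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_hologram_stack(stack: HologramStack, tiff_path) -> None:
    """Write frames as a multi-page TIFF plus a JSON metadata sidecar."""
    tifffile.imwrite(tiff_path, stack.frames, photometric="minisblack")
    meta = {
        "wavelength_um": stack.wavelength_um,
        "pixel_pitch_um": stack.pixel_pitch_um,
        "z_um": stack.z_um,
        "frame_rate_fps": stack.frame_rate_fps,
        "frame_count": len(stack),
        "bit_depth": stack.bit_depth,
    }
    with open(_sidecar_path(tiff_path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_hologram_stack(tiff_path) -> HologramStack:
    """Read a multi-page TIFF stack and its JSON sidecar."""
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    with open(_sidecar_path(tiff_path)) as fh:
        meta = json.load(fh)
    if meta["frame_count"] != len(frames):
        raise ValueError("sidecar frame_count disagrees with the TIFF")
    times = np.arange(len(frames)) / meta["frame_rate_fps"]
    return HologramStack(
        frames=frames,
        frame_times_s=times,
        wavelength_um=meta["wavelength_um"],
        pixel_pitch_um=meta["pixel_pitch_um"],
        z_um=meta["z_um"],
        frame_rate_fps=meta["frame_rate_fps"],
        bit_depth=meta["bit_depth"],
    )


def write_reconstruction_cache(frames: Sequence[ComplexFrame], h5_path) -> None:
    """Cache reconstructed frames as HDF5 amplitude/phase datasets."""
    with h5py.File(h5_path, "w") as fh:
        fh.attrs["n_frames"] = len(frames)
        for i, frame in enumerate(frames):
            grp = fh.create_group(f"frame_{i:04d}")
            grp.create_dataset("amplitude", data=frame.amplitude,
                               compression="gzip")
            grp.create_dataset("phase", data=frame.phase, compression="gzip")
            grp.attrs["z_um"] = frame.z_um


def read_reconstruction_cache(h5_path) -> List[ComplexFrame]:
    """Load reconstructed frames from an HDF5 cache."""
    frames: List[ComplexFrame] = []
    with h5py.File(h5_path, "r") as fh:
        for i in range(int(fh.attrs["n_frames"])):
            grp = fh[f"frame_{i:04d}"]
            field = np.asarray(grp["amplitude"]) * np.exp(
                1j * np.asarray(grp["phase"])
            )
            frames.append(ComplexFrame(field, float(grp.attrs["z_um"])))
    return frames
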