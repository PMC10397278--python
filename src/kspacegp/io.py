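"""Persistence of library stats, masks, cohorts and reports; NIfTI ingestion."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from PIL import Image
from skimage.transform import resize

from .phantoms import PhantomLibrary, PhantomSpec
from .rings import SamplingMask, ring_mask, ring_partition
from .stats import LibraryStats

__all__ = [
    "save_stats",
    "load_stats",
    "save_mask",
    "load_mask",
    "save_library",
    "load_library",
    "save_library_png",
    "read_nifti_axial_slices",
    "save_report",
]

FFT_CONVENTION = "unnormalized forward fft2 / 1/M^2 inverse, fftshifted (DC at N/2)"


# -- library stats (HDF5 + JSON sidecar) ---------------------------------


def save_stats(stats: LibraryStats, h5_path, json_path=None) -> None:
    h5_path = Path(h5_path)
    json_path = Path(json_path) if json_path else h5_path.with_suffix(h5_path.suffix + ".json")
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("mean_magnitude", data=stats.mean_magnitude)
        f.create_dataset("mu0_re", data=stats.mu0_re)
        f.create_dataset("mu0_im", data=stats.mu0_im)
        f.create_dataset("K_re", data=stats.K_re)
        f.create_dataset("K_im", data=stats.K_im)
    json_path.write_text(
        json.dumps(
            {"N": stats.N, "n1": stats.n1, "eps": stats.eps, "convention": FFT_CONVENTION}
        )
    )


def load_stats(h5_path, json_path=None) -> LibraryStats:
    h5_path = Path(h5_path)
    json_path = Path(json_path) if json_path else h5_path.with_suffix(h5_path.suffix + ".json")
    meta = json.loads(json_path.read_text())
    with h5py.File(h5_path, "r") as f:
        stats = LibraryStats(
            mean_magnitude=f["mean_magnitude"][()],
            mu0_re=f["mu0_re"][()],
            mu0_im=f["mu0_im"][()],
            K_re=f["K_re"][()],
            K_im=f["K_im"][()],
            n1=int(meta["n1"]),
            eps=float(meta["eps"]),
        )
    if stats.N != int(meta["N"]):
        raise ValueError("stats sidecar disagrees with datasets on N")
    return stats


# -- sampling masks (PNG + JSON) -----------------------------------------


def save_mask(mask: SamplingMask, png_path, json_path=None, budget=None, basis=None) -> None:
    png_path = Path(png_path)
    json_path = Path(json_path) if json_path else png_path.with_suffix(".json")
    Image.fromarray((mask.mask.astype(np.uint8) * 255), mode="L").save(png_path)
    json_path.write_text(
        json.dumps(
            {
                "N": mask.N,
                "radii": [int(r) for r in mask.radii],
                "fraction": mask.fraction,
                "budget": budget,
                "basis": basis,
            }
        )
    )


def load_mask(png_path, json_path=None) -> SamplingMask:
    """Load a mask and validate it equals the union of its listed rings."""
    png_path = Path(png_path)
    json_path = Path(json_path) if json_path else png_path.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    arr = (np.asarray(Image.open(png_path), dtype=np.uint8) > 127).astype(np.uint8)
    part = ring_partition(int(meta["N"]))
    rebuilt = ring_mask(part, meta["radii"]).mask.copy()
    if not np.array_equal(rebuilt, arr):
        # a full-sampling mask additionally covers the corner set
        rebuilt.ravel()[part.corner_set] = 1
        if not np.array_equal(rebuilt, arr):
            raise ValueError("mask PNG does not equal the union of its listed rings")
    return SamplingMask(mask=arr, radii=meta["radii"], fraction=float(meta["fraction"]))


# -- phantom cohorts ------------------------------------------------------


def save_library(lib: PhantomLibrary, h5_path, json_path=None) -> None:
    h5_path = Path(h5_path)
    json_path = Path(json_path) if json_path else h5_path.with_suffix(h5_path.suffix + ".json")
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("images", data=lib.images)
        for name, idx in lib.partitions.items():
            f.create_dataset(f"partition_{name}", data=idx)
    json_path.write_text(
        json.dumps(
            {
                "seed": lib.seed,
                "spec": asdict(lib.spec),
                "partitions": {k: [int(i) for i in v] for k, v in lib.partitions.items()},
            }
        )
    )


def load_library(h5_path, json_path=None) -> PhantomLibrary:
    h5_path = Path(h5_path)
    json_path = Path(json_path) if json_path else h5_path.with_suffix(h5_path.suffix + ".json")
    meta = json.loads(json_path.read_text())
    spec_dict = dict(meta["spec"])
    spec_dict["intensity_range"] = tuple(spec_dict["intensity_range"])
    if spec_dict.get("lesion") is not None:
        spec_dict["lesion"] = tuple(spec_dict["lesion"])
    with h5py.File(h5_path, "r") as f:
        images = f["images"][()]
        partitions = {
            name: f[f"partition_{name}"][()] for name in ("stats", "path", "test")
        }
    return PhantomLibrary(
        images=images,
        partitions=partitions,
        seed=int(meta["seed"]),
        spec=PhantomSpec(**spec_dict),
    )


def save_library_png(lib: PhantomLibrary, directory) -> None:
    """8-bit grayscale PNG per phantom plus a JSON manifest (lossy: 8-bit)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(lib.images):
        arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / f"phantom_{i:05d}.png")
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "seed": lib.seed,
                "spec": asdict(lib.spec),
                "partitions": {k: [int(i) for i in v] for k, v in lib.partitions.items()},
            }
        )
    )


# -- NIfTI ingestion ------------------------------------------------------


def read_nifti_axial_slices(
    path, slice_range=None, out_size: int = 256, inner_width: int = 200
) -> np.ndarray:
    """Axial slices from a NIfTI volume, prepared as model inputs.

    Each slice is resized to ``out_size x inner_width``, zero-padded left and
    right into an ``out_size x out_size`` square and max-normalized to [0, 1].
    ``slice_range`` is a ``(start, stop)`` pair of axial indices (half-open);
    ``None`` takes the whole volume.
    """
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D NIfTI volume")
    depth = vol.shape[2]
    if slice_range is None:
        slice_range = (0, depth)
    start, stop = int(slice_range[0]), int(slice_range[1])
    if not (0 <= start < stop <= depth):
        raise ValueError(f"slice_range {slice_range} outside volume depth {depth}")
    if inner_width > out_size:
        raise ValueError("inner_width cannot exceed out_size")
    pad_left = (out_size - inner_width) // 2
    pad_right = out_size - inner_width - pad_left
    out = []
    for z in range(start, stop):
        sl = vol[:, :, z]
        sl = np.clip(sl, 0.0, None)
        if sl.shape != (out_size, inner_width):
            sl = resize(sl, (out_size, inner_width), order=1, preserve_range=True,
                        anti_aliasing=True)
        sl = np.pad(sl, ((0, 0), (pad_left, pad_right)))
        top = sl.max()
        if top > 0:
            sl = sl / top
        out.append(sl)
    return np.stack(out)


# -- evaluation reports ----------------------------------------------------


def save_report(rows, csv_path, json_path=None) -> None:
    """Per-image metric rows as CSV plus a JSON summary of the means."""
    import pandas as pd

    csv_path = Path(csv_path)
    df = pd.DataFrame(rows)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {}
        for col in ("nmse", "ssim", "jitter_used"):
            if col in df:
                summary[f"mean_{col}"] = float(df[col].mean())
        summary["n_images"] = int(len(df))
        Path(json_path).write_text(json.dumps(summary, indent=2))
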