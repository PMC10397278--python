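"""End-to-end workflow: cohort -> prior -> path -> mask -> reconstruction report.

Stages follow the three-way data split: subset 1 ("stats") builds the library
prior, subset 2 ("path") drives ring-path optimization (and, optionally,
length-scale tuning), subset 3 ("test") is reconstructed through the
generalized mask and scored. Every stage persists its artifact and the run
log records seeds, timings and jitter events so a run can be replayed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as kio
from .estimators import KSpaceGP, RingPathOptimizer
from .kernels import tune_length_scale
from .kspace import to_kspace
from .phantoms import PhantomSpec, generate_library
from .rings import central_mask, full_mask, ring_partition

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (JSON-serializable)."""

    n0: int = 80
    crop: int = 64
    n_images: int = 60
    split: tuple = (50, 4, 6)
    budget: float = 0.125
    budget_basis: str = "crop"
    kernel: str = "double"
    length_scale: float | str | None = None  # number, None (default) or "tune"
    tune_candidates: tuple = ()
    tuning_set: str = "path"  # which subset supplies tuning images
    tune_n_images: int = 25
    seed: int = 0
    outdir: str = "kspacegp_run"
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    nifti_path: str | None = None
    slice_range: tuple | None = None

    def __post_init__(self):
        if not 0 < self.budget <= 1:
            raise ValueError("budget must lie in (0, 1]")
        if sum(self.split) != self.n_images:
            raise ValueError("split must sum to n_images")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        for key in ("split", "tune_candidates", "slice_range"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _load_images(config: RunConfig):
    if config.nifti_path:
        images = kio.read_nifti_axial_slices(
            config.nifti_path, config.slice_range, out_size=config.n0
        )
        n = images.shape[0]
        if sum(config.split) != n:
            raise ValueError("split does not match the number of NIfTI slices")
        n1, n2, n3 = config.split
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        parts = {
            "stats": np.sort(perm[:n1]),
            "path": np.sort(perm[n1 : n1 + n2]),
            "test": np.sort(perm[n1 + n2 :]),
        }
        return images, parts, None
    spec = PhantomSpec(grid_size_full=config.n0, **config.phantom)
    lib = generate_library(config.n_images, spec, config.seed, config.split)
    return lib.images, lib.partitions, lib


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also persisted)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog: dict = {"seed": config.seed, "stages": {}, "jitter_events": []}
    t0 = time.perf_counter()

    def mark(stage):
        runlog["stages"][stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done at %.2fs", stage, runlog["stages"][stage])

    try:
        images, parts, lib = _load_images(config)
        if lib is not None:
            kio.save_library(lib, outdir / "library.h5")
        mark("library")

        ls = None if config.length_scale == "tune" else config.length_scale
        gp = KSpaceGP(crop_size=config.crop, kernel=config.kernel, length_scale=ls)
        gp.fit(images[parts["stats"]])
        kio.save_stats(gp.stats_, outdir / "stats.h5")
        mark("stats")

        if config.length_scale == "tune":
            if not config.tune_candidates:
                raise ValueError("length_scale='tune' requires tune_candidates")
            part = ring_partition(gp.stats_.N)
            basis = part.basis(config.budget_basis, full_size=config.n0)
            provisional = central_mask(part, config.budget, basis)
            tune_idx = parts[config.tuning_set][: config.tune_n_images]
            kdata = [to_kspace(img, gp.stats_.N) for img in images[tune_idx]]
            chosen = tune_length_scale(
                gp.stats_, kdata, config.kernel, config.tune_candidates,
                provisional, pad_to=config.n0,
            )
            runlog["tuned_length_scale"] = chosen
            gp = KSpaceGP(
                crop_size=config.crop, kernel=config.kernel, length_scale=chosen
            ).fit(images[parts["stats"]])
            mark("tune")

        if config.budget >= 1.0:
            # full sampling: nothing to optimize
            mask = full_mask(ring_partition(gp.stats_.N))
        else:
            opt = RingPathOptimizer(
                gp, budget=config.budget, budget_basis=config.budget_basis
            )
            opt.fit(images[parts["path"]])
            mask = opt.mask_
        kio.save_mask(
            mask, outdir / "mask.png",
            budget=config.budget, basis=config.budget_basis,
        )
        runlog["mask_radii"] = [int(r) for r in mask.radii]
        runlog["mask_fraction_crop"] = mask.n_sampled / (gp.stats_.N ** 2)
        runlog["mask_fraction_full"] = mask.n_sampled / (config.n0 ** 2)
        mark("path")

        report_rows = []
        if len(parts["test"]) > 0:
            for i, img in zip(parts["test"], images[parts["test"]]):
                res = gp.reconstruct_image(img, mask, pad_to=config.n0)
                if res.jitter_used > 0:
                    runlog["jitter_events"].append(
                        {"image": int(i), "jitter": res.jitter_used}
                    )
                report_rows.append(
                    {
                        "image": int(i),
                        "budget": config.budget,
                        "kernel": config.kernel,
                        "nmse": res.nmse,
                        "ssim": res.ssim,
                        "jitter_used": res.jitter_used,
                    }
                )
            kio.save_report(report_rows, outdir / "report.csv", outdir / "summary.json")
            mark("evaluate")
        config.to_json(outdir / "config.json")
        (outdir / "runlog.json").write_text(json.dumps(runlog, indent=2))
    except Exception as exc:
        (outdir / "runlog.json").write_text(json.dumps(runlog, indent=2))
        stage = len(runlog["stages"])
        logger.error("pipeline aborted after stage %d: %s", stage, exc)
        raise
    summary = {
        "rows": report_rows,
        "mask_radii": runlog["mask_radii"],
        "mask_fraction_crop": runlog["mask_fraction_crop"],
        "runlog": runlog,
    }
    if report_rows:
        summary["mean_nmse"] = float(np.mean([r["nmse"] for r in report_rows]))
        summary["mean_ssim"] = float(np.mean([r["ssim"] for r in report_rows]))
    return summary
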