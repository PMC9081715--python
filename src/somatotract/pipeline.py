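"""End-to-end reproducible pipeline: phantom -> fit -> track -> somatotopy.

Every run writes its intermediates (NIfTI, .trk, CSV, JSON) plus a
machine-readable provenance manifest (config hash, seed, versions) so a run
can be reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DwiVolume
from .interpolation import InterpConfig
from .io import (
    dump_json,
    dump_yaml,
    load_yaml,
    write_dwi,
    write_mask,
    write_model_field,
    write_scalar_map,
    write_trk,
)
from .models import dec_map, fa, fit_ball_stick, fit_dti, md
from .phantom import (
    DEFAULT_BVALUES,
    DEFAULT_DIFFUSIVITY,
    DEFAULT_GRID_SHAPE,
    DEFAULT_S0,
    DEFAULT_VOXEL_SIZE,
    PhantomTruth,
    SUBDIVISIONS,
    make_default_geometry,
    make_default_scheme,
    rasterize_bundles,
    simulate_signal,
)
from .somatotopy import (
    ap_rank,
    centroid,
    dsc_table,
    envelope,
    envelope_stats,
    extract_fascicles,
    slice_mask,
    summarize_dsc,
)
from .tracking import Streamline, Tractogram, TrackingConfig, reconstruct_pathway

logger = logging.getLogger("somatotract")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Every knob of one pipeline run; the seed feeds all randomness."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE
    n_dirs: int = 90
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    n_b0: int = 6
    S0: float = DEFAULT_S0
    diffusivity: float = DEFAULT_DIFFUSIVITY
    snr: float = float("inf")
    fa_gate: float = 0.2
    max_sticks: int = 3
    interp: InterpConfig = field(default_factory=InterpConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    seed: int = 0
    out_dir: str = "somatotract_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["bvalues"] = list(self.bvalues)
        d["snr"] = "inf" if np.isinf(self.snr) else float(self.snr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "interp" in d and isinstance(d["interp"], dict):
            d["interp"] = InterpConfig(**d["interp"])
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingConfig(**d["tracking"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "bvalues" in d:
            d["bvalues"] = tuple(d["bvalues"])
        if d.get("snr") == "inf":
            d["snr"] = float("inf")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(load_yaml(path))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output location is not
        part of a run's identity)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def reduced(self) -> "PipelineConfig":
        """A single-shell, 32-direction variant for quick runs."""
        d = self.to_dict()
        d.update(n_dirs=32, bvalues=[1000.0], n_b0=2)
        return PipelineConfig.from_dict(d)


def _slice_levels(truth: PhantomTruth, params: dict) -> dict[str, int]:
    """Axial analysis levels: IC = slab mid-plane, ZI = one slice superior
    to the STN top, CR = the fan (corona-radiata) level."""
    ic_z = int(np.round(np.mean(np.argwhere(truth.roi_ic)[:, 2])))
    zi_z = int(np.argwhere(truth.roi_stn)[:, 2].max()) + 1
    voxel = float(params["voxel_size_mm"])
    cr_z = int(np.round(params["fan_level_z"] / voxel - 0.5))
    return {"IC": ic_z, "ZI": zi_z, "CR": cr_z}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute phantom -> fit -> track -> somatotopy, writing all outputs.

    Returns the summary dictionary that is also written to
    ``summary.json``.  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: phantom ------------------------------------------------------
    try:
        scheme = make_default_scheme(cfg.n_dirs, cfg.bvalues, cfg.n_b0, seed=cfg.seed)
        bundles, params = make_default_geometry(cfg.grid_shape, cfg.voxel_size_mm)
        truth = rasterize_bundles(bundles, params)
        dwi = simulate_signal(
            truth, scheme, S0=cfg.S0, d=cfg.diffusivity, snr=cfg.snr, seed=cfg.seed
        )
        write_dwi(dwi, out / "dwi.nii.gz", out / "dwi.bval", out / "dwi.bvec")
        write_mask(truth.roi_m1_labels, truth.affine, out / "m1_labels.nii.gz")
        write_mask(truth.roi_ic, truth.affine, out / "roi_ic.nii.gz")
        write_mask(truth.roi_stn, truth.affine, out / "roi_stn.nii.gz")
        write_mask(truth.brain_mask, truth.affine, out / "brain_mask.nii.gz")
        gold = Tractogram(
            [
                Streamline(pts, ("gold", "gold"), pts[0])
                for pts in truth.gold_streamlines.values()
            ],
            truth.affine,
        )
        write_trk(gold, out / "gold_streamlines.trk", truth.grid_shape)
        logger.info("phantom: %d voxels with fibers",
                    int((truth.fractions.sum(axis=3) > 0).sum()))
    except Exception as e:
        raise PipelineError(f"phantom stage failed: {e}") from e

    # stage 2: model fitting ------------------------------------------------
    try:
        tensor = fit_dti(dwi, truth.brain_mask)
        fa_map = fa(tensor.eigenvalues)
        md_map = md(tensor.eigenvalues)
        write_scalar_map(fa_map, truth.affine, out / "fa.nii.gz")
        write_scalar_map(md_map, truth.affine, out / "md.nii.gz")
        write_scalar_map(dec_map(tensor), truth.affine, out / "dec.nii.gz")
        field_ = fit_ball_stick(
            dwi, truth.brain_mask, max_sticks=cfg.max_sticks,
            seed=cfg.seed, fa_gate=cfg.fa_gate,
        )
        write_model_field(field_, out / "model_field.nii.gz", out / "model_field.json")
    except Exception as e:
        raise PipelineError(f"fit stage failed: {e}") from e

    # stage 3: tracking -----------------------------------------------------
    try:
        tractogram = reconstruct_pathway(
            field_, truth.roi_m1_labels > 0, truth.roi_ic, truth.roi_stn,
            truth.brain_mask, cfg.interp, cfg.tracking,
        )
        write_trk(tractogram, out / "pathway.trk", truth.grid_shape)
    except Exception as e:
        raise PipelineError(f"tracking stage failed: {e}") from e

    # stage 4: somatotopy ---------------------------------------------------
    try:
        fset = extract_fascicles(tractogram, truth.roi_m1_labels)
        levels = _slice_levels(truth, params)
        envs = {}
        stats = {}
        for name in SUBDIVISIONS:
            tg = fset[name]
            env = envelope(tg, truth.grid_shape, truth.affine, name=name)
            envs[name] = env
            write_mask(env.mask, truth.affine, out / f"envelope_{name}.nii.gz")
            write_trk(tg, out / f"fascicle_{name}.trk", truth.grid_shape)
            if env.count:
                stats[name] = {
                    "FA": envelope_stats(env, fa_map),
                    "MD": envelope_stats(env, md_map),
                }
        nonempty = {n: e for n, e in envs.items() if e.count}
        table = dsc_table(nonempty, levels, instance=f"seed{cfg.seed}")
        summary_dsc = summarize_dsc([table])
        summary_dsc.per_pair.reset_index().to_csv(
            out / "dsc.csv", index=False, float_format="%.10g"
        )

        centroids = {}
        rankings = {}
        for level, zi in levels.items():
            cs = {}
            for name, env in nonempty.items():
                sm = slice_mask(env, zi)
                if sm.any():
                    cs[name] = centroid(sm, truth.affine, zi)
            centroids[level] = cs
            if len(cs) >= 2:
                order, tied = ap_rank(cs)
                rankings[level] = {"order": order, "tied": tied}

        summary = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_streamlines": len(tractogram),
            "fascicle_counts": {n: len(fset[n]) for n in SUBDIVISIONS},
            "slice_levels": levels,
            "dsc_grand_mean": summary_dsc.grand_mean,
            "dsc_per_pair": {
                level: {f"{a}-{b}": v for (a, b), v in table.values[level].items()}
                for level in table.values
            },
            "centroids": centroids,
            "ap_rankings": rankings,
            "envelope_stats": {
                n: {m: vars(s) for m, s in per.items()} for n, per in stats.items()
            },
        }
        dump_json(summary, out / "summary.json")
    except Exception as e:
        raise PipelineError(f"somatotopy stage failed: {e}") from e

    # provenance records the scientific parameters only; the output
    # location is implied by where the manifest lives
    cfg_dict = cfg.to_dict()
    cfg_dict.pop("out_dir", None)
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    dump_json(manifest, out / "manifest.json")
    dump_yaml(cfg_dict, out / "config.yaml")
    return summary
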