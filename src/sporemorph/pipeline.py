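"""End-to-end orchestration: images → outlines → NEFDs → shape spaces →
traits → correlations → discriminant comparison.

One config drives the whole run; every numeric artifact is a plain-text
file (chain codes, NEFD table, CSVs) so a run is fully reproducible
from the config and the seed alone. A single root seed feeds documented
derived streams per stage, so changing the number of CV replicates
never perturbs the synthetic data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discriminate import compare_feature_sets, standard_feature_sets
from .efa import (
    compute_efd,
    nefd_to_vector,
    normalize_efd,
    read_nefd_file,
    write_nefd_file,
)
from .outline import (
    BinaryImage,
    chain_to_polygon,
    morphological_clean,
    standardize_orientation,
    trace_boundary,
    write_chain_codes,
)
from .shapespace import eigen_table, fit_shape_pca
from .simulate import generate_dataset, sample_species_panel
from .traits import aggregate_per_image, derived_size_traits, measure_length_width, spearman_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("sporemorph.pipeline")

# derived-stream spawn keys off the root seed
_STREAM_SYNTHETIC = 0
_STREAM_CV = 1


@dataclass
class PipelineConfig:
    """All settings of one analysis run.

    Defaults follow the standard protocol: 20 harmonics, 70% training
    fraction, 1000 cross-validation replicates, alpha = 0.05.
    """

    mode: str = "synthetic"  # synthetic | images | polygons | cached
    outdir: str = "sporemorph_run"
    seed: int = 0
    # synthetic design
    n_species: int = 10
    n_specimens: int = 3
    spores_per_specimen: object = (10, 37)
    spores_per_image: object = (1, 4)
    scale_um_per_px: float = 0.1
    # images mode
    images_dir: str | None = None
    manifest_path: str | None = None
    # cached mode: directory of a previous run holding nefd.txt + spores.csv
    cached_dir: str | None = None
    # outline extraction
    clean_mode: str = "none"
    clean_radius: int = 1
    min_area_px: int = 20
    # shape analysis
    n_harmonics: int = 20
    pca_criterion: object = "gt_mean"
    # comparative statistics
    feature_sets: tuple = ("S", "A", "G", "LW", "Q", "QLW", "GLW", "SALW", "SIZEINT")
    train_frac: float = 0.7
    n_reps: int = 1000
    alpha: float = 0.05
    make_figures: bool = False

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spores_per_specimen", "spores_per_image"):
            if isinstance(data.get(key), list):
                data[key] = tuple(data[key])
        if isinstance(data.get("feature_sets"), list):
            data["feature_sets"] = tuple(data["feature_sets"])
        return PipelineConfig(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    spores: pd.DataFrame  # per-spore traits and PC scores
    traits: pd.DataFrame  # per-image trait table
    pca: dict  # variant -> PCAResult
    spearman: tuple  # (rho, p, mask) DataFrames
    comparison: object  # CVComparison
    truth: pd.DataFrame | None = None
    artifacts: dict = field(default_factory=dict)


def _stream(seed: int, key: int):
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _load_images(cfg: PipelineConfig):
    """Images mode: read the manifest CSV and the rasters it names."""
    from PIL import Image

    manifest = pd.read_csv(cfg.manifest_path)
    required = {"image_id", "specimen_id", "species_id"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must contain columns {sorted(required)}")
    images = []
    for image_id in manifest["image_id"]:
        path = os.path.join(cfg.images_dir, f"{image_id}.png")
        if not os.path.exists(path):
            raise FileNotFoundError(f"image file missing for image_id {image_id!r}: {path}")
        arr = np.asarray(Image.open(path).convert("L"))
        images.append(BinaryImage(pixels=arr > 127, scale_um_per_px=cfg.scale_um_per_px))
    return images, manifest


def _extract_polygons(images, manifest, cfg: PipelineConfig):
    """Trace every image; spores are ordered left-to-right within an image."""
    chains_out, polys, rows = [], [], []
    for image_id, img in zip(manifest["image_id"], images):
        try:
            chains = trace_boundary(
                morphological_clean(img, cfg.clean_mode, cfg.clean_radius),
                min_area=cfg.min_area_px,
            )
        except ValueError as exc:
            raise RuntimeError(f"outline extraction failed for image {image_id!r}: {exc}")
        if not chains:
            raise RuntimeError(f"no valid spore outline in image {image_id!r}")
        chains.sort(key=lambda ch: ch.start[1])  # left-to-right
        for j, ch in enumerate(chains, start=1):
            spore_id = f"{image_id}_s{j}"
            chains_out.append((spore_id, ch))
            poly = standardize_orientation(chain_to_polygon(ch, img.scale_um_per_px))
            polys.append((spore_id, image_id, poly))
            rows.append({"spore_id": spore_id, "image_id": image_id})
    return chains_out, polys


def _spore_table(polys, manifest, cfg: PipelineConfig):
    """Measure sizes and NEFDs for every spore polygon."""
    meta = manifest.set_index("image_id")
    nefd_records, rows = [], []
    for spore_id, image_id, poly in polys:
        nefd = normalize_efd(compute_efd(poly, cfg.n_harmonics))
        length, width = measure_length_width(poly)
        q, size_int = derived_size_traits(length, width)
        nefd_records.append((spore_id, image_id, nefd))
        rows.append(
            {
                "spore_id": spore_id,
                "image_id": image_id,
                "specimen_id": meta.loc[image_id, "specimen_id"],
                "species_id": meta.loc[image_id, "species_id"],
                "length_um": length,
                "width_um": width,
                "q_ratio": q,
                "size_int": size_int,
            }
        )
    return pd.DataFrame(rows), nefd_records


# per-variant number of PC-score columns carried into the trait table,
# matching the named feature sets (sym PC1, asym PC1-3, glob PC1-2 at
# minimum; more if the effective rule keeps more)
_MIN_SCORES = {"symmetric": 1, "asymmetric": 3, "global": 2}
_PREFIX = {"symmetric": "sym_pc", "asymmetric": "asym_pc", "global": "glob_pc"}


def _shape_spaces(spores: pd.DataFrame, nefd_records, cfg: PipelineConfig):
    pca = {}
    for variant in ("symmetric", "asymmetric", "global"):
        X = np.vstack([nefd_to_vector(n, variant) for _, _, n in nefd_records])
        res = fit_shape_pca(X, variant, criterion=cfg.pca_criterion)
        pca[variant] = res
        n_keep = max(_MIN_SCORES[variant], len(res.effective_idx))
        n_keep = min(n_keep, res.scores.shape[1])
        for j in range(n_keep):
            spores[f"{_PREFIX[variant]}{j + 1}"] = res.scores[:, j]
    return pca


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured analysis and write all artifacts.

    Re-running with an identical config reproduces every numeric output
    exactly.
    """
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    log_path = os.path.join(cfg.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts = {"log": log_path}
    truth = None
    try:
        logger.info("mode=%s seed=%d hash=%s", cfg.mode, cfg.seed, cfg.config_hash())
        if cfg.mode in ("synthetic", "polygons"):
            syn_rng = _stream(cfg.seed, _STREAM_SYNTHETIC)
            panel = sample_species_panel(
                cfg.n_species, cfg.n_specimens, seed=int(syn_rng.integers(2**31))
            )
            ds = generate_dataset(
                panel,
                spores_per_specimen=cfg.spores_per_specimen,
                scale_um_per_px=cfg.scale_um_per_px,
                seed=int(syn_rng.integers(2**31)),
                spores_per_image=cfg.spores_per_image,
                render_images=cfg.mode == "synthetic",
            )
            truth = ds.truth
            ds.truth.to_csv(os.path.join(cfg.outdir, "truth.csv"), index=False)
            images, manifest = ds.images or None, ds.manifest
        elif cfg.mode == "images":
            images, manifest = _load_images(cfg)
        elif cfg.mode == "cached":
            images, manifest = None, None
        else:
            raise ValueError(f"unknown mode: {cfg.mode!r}")

        if cfg.mode == "cached":
            nefd_records = read_nefd_file(os.path.join(cfg.cached_dir, "nefd.txt"))
            spores = pd.read_csv(os.path.join(cfg.cached_dir, "spores_sizes.csv"))
        elif cfg.mode == "polygons":
            polys = [
                (row.spore_id, row.image_id, ds.polygons[row.spore_id])
                for row in ds.truth.itertuples()
            ]
            spores, nefd_records = _spore_table(polys, manifest, cfg)
        else:
            chains, polys = _extract_polygons(images, manifest, cfg)
            write_chain_codes(os.path.join(cfg.outdir, "chains.txt"), chains)
            artifacts["chains"] = os.path.join(cfg.outdir, "chains.txt")
            spores, nefd_records = _spore_table(polys, manifest, cfg)

        nefd_path = os.path.join(cfg.outdir, "nefd.txt")
        write_nefd_file(nefd_path, nefd_records)
        spores.to_csv(os.path.join(cfg.outdir, "spores_sizes.csv"), index=False)
        artifacts["nefd"] = nefd_path

        pca = _shape_spaces(spores, nefd_records, cfg)
        for variant, res in pca.items():
            eigen_table(res).to_csv(
                os.path.join(cfg.outdir, f"pca_{variant}_eigen.csv"), index=False
            )
        spores.to_csv(os.path.join(cfg.outdir, "spores.csv"), index=False)

        trait_table = aggregate_per_image(spores)
        trait_table.to_csv(os.path.join(cfg.outdir, "traits.csv"), index=False)

        trait_cols = [
            c
            for c in trait_table.columns
            if c not in ("image_id", "specimen_id", "species_id", "n_spores")
        ]
        rho, p, mask = spearman_matrix(trait_table, trait_cols, alpha=cfg.alpha)
        rho.to_csv(os.path.join(cfg.outdir, "spearman_rho.csv"))
        p.to_csv(os.path.join(cfg.outdir, "spearman_p.csv"))
        mask.to_csv(os.path.join(cfg.outdir, "spearman_significant.csv"))

        specs = standard_feature_sets(cfg.feature_sets)
        comparison = compare_feature_sets(
            trait_table,
            specs,
            n_reps=cfg.n_reps,
            seed=int(_stream(cfg.seed, _STREAM_CV).integers(2**31)),
            train_frac=cfg.train_frac,
        )
        comparison.table.to_csv(os.path.join(cfg.outdir, "cv_results.csv"), index=False)
        comparison.replicates.to_csv(
            os.path.join(cfg.outdir, "cv_replicates.csv"), index=False
        )

        if cfg.make_figures:
            _write_figures(cfg, pca, nefd_records, rho, mask)

        cfg.to_yaml(os.path.join(cfg.outdir, "config.yaml"))
        with open(os.path.join(cfg.outdir, "run_manifest.json"), "w") as fh:
            json.dump(
                {
                    "package_version": __version__,
                    "config_hash": cfg.config_hash(),
                    "seed": cfg.seed,
                    "n_spores": int(len(spores)),
                    "n_images": int(trait_table.shape[0]),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        logger.info("run complete: %d spores, %d images", len(spores), len(trait_table))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return PipelineResult(
        config=cfg,
        spores=spores,
        traits=trait_table,
        pca=pca,
        spearman=(rho, p, mask),
        comparison=comparison,
        truth=truth,
        artifacts=artifacts,
    )


def _write_figures(cfg, pca, nefd_records, rho, mask):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .efa import NEFD
    from .shapespace import plot_pc_shape_range
    from .traits import plot_correlation_heatmap

    mean_coeffs = np.mean([n.coeffs for _, _, n in nefd_records], axis=0)
    mean_coeffs[0, :3] = (1.0, 0.0, 0.0)
    mean_nefd = NEFD(coeffs=mean_coeffs, size_scalar=1.0)
    figdir = os.path.join(cfg.outdir, "figures")
    os.makedirs(figdir, exist_ok=True)
    for variant, res in pca.items():
        for pc in res.effective_idx[:3]:
            ax = plot_pc_shape_range(res, mean_nefd, pc)
            ax.figure.savefig(os.path.join(figdir, f"shape_range_{variant}_pc{pc + 1}.png"), dpi=150)
            plt.close(ax.figure)
    ax = plot_correlation_heatmap(rho, mask)
    ax.figure.tight_layout()
    ax.figure.savefig(os.path.join(figdir, "spearman_heatmap.png"), dpi=150)
    plt.close(ax.figure)
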