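"""Synthetic spore panels with known ground truth.

The generative model is a bent capsule: a straight centerline of length L
is given a single-bow offset (``bow_kappa1``) plus an S-shaped offset
(``end_kappa2``) distinguishing the two ends, a symmetric half-width
profile ``(W/2) * (4 t (1-t))**taper_p`` controlling end taper, and a
Gaussian bump of height ``apiculus_h`` on the adaxial (upper) profile at
the proximal end standing in for the hilar appendix. These four shape
axes were chosen so each maps onto one interpretable mode of outline
variation (relative thickness, long-axis bowing, end curvature,
pointedness), which makes parameter-recovery tests possible.

Hierarchical sampling mirrors a taxonomic study design: species means,
between-specimen random effects, and within-specimen (spore-level)
noise. Length and width are sampled on the log scale so dimensions stay
positive and right-skewed; curvature/taper/apiculus terms are Gaussian,
clipped to the parameter invariants.
"""

from __future__ import annotations


from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import polygon as _fill_polygon
from PIL import Image

from .geometry import ensure_ccw

__all__ = [
    "SporeParams",
    "SpeciesShapeModel",
    "SyntheticDataset",
    "PARAM_NAMES",
    "DEFAULT_MEAN_RANGES",
    "DEFAULT_SPECIMEN_SD",
    "DEFAULT_SPORE_SD",
    "sample_species_panel",
    "sample_spore",
    "render_polygon",
    "rasterize_polygon",
    "generate_dataset",
]

PARAM_NAMES = (
    "length_um",
    "width_um",
    "bow_kappa1",
    "end_kappa2",
    "taper_p",
    "apiculus_h",
    "apiculus_sigma",
)

#: indices of parameters sampled on the log scale (positive dimensions)
_LOG_PARAMS = (0, 1)


@dataclass(frozen=True)
class SporeParams:
    """Ground-truth parameters of one spore outline.

    Units: ``length_um``, ``width_um`` and ``apiculus_h`` in micrometres;
    ``bow_kappa1`` and ``end_kappa2`` are centerline-offset amplitudes as
    fractions of length; ``apiculus_sigma`` is the bump width as a
    fraction of length; ``taper_p`` is the dimensionless taper exponent.
    """

    length_um: float
    width_um: float
    bow_kappa1: float = 0.0
    end_kappa2: float = 0.0
    taper_p: float = 0.5
    apiculus_h: float = 0.0
    apiculus_sigma: float = 0.04

    def __post_init__(self):
        if not (self.length_um > 0 and self.width_um > 0):
            raise ValueError("length_um and width_um must be positive")
        if not self.width_um < self.length_um:
            raise ValueError("width_um must be smaller than length_um")
        if not 0 < self.taper_p <= 2:
            raise ValueError("taper_p must lie in (0, 2]")
        if abs(self.bow_kappa1) > 0.2 or abs(self.end_kappa2) > 0.2:
            raise ValueError("|bow_kappa1| and |end_kappa2| must be <= 0.2")
        if self.apiculus_h < 0:
            raise ValueError("apiculus_h must be nonnegative")
        if self.apiculus_sigma <= 0:
            raise ValueError("apiculus_sigma must be positive")

    def to_vector(self) -> np.ndarray:
        """Internal sampling-scale vector (log length, log width, rest raw)."""
        v = np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)
        v[list(_LOG_PARAMS)] = np.log(v[list(_LOG_PARAMS)])
        return v

    @staticmethod
    def from_vector(v: np.ndarray) -> "SporeParams":
        v = np.asarray(v, dtype=float).copy()
        v[list(_LOG_PARAMS)] = np.exp(v[list(_LOG_PARAMS)])
        # clip to invariants rather than reject: random effects may wander
        length, width, bow, end, taper, api_h, api_s = v
        width = min(width, 0.95 * length)
        bow = float(np.clip(bow, -0.2, 0.2))
        end = float(np.clip(end, -0.2, 0.2))
        taper = float(np.clip(taper, 0.05, 2.0))
        api_h = max(api_h, 0.0)
        api_s = max(api_s, 1e-3)
        return SporeParams(length, width, bow, end, taper, api_h, api_s)

    def as_dict(self) -> dict:
        return asdict(self)


def _sd_vector(sd: SporeParams | dict | None) -> np.ndarray:
    """SDs on the internal scale; log-scale for length/width."""
    if sd is None:
        return np.zeros(len(PARAM_NAMES))
    d = sd if isinstance(sd, dict) else sd.as_dict()
    v = np.array([float(d.get(n, 0.0)) for n in PARAM_NAMES])
    if np.any(v < 0):
        raise ValueError("parameter SDs must be nonnegative")
    return v


@dataclass
class SpeciesShapeModel:
    """Species mean shape plus pre-drawn between-specimen random effects."""

    species_id: str
    mean: SporeParams
    specimen_sd: dict = field(default_factory=dict)
    spore_sd: dict = field(default_factory=dict)
    specimen_effects: np.ndarray = field(default=None, repr=False)

    @property
    def n_specimens(self) -> int:
        return 0 if self.specimen_effects is None else len(self.specimen_effects)


# Species-mean ranges loosely emulating the spore spectrum of a
# Subulicystidium-like genus: needle-shaped to short-cylindric spores.
DEFAULT_MEAN_RANGES: dict[str, tuple[float, float]] = {
    "length_um": (6.0, 16.0),
    "width_um": (1.8, 4.5),
    "bow_kappa1": (-0.08, 0.08),
    "end_kappa2": (-0.05, 0.05),
    "taper_p": (0.4, 1.0),
    "apiculus_h": (0.2, 0.5),
    "apiculus_sigma": (0.03, 0.06),
}

# Between-specimen and within-specimen SDs (log scale for length/width).
DEFAULT_SPECIMEN_SD: dict[str, float] = {
    "length_um": 0.04,
    "width_um": 0.04,
    "bow_kappa1": 0.010,
    "end_kappa2": 0.006,
    "taper_p": 0.03,
    "apiculus_h": 0.02,
    "apiculus_sigma": 0.002,
}
DEFAULT_SPORE_SD: dict[str, float] = {
    "length_um": 0.07,
    "width_um": 0.07,
    "bow_kappa1": 0.020,
    "end_kappa2": 0.012,
    "taper_p": 0.05,
    "apiculus_h": 0.04,
    "apiculus_sigma": 0.004,
}


def sample_species_panel(
    n_species: int,
    n_specimens: int,
    mean_ranges: dict | None = None,
    specimen_sd: dict | None = None,
    spore_sd: dict | None = None,
    seed: int = 0,
) -> list[SpeciesShapeModel]:
    """Draw a balanced panel of species shape models.

    Species means are drawn uniformly from ``mean_ranges`` (length and
    width on the log scale of the range endpoints); every species gets
    ``n_specimens`` Gaussian specimen effects on the internal scale.
    """
    if n_species < 2 or n_specimens < 1:
        raise ValueError("need n_species >= 2 and n_specimens >= 1")
    ranges = dict(DEFAULT_MEAN_RANGES)
    if mean_ranges:
        ranges.update(mean_ranges)
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"invalid range for {name}: {(lo, hi)}")
    if ranges["taper_p"][0] <= 0 or ranges["taper_p"][1] > 2:
        raise ValueError("taper_p range must lie in (0, 2]")
    spm_sd = _sd_vector(specimen_sd if specimen_sd is not None else DEFAULT_SPECIMEN_SD)
    spo_sd = dict(DEFAULT_SPORE_SD) if spore_sd is None else dict(spore_sd)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    panel = []
    for i in range(n_species):
        mean = {}
        for name in PARAM_NAMES:
            lo, hi = ranges[name]
            if name in ("length_um", "width_um"):
                mean[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                mean[name] = float(rng.uniform(lo, hi))
        mean["width_um"] = min(mean["width_um"], 0.9 * mean["length_um"])
        effects = rng.normal(0.0, 1.0, size=(n_specimens, len(PARAM_NAMES))) * spm_sd
        panel.append(
            SpeciesShapeModel(
                species_id=f"sp{i + 1:02d}",
                mean=SporeParams(**mean),
                specimen_sd={n: float(s) for n, s in zip(PARAM_NAMES, spm_sd)},
                spore_sd=spo_sd,
                specimen_effects=effects,
            )
        )
    # continuous draws make identical means a measure-zero event; verify anyway
    vecs = np.array([m.mean.to_vector() for m in panel])
    if len(np.unique(vecs, axis=0)) != n_species:
        raise RuntimeError("sampled species means are not mutually distinct")
    return panel


def sample_spore(model: SpeciesShapeModel, specimen_idx: int, rng) -> SporeParams:
    """One spore draw: species mean + specimen effect + spore-level noise."""
    if not 0 <= specimen_idx < model.n_specimens:
        raise IndexError(f"specimen_idx {specimen_idx} outside panel design")
    noise = rng.normal(0.0, 1.0, size=len(PARAM_NAMES)) * _sd_vector(model.spore_sd)
    vec = model.mean.to_vector() + model.specimen_effects[specimen_idx] + noise
    return SporeParams.from_vector(vec)


def render_polygon(params: SporeParams, n_points: int = 200) -> np.ndarray:
    """Evaluate the bent-capsule outline as a counterclockwise polygon (µm).

    The proximal (apiculus) end sits at x = 0, the adaxial side faces +y.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    L, W = params.length_um, params.width_um
    nb = n_points // 2 + 1
    t_b = np.linspace(0.0, 1.0, nb)

    def _centerline(t):
        return params.bow_kappa1 * L * np.sin(np.pi * t) + params.end_kappa2 * L * np.sin(
            2 * np.pi * t
        )

    def _halfwidth(t):
        return (W / 2.0) * (4.0 * t * (1.0 - t)) ** params.taper_p

    if not np.any(_halfwidth(np.linspace(0, 1, 101)) > 0):
        raise ValueError("degenerate parameters: half-width nonpositive everywhere")

    def _apiculus(t):
        if params.apiculus_h == 0:
            return np.zeros_like(t)
        s = params.apiculus_sigma * L
        return params.apiculus_h * np.exp(-((t * L) ** 2) / (2 * s * s))

    bottom = np.column_stack([t_b * L, _centerline(t_b) - _halfwidth(t_b)])
    t_t = t_b[::-1][1:-1]
    top = np.column_stack([t_t * L, _centerline(t_t) + _halfwidth(t_t) + _apiculus(t_t)])
    poly = np.vstack([bottom, top])
    return ensure_ccw(poly)


def rasterize_polygon(
    poly: np.ndarray,
    scale_um_per_px: float,
    pad_px: int = 5,
    canvas_shape: tuple[int, int] | None = None,
):
    """Fill a polygon into a binary raster (spore white, background black).

    Returns a :class:`~sporemorph.outline.BinaryImage`. With
    ``canvas_shape`` given, the spore must fit inside it with the
    requested margin, else an error is raised.
    """
    from .outline import BinaryImage  # local import: outline is downstream

    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3:
        raise ValueError("need a polygon with at least 3 vertices")
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    xmin, ymin = p.min(axis=0)
    xmax, ymax = p.max(axis=0)
    ncols = int(np.ceil((xmax - xmin) / scale_um_per_px)) + 2 * pad_px + 1
    nrows = int(np.ceil((ymax - ymin) / scale_um_per_px)) + 2 * pad_px + 1
    if canvas_shape is not None:
        if nrows > canvas_shape[0] or ncols > canvas_shape[1]:
            raise ValueError("spore does not fit the requested canvas")
        nrows, ncols = canvas_shape
    c = (p[:, 0] - xmin) / scale_um_per_px + pad_px
    r_up = (p[:, 1] - ymin) / scale_um_per_px + pad_px
    r = (nrows - 1) - r_up  # flip to image row convention
    rr, cc = _fill_polygon(r, c, shape=(nrows, ncols))
    pixels = np.zeros((nrows, ncols), dtype=bool)
    pixels[rr, cc] = True
    return BinaryImage(pixels=pixels, scale_um_per_px=float(scale_um_per_px))


@dataclass
class SyntheticDataset:
    """Images plus the manifest/truth tables that describe them."""

    images: list  # list of BinaryImage (empty if render_images=False)
    manifest: pd.DataFrame  # image_id, specimen_id, species_id, n_spores
    truth: pd.DataFrame  # one row per spore incl. true parameters
    polygons: dict  # spore_id -> (N, 2) polygon in µm, proximal end left
    scale_um_per_px: float

    def write(self, outdir) -> None:
        """Write images as PNG and tables as CSV into ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
        self.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
        for image_id, img in zip(self.manifest["image_id"], self.images):
            arr = (img.pixels.astype(np.uint8)) * 255
            Image.fromarray(arr, mode="L").save(os.path.join(outdir, f"{image_id}.png"))


def _compose_images(rasters, gap_px: int = 4):
    """Place per-spore rasters side by side on one canvas, bottom-aligned."""
    from .outline import BinaryImage

    heights = [r.pixels.shape[0] for r in rasters]
    widths = [r.pixels.shape[1] for r in rasters]
    H = max(heights)
    Wtot = sum(widths) + gap_px * (len(rasters) - 1)
    canvas = np.zeros((H, Wtot), dtype=bool)
    x = 0
    for r in rasters:
        h, w = r.pixels.shape
        canvas[H - h :, x : x + w] |= r.pixels
        x += w + gap_px
    return BinaryImage(pixels=canvas, scale_um_per_px=rasters[0].scale_um_per_px)


def generate_dataset(
    panel: list[SpeciesShapeModel],
    spores_per_specimen: int | tuple[int, int] = (10, 37),
    scale_um_per_px: float = 0.1,
    seed: int = 0,
    spores_per_image: int | tuple[int, int] = 1,
    n_polygon_points: int = 200,
    render_images: bool = True,
    pad_px: int = 6,
) -> SyntheticDataset:
    """Sample spores for every specimen in the panel and build the dataset.

    ``spores_per_specimen`` and ``spores_per_image`` may be an int or an
    inclusive (low, high) range. Deterministic for a fixed seed.
    """
    if not panel:
        raise ValueError("empty panel")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def _draw_count(spec) -> int:
        if isinstance(spec, (tuple, list)):
            lo, hi = spec
            return int(rng.integers(lo, hi + 1))
        return int(spec)

    images, manifest_rows, truth_rows, polygons = [], [], [], {}
    image_counter = 0
    for model in panel:
        for j in range(model.n_specimens):
            specimen_id = f"{model.species_id}_sp{j + 1}"
            n_spores = _draw_count(spores_per_specimen)
            spores = [sample_spore(model, j, rng) for _ in range(n_spores)]
            k = 0
            while k < n_spores:
                group = min(_draw_count(spores_per_image), n_spores - k)
                image_counter += 1
                image_id = f"img{image_counter:05d}"
                rasters = []
                for g in range(group):
                    params = spores[k + g]
                    spore_id = f"{image_id}_s{g + 1}"
                    poly = render_polygon(params, n_polygon_points)
                    polygons[spore_id] = poly
                    if render_images:
                        rasters.append(rasterize_polygon(poly, scale_um_per_px, pad_px))
                    truth_rows.append(
                        {
                            "spore_id": spore_id,
                            "image_id": image_id,
                            "specimen_id": specimen_id,
                            "species_id": model.species_id,
                            **params.as_dict(),
                        }
                    )
                if render_images:
                    images.append(_compose_images(rasters))
                manifest_rows.append(
                    {
                        "image_id": image_id,
                        "specimen_id": specimen_id,
                        "species_id": model.species_id,
                        "n_spores": group,
                    }
                )
                k += group
    return SyntheticDataset(
        images=images,
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.DataFrame(truth_rows),
        polygons=polygons,
        scale_um_per_px=float(scale_um_per_px),
    )
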