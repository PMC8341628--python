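"""From micrograph to cleaned, consistently oriented outline polygons.

Stages: threshold to binary (spores white), optional morphological
cleaning (opening removes protruding noise pixels, closing fills
cavities), Moore-neighbour boundary tracing into Freeman 8-direction
chain codes (one per connected spore), conversion to µm polygons in the
mathematical y-up convention, and a 0°/180° rotation that places the
hilar-appendix (proximal) end on the left of the centroid. Objects that
touch the image border or fall under a minimum area are rejected with a
warning rather than repaired — an automated stand-in for selecting
healthy, fully visible spores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _closing, disk, opening as _opening

from .geometry import centroid, ensure_ccw, resample_closed, turning_angles

__all__ = [
    "BinaryImage",
    "ChainCode",
    "binarize",
    "morphological_clean",
    "trace_boundary",
    "chain_to_polygon",
    "standardize_orientation",
    "write_chain_codes",
    "read_chain_codes",
]

# Freeman directions, 0 = east, counterclockwise increase in y-up
# coordinates; expressed as (drow, dcol) in image (row-down) indexing.
FREEMAN_STEPS = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)],
    dtype=int,
)
_STEP_TO_DIR = {tuple(v): i for i, v in enumerate(FREEMAN_STEPS)}


@dataclass
class BinaryImage:
    """Binary raster (True = spore) with its spatial scale in µm/pixel."""

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ChainCode:
    """Freeman chain code of one object boundary.

    ``start`` is the (row, col) of the topmost-then-leftmost boundary
    pixel; ``directions`` the move sequence; ``shape`` the image
    dimensions (needed to flip rows into y-up coordinates later).
    """

    start: tuple[int, int]
    directions: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=np.int8)

    def is_closed(self) -> bool:
        disp = FREEMAN_STEPS[self.directions].sum(axis=0)
        return bool(np.all(disp == 0)) and len(self.directions) >= 4

    def pixel_path(self) -> np.ndarray:
        """(n_moves, 2) array of visited (row, col) pixels, start excluded at end."""
        steps = FREEMAN_STEPS[self.directions]
        path = np.vstack([self.start, np.asarray(self.start) + np.cumsum(steps, axis=0)])
        return path[:-1] if np.all(path[-1] == path[0]) else path


def binarize(gray, method="otsu", scale_um_per_px: float = 1.0) -> BinaryImage:
    """Threshold a single-channel image; spores are the bright phase.

    ``method`` is ``"otsu"`` (automatic) or ``("fixed", t)`` / a number
    for a manual threshold: pixels strictly above ``t`` are foreground.
    """
    img = np.asarray(gray)
    if img.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if img.min() == img.max():
        raise ValueError("blank image: all pixels share one value")
    if method == "otsu":
        t = threshold_otsu(img)
    elif isinstance(method, (tuple, list)) and method[0] == "fixed":
        t = method[1]
    elif isinstance(method, (int, float)):
        t = method
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    return BinaryImage(pixels=img > t, scale_um_per_px=scale_um_per_px)


def morphological_clean(img: BinaryImage, mode: str = "erosion_dilation", radius: int = 1) -> BinaryImage:
    """Morphological cleanup of a binary image.

    ``erosion_dilation`` = opening (drops protruding noise pixels),
    ``dilation_erosion`` = closing (fills cavities), ``both`` = opening
    then closing, ``none`` = identity. Warns if an object vanishes.
    """
    if mode == "none":
        return BinaryImage(img.pixels.copy(), img.scale_um_per_px)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    fp = disk(radius)
    out = img.pixels
    if mode in ("erosion_dilation", "both"):
        out = _opening(out, fp)
    if mode in ("dilation_erosion", "both"):
        out = _closing(out, fp)
    if mode not in ("erosion_dilation", "dilation_erosion", "both"):
        raise ValueError(f"unknown cleaning mode: {mode!r}")
    n_before = ndimage.label(img.pixels, structure=np.ones((3, 3)))[1]
    n_after = ndimage.label(out, structure=np.ones((3, 3)))[1]
    if n_after < n_before:
        warnings.warn(
            f"morphological_clean({mode}, r={radius}) removed "
            f"{n_before - n_after} object(s) entirely"
        )
    return BinaryImage(pixels=out, scale_um_per_px=img.scale_um_per_px)


def _trace_component(mask: np.ndarray, offset: tuple[int, int]) -> ChainCode | None:
    """Moore-neighbour tracing of one padded component mask.

    Scans neighbours counterclockwise (in image coordinates) so the
    emitted boundary runs counterclockwise once rows are flipped to
    y-up. Start pixel: topmost, then leftmost. Terminates when the start
    pixel is about to be left by the initial move again (Jacob's
    stopping criterion).
    """
    fg = np.argwhere(mask)
    order = np.lexsort((fg[:, 1], fg[:, 0]))
    start = (int(fg[order[0]][0]), int(fg[order[0]][1]))
    p, backtrack = start, 4  # west neighbour of topmost-leftmost pixel is background
    directions: list[int] = []
    first_move = None
    max_steps = 4 * len(fg) + 8
    H, W = mask.shape
    while True:
        found = None
        for k in range(1, 9):  # counterclockwise scan starting after backtrack
            d = (backtrack + k) % 8
            r = p[0] + FREEMAN_STEPS[d][0]
            c = p[1] + FREEMAN_STEPS[d][1]
            if 0 <= r < H and 0 <= c < W and mask[r, c]:
                found = (d, (r, c))
                break
        if found is None:
            return None  # isolated pixel: no closed boundary
        d, q = found
        if first_move is None:
            first_move = d
        elif p == start and d == first_move:
            break  # about to repeat the initial move (Jacob's criterion)
        directions.append(d)
        # the neighbour scanned just before q is background; backtrack of q
        prev_d = (backtrack + k - 1) % 8
        cprev = (p[0] + FREEMAN_STEPS[prev_d][0], p[1] + FREEMAN_STEPS[prev_d][1])
        backtrack = _STEP_TO_DIR[(cprev[0] - q[0], cprev[1] - q[1])]
        p = q
        if len(directions) > max_steps:  # pragma: no cover - safety guard
            raise RuntimeError("boundary tracing failed to close")
    return ChainCode(
        start=(start[0] + offset[0], start[1] + offset[1]),
        directions=np.array(directions, dtype=np.int8),
        shape=(-1, -1),  # filled in by trace_boundary
    )


def trace_boundary(img: BinaryImage, min_area: int = 5) -> list[ChainCode]:
    """Trace every connected foreground object into a Freeman chain code.

    8-connected components; objects touching the image border or smaller
    than ``min_area`` pixels are skipped with a warning (an empty list
    is possible). Raises only when the image has no foreground at all.
    """
    labels, n = ndimage.label(img.pixels, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("no foreground object in image")
    H, W = img.pixels.shape
    chains = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        rows, cols = sl
        comp = labels[sl] == i
        area = int(comp.sum())
        if rows.start == 0 or cols.start == 0 or rows.stop == H or cols.stop == W:
            warnings.warn(f"object {i} touches the image border; skipped")
            continue
        if area < min_area:
            warnings.warn(f"object {i} smaller than min_area={min_area}; skipped")
            continue
        chain = _trace_component(comp, offset=(rows.start, cols.start))
        if chain is None:
            warnings.warn(f"object {i} has no closed boundary; skipped")
            continue
        chain.shape = (H, W)
        chains.append(chain)
    if not chains:
        warnings.warn("no valid object remained after filtering")
    return chains


def chain_to_polygon(chain: ChainCode, scale_um_per_px: float = 1.0) -> np.ndarray:
    """Convert a closed chain code to a counterclockwise µm polygon.

    Pixel centers become vertices; image rows are flipped so y grows
    upward.
    """
    if not chain.is_closed():
        raise ValueError("chain code is not closed")
    path = chain.pixel_path()
    H = chain.shape[0]
    x = path[:, 1].astype(float) * scale_um_per_px
    y = (H - 1 - path[:, 0]).astype(float) * scale_um_per_px
    return ensure_ccw(np.column_stack([x, y]))


def _end_sharpness(poly: np.ndarray, n_resample: int = 400, smooth_frac: float = 0.015):
    """Peak boundary curvature near each major-axis end of an outline.

    Returns (score_low, score_high, axis) where low/high refer to the
    projection onto the major axis. Coordinates are smoothed along arc
    length first so pixel staircase noise does not saturate the turning
    angles.
    """
    rs = resample_closed(poly, n_resample)
    sigma = max(smooth_frac * n_resample, 1.0)
    sm = np.column_stack(
        [
            gaussian_filter1d(rs[:, 0], sigma, mode="wrap"),
            gaussian_filter1d(rs[:, 1], sigma, mode="wrap"),
        ]
    )
    c = sm.mean(axis=0)
    cov = np.cov((sm - c).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    proj = (sm - c) @ axis
    lo, hi = proj.min(), proj.max()
    span = hi - lo
    ds = np.hypot(*np.diff(np.vstack([sm, sm[:1]]), axis=0).T)
    kappa = turning_angles(sm) / np.maximum(ds, 1e-12)
    low_win = proj < lo + 0.15 * span
    high_win = proj > hi - 0.15 * span
    return float(kappa[low_win].max()), float(kappa[high_win].max()), axis, c, proj


def standardize_orientation(poly: np.ndarray, appendix_hint: str = "auto") -> np.ndarray:
    """Rotate a polygon by 0° or 180° so the proximal end sits upper-left.

    ``appendix_hint``: ``"auto"`` locates the appendix as the sharper end
    (larger curvature extremum); ``"left"``/``"right"`` state where the
    appendix currently lies and override detection. On an auto tie the
    polygon is returned unchanged with a warning. Arbitrary rotation is
    deliberately not attempted — that is removed later by the Fourier
    normalization.
    """
    p = ensure_ccw(poly)
    c = centroid(p)
    if appendix_hint == "left":
        return p
    if appendix_hint == "right":
        return ensure_ccw(2 * c - p)
    if appendix_hint != "auto":
        raise ValueError(f"unknown appendix_hint: {appendix_hint!r}")
    s_lo, s_hi, axis, c_sm, proj = _end_sharpness(p)
    if abs(s_lo - s_hi) <= 0.05 * max(s_lo, s_hi):
        warnings.warn("appendix end detection tie; polygon left unchanged")
        return p
    # position of the sharper end in the original x/y frame
    end_proj = proj.min() if s_lo > s_hi else proj.max()
    end_xy = c_sm + end_proj * axis
    dx, dy = end_xy - centroid(p)
    appendix_left = dx < 0 if abs(dx) > 1e-9 else dy > 0
    if appendix_left:
        return p
    return ensure_ccw(2 * c - p)


def write_chain_codes(path, chains: list[tuple[str, ChainCode]]) -> None:
    """Plain-text chain-code file, two lines per spore (bit-exact round trip)."""
    with open(path, "w") as fh:
        for spore_id, ch in chains:
            fh.write(
                f"{spore_id} {ch.shape[1]} {ch.shape[0]} "
                f"{ch.start[0]} {ch.start[1]} {len(ch.directions)}\n"
            )
            fh.write("".join(str(int(d)) for d in ch.directions) + "\n")


def read_chain_codes(path) -> list[tuple[str, ChainCode]]:
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i in range(0, len(lines), 2):
        spore_id, w, h, r0, c0, n = lines[i].split()
        digits = lines[i + 1].strip()
        if len(digits) != int(n):
            raise ValueError(f"chain record {spore_id}: move count mismatch")
        out.append(
            (
                spore_id,
                ChainCode(
                    start=(int(r0), int(c0)),
                    directions=np.array([int(d) for d in digits], dtype=np.int8),
                    shape=(int(h), int(w)),
                ),
            )
        )
    return out
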