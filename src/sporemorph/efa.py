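"""Elliptic Fourier analysis of closed outlines.

A closed outline parameterized by arc length t over one period T is
expanded as truncated Fourier series

    x(t) = A0 + sum_n a_n cos(2πnt/T) + b_n sin(2πnt/T)
    y(t) = C0 + sum_n c_n cos(2πnt/T) + d_n sin(2πnt/T)

with closed-form coefficients for a piecewise-linear (polygonal)
outline. Normalization follows the first-harmonic-ellipse procedure:
a start-point rotation aligns the first-harmonic phase, a spatial
rotation aligns its major axis with x, and division by the semi-major
axis removes size; the result has a1 = 1, b1 = c1 = 0, so 20 harmonics
store 80 coefficients of which 77 are free shape variables. The size
scalar (semi-major axis, µm) is retained as metadata.

The residual 180° ambiguity of the first-harmonic frame is resolved
intrinsically: the sharper outline end (the curvature extremum, in
practice the hilar-appendix end) is mapped to negative x. Reflection is
deliberately not normalized away — mirroring is treated as upstream
data curation, not shape mathematics.

Coefficient blocks: for shapes mirror-symmetric about the normalized
major axis the sine/cosine cross terms vanish, so {a_n, d_n} carry the
symmetric and {b_n, c_n} the asymmetric shape variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import as_polygon, resample_closed, turning_angles

__all__ = [
    "EFD",
    "NEFD",
    "compute_efd",
    "normalize_efd",
    "reconstruct_outline",
    "split_sym_asym",
    "nefd_to_vector",
    "nefd_from_vector",
    "vector_index_map",
    "write_nefd_file",
    "read_nefd_file",
]


@dataclass
class EFD:
    """Raw elliptic Fourier descriptors of one outline (µm units)."""

    a0: float
    c0: float
    coeffs: np.ndarray  # (n_harmonics, 4) rows (a_n, b_n, c_n, d_n)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != 4 or len(self.coeffs) < 1:
            raise ValueError("coeffs must have shape (n_harmonics >= 1, 4)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite Fourier coefficients")

    @property
    def n_harmonics(self) -> int:
        return len(self.coeffs)


@dataclass
class NEFD:
    """Normalized (dimensionless) elliptic Fourier descriptors.

    Invariant: coeffs[0] == (1, 0, 0, d1). ``size_scalar`` is the
    semi-major axis of the first-harmonic ellipse in µm.
    """

    coeffs: np.ndarray
    size_scalar: float

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        a1, b1, c1 = self.coeffs[0, :3]
        if abs(a1 - 1) > 1e-6 or abs(b1) > 1e-6 or abs(c1) > 1e-6:
            raise ValueError("not normalized: first harmonic must be (1, 0, 0, d1)")

    @property
    def n_harmonics(self) -> int:
        return len(self.coeffs)


def compute_efd(poly: np.ndarray, n_harmonics: int = 20) -> EFD:
    """Closed-form elliptic Fourier coefficients of a polygonal outline.

    Uses the chord-length parameterization: on each edge the outline is
    linear in arc length, so every Fourier integral has an exact
    closed form.
    """
    p = as_polygon(poly)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    closed = np.vstack([p, p[:1]])
    d = np.diff(closed, axis=0)  # (N, 2) edge vectors
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.all(dt == 0) or dt.sum() <= 0:
        raise ValueError("zero-perimeter polygon")
    keep = dt > 0  # drop duplicate vertices
    d, dt = d[keep], dt[keep]
    starts = closed[:-1][keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T  # (N+1,)
    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    const = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, N)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    vx, vy = d[:, 0] / dt, d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)
    # A0/C0: arc-length weighted mean of the piecewise-linear outline
    mids = starts + 0.5 * d
    a0 = float((dt * mids[:, 0]).sum() / T)
    c0 = float((dt * mids[:, 1]).sum() / T)
    return EFD(a0=a0, c0=c0, coeffs=np.column_stack([a, b, c, dd]))


def _rotate_start(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the outline start point: harmonic n rotated by n*theta."""
    out = np.empty_like(coeffs)
    for i in range(len(coeffs)):
        nth = (i + 1) * theta
        rot = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        m = coeffs[i].reshape(2, 2) @ rot
        out[i] = m.ravel()
    return out


def _rotate_space(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the outline spatially by -psi (align major axis with x)."""
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(coeffs)
    for i in range(len(coeffs)):
        out[i] = (rot @ coeffs[i].reshape(2, 2)).ravel()
    return out


def _phase_angle(row: np.ndarray, harmonic: int) -> float:
    a, b, c, d = row
    return 0.5 * np.arctan2(2.0 * (a * b + c * d), a * a + c * c - b * b - d * d) / harmonic


def _sharper_end_is_right(coeffs: np.ndarray, n_points: int = 400) -> bool | None:
    """Decide the 180° flip from the reconstructed normalized outline.

    Returns True if the sharper (higher peak curvature) end lies at
    positive x, None on a tie.
    """
    pts = _evaluate_series(0.0, 0.0, coeffs, n_points)
    rs = resample_closed(pts, n_points)
    ds = np.hypot(*np.diff(np.vstack([rs, rs[:1]]), axis=0).T)
    kappa = turning_angles(rs) / np.maximum(ds, 1e-12)
    x = rs[:, 0]
    lo, hi = x.min(), x.max()
    span = hi - lo
    s_left = kappa[x < lo + 0.15 * span].max()
    s_right = kappa[x > hi - 0.15 * span].max()
    if abs(s_left - s_right) <= 0.05 * max(s_left, s_right):
        return None
    return s_right > s_left


def normalize_efd(efd: EFD, resolve_flip: bool = True) -> NEFD:
    """First-harmonic normalization: remove size, rotation, translation
    and start point; keep the semi-major axis as ``size_scalar``.
    """
    coeffs = efd.coeffs.copy()
    a1, b1, c1, d1 = coeffs[0]
    major_sq = a1 * a1 + c1 * c1
    minor_sq = b1 * b1 + d1 * d1
    if max(major_sq, minor_sq) <= 0:
        raise ValueError("degenerate first harmonic")
    # near-circular first harmonic: its phase is ill-conditioned, so
    # pre-align the start point using the second harmonic
    axis_ratio_sq = min(major_sq, minor_sq) / max(major_sq, minor_sq)
    if axis_ratio_sq > 0.999**2 and len(coeffs) >= 2:
        warnings.warn(
            "near-circular first harmonic; start point pre-aligned from harmonic 2"
        )
        coeffs = _rotate_start(coeffs, _phase_angle(coeffs[1], 2))
    theta = _phase_angle(coeffs[0], 1)
    cand = _rotate_start(coeffs, theta)
    # the stationary phase can align the minor axis instead; pick the
    # solution with the larger first-harmonic (a1, c1) magnitude
    alt = _rotate_start(coeffs, theta + np.pi / 2.0)
    if alt[0, 0] ** 2 + alt[0, 2] ** 2 > cand[0, 0] ** 2 + cand[0, 2] ** 2:
        cand = alt
    psi = np.arctan2(cand[0, 2], cand[0, 0])
    cand = _rotate_space(cand, psi)
    size = cand[0, 0]  # = sqrt(a1^2 + c1^2) >= 0 by construction
    if size <= 0:
        raise ValueError("degenerate first harmonic (zero semi-major axis)")
    cand = cand / size
    if resolve_flip:
        flip = _sharper_end_is_right(cand)
        if flip is None and len(cand) >= 2:
            # both ends equally sharp: fall back to a deterministic
            # algebraic convention so the result stays orientation
            # invariant — the largest-magnitude symmetric-block (a, d)
            # coefficient among the flip-sensitive (even) harmonics is
            # made positive; restricting to the symmetric block keeps
            # the convention stable under mirror reflection as well
            even_sym = cand[1::2][:, [0, 3]]  # a, d of harmonics 2, 4, ...
            flip = (
                even_sym.ravel()[np.abs(even_sym).argmax()] < 0
                if np.abs(even_sym).max() > 0
                else False
            )
        if flip:
            # 180° spatial rotation combined with a half-period start
            # shift: harmonic n scaled by (-1)^(n+1), first harmonic fixed
            signs = np.where(np.arange(1, len(cand) + 1) % 2 == 0, -1.0, 1.0)
            cand = cand * signs[:, None]
    cand[0, 0], cand[0, 1], cand[0, 2] = 1.0, 0.0, 0.0  # snap exact constants
    return NEFD(coeffs=cand, size_scalar=float(size))


def _evaluate_series(a0: float, c0: float, coeffs: np.ndarray, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, len(coeffs) + 1)[:, None]
    cos = np.cos(2 * np.pi * n * t)
    sin = np.sin(2 * np.pi * n * t)
    x = a0 + coeffs[:, 0] @ cos + coeffs[:, 1] @ sin
    y = c0 + coeffs[:, 2] @ cos + coeffs[:, 3] @ sin
    return np.column_stack([x, y])


def reconstruct_outline(d: "EFD | NEFD", n_points: int = 256, n_harmonics: int | None = None, rescale: bool = False) -> np.ndarray:
    """Evaluate the truncated Fourier series at equally spaced parameters.

    For an :class:`NEFD` the outline is dimensionless unless ``rescale``
    multiplies back the retained size scalar. ``n_harmonics`` truncates
    the series further if given.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    coeffs = d.coeffs
    if n_harmonics is not None:
        coeffs = coeffs[:n_harmonics]
    if isinstance(d, NEFD):
        pts = _evaluate_series(0.0, 0.0, coeffs, n_points)
        return pts * d.size_scalar if rescale else pts
    return _evaluate_series(d.a0, d.c0, coeffs, n_points)


def vector_index_map(n_harmonics: int, variant: str = "global") -> list[tuple[int, int]]:
    """(harmonic index, coefficient column) pairs in storage order.

    Ordering is per-harmonic quadruple (a, b, c, d) with the three
    normalization constants a1, b1, c1 dropped; the symmetric variant
    keeps columns a and d, the asymmetric variant b and c.
    """
    cols = {"global": (0, 1, 2, 3), "symmetric": (0, 3), "asymmetric": (1, 2)}
    if variant not in cols:
        raise ValueError(f"unknown variant: {variant!r}")
    out = []
    for h in range(n_harmonics):
        for c in cols[variant]:
            if h == 0 and c in (0, 1, 2):
                continue  # constants
            out.append((h, c))
    return out


def nefd_to_vector(nefd: NEFD, variant: str = "global") -> np.ndarray:
    """Flatten an NEFD into the feature vector of the requested variant."""
    idx = vector_index_map(nefd.n_harmonics, variant)
    return np.array([nefd.coeffs[h, c] for h, c in idx])


def nefd_from_vector(vec: np.ndarray, variant: str, template: NEFD) -> NEFD:
    """Re-embed a feature vector into a full NEFD.

    Coefficients outside the variant's block (and the constants) are
    taken from ``template`` — used to turn principal-component
    perturbations back into reconstructable shapes.
    """
    coeffs = template.coeffs.copy()
    idx = vector_index_map(template.n_harmonics, variant)
    if len(vec) != len(idx):
        raise ValueError(f"expected vector of length {len(idx)}, got {len(vec)}")
    for v, (h, c) in zip(vec, idx):
        coeffs[h, c] = v
    coeffs[0, 0], coeffs[0, 1], coeffs[0, 2] = 1.0, 0.0, 0.0
    return NEFD(coeffs=coeffs, size_scalar=template.size_scalar)


def split_sym_asym(nefd: NEFD) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric {a_n, d_n} and asymmetric {b_n, c_n} coefficient blocks."""
    return nefd_to_vector(nefd, "symmetric"), nefd_to_vector(nefd, "asymmetric")


def write_nefd_file(path, records: list[tuple[str, str, NEFD]]) -> None:
    """One text file for a whole panel: header, then one spore per line
    ("spore_id image_id size_scalar" + coefficients in storage order).
    """
    with open(path, "w") as fh:
        if records:
            fh.write(f"n_harmonics={records[0][2].n_harmonics}\n")
        for spore_id, image_id, nefd in records:
            vals = " ".join(repr(float(v)) for v in nefd.coeffs.ravel())
            fh.write(f"{spore_id} {image_id} {nefd.size_scalar!r} {vals}\n")


def read_nefd_file(path) -> list[tuple[str, str, NEFD]]:
    with open(path) as fh:
        header = fh.readline().strip()
        k = int(header.split("=")[1])
        out = []
        for line in fh:
            parts = line.split()
            spore_id, image_id, size = parts[0], parts[1], float(parts[2])
            coeffs = np.array([float(v) for v in parts[3:]]).reshape(k, 4)
            out.append((spore_id, image_id, NEFD(coeffs=coeffs, size_scalar=size)))
    return out
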