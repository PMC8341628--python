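"""Principal-component shape spaces over normalized Fourier descriptors.

Three PCAs are run per study — on the symmetric {a_n, d_n} block, the
asymmetric {b_n, c_n} block, and the global (all free) coefficient
vector. PCA is on the covariance matrix without standardization: after
normalization the coefficients already share one dimensionless scale.
"Effective" components are selected by an eigenvalue-magnitude rule
(default: eigenvalue strictly greater than the mean eigenvalue, the
covariance analogue of the Kaiser criterion). Shape variation along a
component is visualized by reconstructing the mean outline perturbed by
±k standard deviations along that component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efa import NEFD, nefd_from_vector, reconstruct_outline

__all__ = [
    "PCAResult",
    "fit_shape_pca",
    "effective_components",
    "pc_shape_range",
    "eigen_table",
    "plot_pc_shape_range",
]

VARIANTS = ("symmetric", "asymmetric", "global")


@dataclass
class PCAResult:
    variant: str
    mean: np.ndarray  # (p,)
    eigenvalues: np.ndarray  # (k,) descending, >= 0
    components: np.ndarray  # (k, p) rows are eigenvectors
    scores: np.ndarray  # (n, k) centered data projected on components
    proportion: np.ndarray  # (k,) fractions of total variance
    effective_idx: list = field(default_factory=list)
    criterion: str = "gt_mean"


def fit_shape_pca(vectors: np.ndarray, variant: str = "global", criterion="gt_mean") -> PCAResult:
    """Covariance PCA of spore-level coefficient vectors.

    Eigenvector signs are fixed so each component's largest-magnitude
    loading is positive, making scores reproducible across runs.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("vectors must be a 2-D (spores x coefficients) matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spores for a PCA")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    # sign convention: largest-|loading| positive
    flip = np.sign(vt[np.arange(len(vt)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = Xc @ vt.T
    total = eig.sum()
    proportion = eig / total if total > 0 else np.full_like(eig, 1.0 / len(eig))
    res = PCAResult(
        variant=variant,
        mean=mean,
        eigenvalues=eig,
        components=vt,
        scores=scores,
        proportion=proportion,
        criterion=criterion if isinstance(criterion, str) else "proportion",
    )
    res.effective_idx = effective_components(res, criterion)
    return res


def effective_components(res: PCAResult, criterion="gt_mean") -> list[int]:
    """Indices of components retained by an eigenvalue-magnitude rule.

    ``"gt_mean"`` keeps eigenvalues strictly greater than the mean
    eigenvalue; ``"kaiser_scaled"`` divides eigenvalues by their mean
    and keeps those above 1 (the same set); ``("proportion", p)`` keeps
    the smallest leading set whose cumulative variance share reaches p.
    At least the first component is always retained.
    """
    eig = res.eigenvalues
    if isinstance(criterion, (tuple, list)) and criterion[0] == "proportion":
        p = float(criterion[1])
        cum = np.cumsum(res.proportion)
        idx = list(range(int(np.searchsorted(cum, p - 1e-12)) + 1))
    elif criterion in ("gt_mean", "kaiser_scaled"):
        idx = list(np.flatnonzero(eig > eig.mean()))
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    return idx if idx else [0]


def pc_shape_range(
    res: PCAResult,
    mean_nefd: NEFD,
    pc: int,
    k_sd: float = 2.0,
    n_points: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outlines at mean − k·SD, mean, and mean + k·SD along one component.

    The perturbed coefficient vectors are re-embedded into the full
    NEFD layout (constants restored, complementary block from the mean)
    and reconstructed.
    """
    if not 0 <= pc < len(res.eigenvalues):
        raise IndexError(f"pc {pc} out of range (have {len(res.eigenvalues)})")
    sd = float(np.sqrt(res.eigenvalues[pc]))
    outlines = []
    for sign in (-1.0, 0.0, 1.0):
        vec = res.mean + sign * k_sd * sd * res.components[pc]
        nefd = nefd_from_vector(vec, res.variant, mean_nefd)
        outlines.append(reconstruct_outline(nefd, n_points))
    return tuple(outlines)


def eigen_table(res: PCAResult) -> pd.DataFrame:
    """Eigenvalue table with variance shares and the effective flag."""
    k = len(res.eigenvalues)
    return pd.DataFrame(
        {
            "component": np.arange(1, k + 1),
            "eigenvalue": res.eigenvalues,
            "proportion": res.proportion,
            "effective": [i in set(res.effective_idx) for i in range(k)],
        }
    )


def plot_pc_shape_range(res: PCAResult, mean_nefd: NEFD, pc: int, k_sd: float = 2.0, ax=None):
    """Mean ± k·SD outline triptych for one principal component."""
    import matplotlib.pyplot as plt

    lo, mid, hi = pc_shape_range(res, mean_nefd, pc, k_sd)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for outline, style, label in (
        (lo, "--", f"-{k_sd:g} SD"),
        (mid, "-", "mean"),
        (hi, ":", f"+{k_sd:g} SD"),
    ):
        closed = np.vstack([outline, outline[:1]])
        ax.plot(closed[:, 0], closed[:, 1], style, label=label)
    ax.set_aspect("equal")
    ax.set_title(f"{res.variant} PC{pc + 1} ({100 * res.proportion[pc]:.1f}% var)")
    ax.legend(fontsize=7)
    return ax
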