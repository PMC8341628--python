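"""Linear size traits, per-image aggregation and trait correlations.

Length is the maximum Feret diameter of the outline (the longest
dimension, the mycological standard); width is the maximal caliper
extent measured perpendicular to the length axis (the broadest
dimension across the spore). Derived traits: the classical length/width
ratio Q, and an integrated size sqrt(length × width) that is less
entangled with shape than either measurement alone.

Because shape and size acquisition may not be alignable per spore when
an image holds several spores, the observation unit of all comparative
statistics is the average-per-image trait value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

__all__ = [
    "measure_length_width",
    "derived_size_traits",
    "aggregate_per_image",
    "spearman_matrix",
    "plot_correlation_heatmap",
]

ID_COLUMNS = ("image_id", "specimen_id", "species_id")


def measure_length_width(poly: np.ndarray) -> tuple[float, float]:
    """(length, width) of an outline in µm.

    Length = max pairwise distance between outline points (max Feret);
    width = extent perpendicular to the length axis. Always
    length >= width.
    """
    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or len(p) < 3:
        raise ValueError("degenerate polygon")
    try:
        hull = p[ConvexHull(p).vertices]
    except Exception as exc:  # collinear / degenerate input
        raise ValueError("degenerate polygon") from exc
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = float(np.sqrt(d2[i, j]))
    if length <= 0:
        raise ValueError("degenerate polygon")
    axis = (hull[j] - hull[i]) / length
    perp = np.array([-axis[1], axis[0]])
    proj = p @ perp
    width = float(proj.max() - proj.min())
    return max(length, width), min(length, width)


def derived_size_traits(length: float, width: float) -> tuple[float, float]:
    """(Q ratio, integrated size): L/W and sqrt(L·W)."""
    if not (length >= width > 0):
        raise ValueError("need length >= width > 0")
    return length / width, float(np.sqrt(length * width))


def aggregate_per_image(records: pd.DataFrame) -> pd.DataFrame:
    """Average every trait over the spores of each image.

    ``records`` needs one row per spore with the id columns
    (image_id, specimen_id, species_id) and numeric trait columns.
    Labels must be constant within an image.
    """
    for col in ID_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing id column: {col}")
    nun = records.groupby("image_id")[["specimen_id", "species_id"]].nunique()
    bad = nun[(nun > 1).any(axis=1)]
    if len(bad):
        raise ValueError(f"conflicting labels within image(s): {list(bad.index)}")
    traits = [
        c
        for c in records.columns
        if c not in ID_COLUMNS + ("spore_id",) and pd.api.types.is_numeric_dtype(records[c])
    ]
    grouped = records.groupby("image_id", sort=False)
    out = grouped[traits].mean()
    out.insert(0, "specimen_id", grouped["specimen_id"].first())
    out.insert(1, "species_id", grouped["species_id"].first())
    out["n_spores"] = grouped.size()
    return out.reset_index()


def spearman_matrix(
    table: pd.DataFrame,
    traits: list[str],
    alpha: float = 0.05,
    adjust: str | None = None,
):
    """Pairwise Spearman correlations with a significance mask.

    Average-rank ties; two-sided p-values from the t approximation;
    p-values are unadjusted by default, ``adjust="holm"`` applies a
    Holm correction over the off-diagonal pairs. Constant trait columns
    yield missing correlations with a warning.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    X = table[list(traits)].to_numpy(dtype=float)
    k = len(traits)
    traits = list(traits)
    constant = [t for t, col in zip(traits, X.T) if np.ptp(col) == 0]
    if constant:
        warnings.warn(f"constant trait column(s), correlations undefined: {constant}")
    good = [i for i, t in enumerate(traits) if t not in constant]
    rho_arr = np.full((k, k), np.nan)
    p_arr = np.full((k, k), np.nan)
    if len(good) >= 2:
        sub_rho, sub_p = stats.spearmanr(X[:, good])
        if len(good) == 2:  # scipy returns scalars for two columns
            sub_rho = np.array([[1.0, sub_rho], [sub_rho, 1.0]])
            sub_p = np.array([[0.0, sub_p], [sub_p, 0.0]])
        rho_arr[np.ix_(good, good)] = sub_rho
        p_arr[np.ix_(good, good)] = sub_p
    for i in good:
        rho_arr[i, i], p_arr[i, i] = 1.0, 0.0
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(k, 1)
        pvals = p_arr[iu]
        ok = np.isfinite(pvals)
        if ok.any():
            adj = pvals.copy()
            adj[ok] = multipletests(pvals[ok], method="holm")[1]
            p_arr[iu] = adj
            p_arr[(iu[1], iu[0])] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    rho = pd.DataFrame(rho_arr, index=traits, columns=traits)
    p = pd.DataFrame(p_arr, index=traits, columns=traits)
    mask = p < alpha
    return rho, p, mask


def plot_correlation_heatmap(rho: pd.DataFrame, mask: pd.DataFrame, ax=None):
    """Correlation heatmap with non-significant cells greyed out."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    shown = rho.where(mask)
    im = ax.imshow(shown.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho)), rho.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(rho)), rho.index, fontsize=7)
    plt.colorbar(im, ax=ax, label="Spearman rho (significant only)")
    return ax
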