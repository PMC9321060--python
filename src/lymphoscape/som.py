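"""Batch self-organizing map over gene expression profiles, and portraits.

Genes (points in sample space) are distributed over a planar rectangular grid
of prototype "metagenes" so that co-expressed genes end up in the same or
adjacent pixels. Evaluating all prototypes for one sample yields that
sample's *portrait* — the image of its metagene expression.

Training is the deterministic batch variant: per epoch every gene is
assigned to its Euclidean best-matching unit (BMU, ties to the lowest pixel
index), then each prototype is recomputed as the Gaussian-neighborhood-
weighted mean of the assigned gene profiles. The neighborhood radius decays
linearly from max(rows, cols)/2 to ``final_radius`` over the epochs, and the
grid is initialized on the plane of the first two principal components of
the gene cloud, so a run is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger("lymphoscape")

__all__ = [
    "SOMModel",
    "Portrait",
    "preprocess",
    "quantile_normalize",
    "train_som",
    "portrait",
    "portraits",
    "group_mean_portrait",
    "difference_portrait",
    "correlation_map",
]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) to a common distribution.

    Every column is replaced by the mean sorted profile, assigned by rank
    (ties resolved by column order, as in the classical procedure).
    """
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n = values.shape[0]
    rows = np.arange(n)
    for j in range(values.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    return mean_sorted[ranks]


def preprocess(em: ExpressionMatrix, quantile_normalize_flag: bool = False) -> ExpressionMatrix:
    """Optional quantile normalization, then mandatory per-gene centering.

    After centering every gene has zero mean across samples, so portraits
    show differential expression. A single-sample matrix is rejected —
    centering it would zero the data.
    """
    if em.n_samples < 2:
        raise ValueError("preprocess requires at least 2 samples (centering is degenerate)")
    values = em.values
    if quantile_normalize_flag:
        values = quantile_normalize(values)
    centered = values - values.mean(axis=1, keepdims=True)
    return em.copy_with(centered)


@dataclass
class SOMModel:
    """A trained metagene grid.

    ``prototypes`` holds one profile across samples per pixel (pixels x
    samples); ``bmu`` maps every gene ID to its pixel index, with pixel
    index = row * grid_cols + col on a planar (non-toroidal) grid.
    """

    grid_rows: int
    grid_cols: int
    prototypes: np.ndarray
    bmu: dict[str, int]
    sample_ids: list[str]
    sample_labels: dict[str, str] | None = None
    epochs: int = 0
    radii: tuple[float, ...] = ()
    quantization_errors: tuple[float, ...] = ()
    seed: int = 0

    @property
    def n_pixels(self) -> int:
        return self.grid_rows * self.grid_cols

    def pixel_coords(self, pixel: int) -> tuple[int, int]:
        return divmod(pixel, self.grid_cols)

    def genes_of_pixels(self, pixels: set[int]) -> set[str]:
        return {g for g, p in self.bmu.items() if p in pixels}


def _grid_positions(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _pca_plane_init(X: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Initial prototypes on the grid spanning +-2 sd along the first two
    principal components of the (column-mean-removed) gene cloud."""
    center = X.mean(axis=0)
    Xc = X - center
    cov = Xc.T @ Xc
    w, v = np.linalg.eigh(cov)
    pcs = v[:, ::-1][:, :2]  # columns: PC1, PC2 directions in sample space
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, k]))
        if pcs[i, k] < 0:
            pcs[:, k] = -pcs[:, k]
    scores = Xc @ pcs
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    row_span = np.linspace(-2.0, 2.0, rows) if rows > 1 else np.zeros(1)
    col_span = np.linspace(-2.0, 2.0, cols) if cols > 1 else np.zeros(1)
    rr, cc = np.meshgrid(row_span, col_span, indexing="ij")
    # columns follow PC1, rows follow PC2
    coords = np.column_stack([cc.ravel() * sd[0], rr.ravel() * sd[1]])
    return center[None, :] + coords @ pcs.T


def _assign_bmu(X: np.ndarray, prototypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-matching unit per gene and squared distance to it.

    argmin over squared Euclidean distance; np.argmin takes the lowest index
    on ties, which is the documented tie-break.
    """
    # ||x||^2 - 2 x.p + ||p||^2 ; the ||x||^2 term is shared across pixels
    cross = X @ prototypes.T
    pn = np.einsum("ij,ij->i", prototypes, prototypes)
    d2 = pn[None, :] - 2.0 * cross
    bmu = np.argmin(d2, axis=1)
    xn = np.einsum("ij,ij->i", X, X)
    best = d2[np.arange(len(X)), bmu] + xn
    return bmu, np.maximum(best, 0.0)


def train_som(em: ExpressionMatrix, rows: int = 50, cols: int = 50,
              epochs: int = 20, seed: int = 0, final_radius: float = 1.0) -> SOMModel:
    """Train the batch SOM on a row-centered expression matrix.

    Raises if the input is not centered (any |gene mean| > 1e-6) or if a NaN
    appears during training (reported with the epoch index). Emits a warning
    when there are fewer genes than pixels.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    X = em.values
    row_means = X.mean(axis=1)
    if np.abs(row_means).max() > 1e-6:
        raise ValueError("train_som expects per-gene centered input (run preprocess first)")
    n_genes, n_samples = X.shape
    n_pixels = rows * cols
    if n_genes < n_pixels:
        logger.warning("fewer genes (%d) than pixels (%d); many metagenes will be empty",
                       n_genes, n_pixels)

    prototypes = _pca_plane_init(X, rows, cols)
    grid = _grid_positions(rows, cols)
    gd2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)

    radius0 = max(rows, cols) / 2.0
    radii = (np.linspace(radius0, final_radius, epochs) if epochs > 1
             else np.array([final_radius]))
    qe_history = []
    bmu = np.zeros(n_genes, dtype=int)
    for epoch, radius in enumerate(radii):
        bmu, d2 = _assign_bmu(X, prototypes)
        qe_history.append(float(np.sqrt(d2).mean()))
        h = np.exp(-gd2 / (2.0 * radius * radius))
        counts = np.bincount(bmu, minlength=n_pixels).astype(float)
        sums = np.zeros((n_pixels, n_samples))
        np.add.at(sums, bmu, X)
        denom = h @ counts
        prototypes = (h @ sums) / denom[:, None]
        if not np.all(np.isfinite(prototypes)):
            raise FloatingPointError(f"NaN in prototypes at epoch {epoch}")
    bmu, _ = _assign_bmu(X, prototypes)

    return SOMModel(
        grid_rows=rows, grid_cols=cols, prototypes=prototypes,
        bmu={g: int(p) for g, p in zip(em.gene_ids, bmu)},
        sample_ids=list(em.sample_ids),
        sample_labels=dict(em.sample_labels) if em.sample_labels else None,
        epochs=epochs, radii=tuple(float(r) for r in radii),
        quantization_errors=tuple(qe_history), seed=seed,
    )


@dataclass
class Portrait:
    """Per-sample vector over grid pixels (the sample's metagene image)."""

    sample_id: str
    pixel_values: np.ndarray
    grid_rows: int
    grid_cols: int

    def as_image(self) -> np.ndarray:
        return self.pixel_values.reshape(self.grid_rows, self.grid_cols)


def portrait(model: SOMModel, sample_id: str) -> Portrait:
    try:
        j = model.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample {sample_id!r}") from None
    return Portrait(sample_id, model.prototypes[:, j].copy(),
                    model.grid_rows, model.grid_cols)


def portraits(model: SOMModel) -> list[Portrait]:
    return [Portrait(s, model.prototypes[:, j].copy(), model.grid_rows, model.grid_cols)
            for j, s in enumerate(model.sample_ids)]


def group_mean_portrait(portrait_list: list[Portrait], labels: dict[str, str],
                        group: str) -> Portrait:
    members = [p for p in portrait_list if labels.get(p.sample_id) == group]
    if not members:
        raise ValueError(f"group {group!r} has no samples")
    values = np.mean([p.pixel_values for p in members], axis=0)
    g = members[0]
    return Portrait(f"mean({group})", values, g.grid_rows, g.grid_cols)


def difference_portrait(pa: Portrait, pb: Portrait) -> Portrait:
    if pa.pixel_values.shape != pb.pixel_values.shape:
        raise ValueError("portraits come from different grids")
    return Portrait(f"{pa.sample_id} - {pb.sample_id}",
                    pa.pixel_values - pb.pixel_values, pa.grid_rows, pa.grid_cols)


def render_portrait(p: Portrait, path, cmap: str = "RdBu_r") -> None:
    """Write a portrait as a PNG image (red = over-, blue = under-expression,
    symmetric color scale around zero)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    img = p.as_image()
    limit = max(abs(float(img.min())), abs(float(img.max())), 1e-12)
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(img, cmap=cmap, vmin=-limit, vmax=limit, interpolation="nearest")
    ax.set_title(p.sample_id, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def correlation_map(portrait_list: list[Portrait]) -> np.ndarray:
    """Pairwise Pearson correlation of portraits (symmetric, unit diagonal).

    Zero-variance portraits get correlation 0 to every other portrait, with
    a warning.
    """
    if len(portrait_list) < 2:
        raise ValueError("correlation_map needs at least 2 portraits")
    mat = np.array([p.pixel_values for p in portrait_list])
    sd = mat.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance portrait(s); correlations set to 0", flat.sum())
    safe = mat.copy()
    safe[flat] = 0.0
    centered = safe - safe.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr
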