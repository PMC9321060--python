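"""Segmentation of over-expression spot modules from the portrait landscape.

Spots are segmented on the *summary map* — the pixel-wise maximum over the
group-mean portraits. Pixels above a map-value quantile are kept and grouped
into spots as 8-connected components of *coherently co-expressed* metagenes:
two adjacent above-threshold pixels belong to the same spot only when they
fall in the same profile cluster (average-linkage clustering of the pixels'
prototype profiles, cut at a Pearson-correlation threshold). The coherence
criterion matters because distinct co-expression modules that are activated
in the same subtype sit side by side at equal summary height — a pure
height-based segmentation would fuse them even though their expression
profiles across samples clearly differ. Each spot inherits the genes whose
BMUs fall inside its pixels; those gene sets are the candidate classifier
signatures. Only over-expression (red) spots are extracted; letters are
assigned in decreasing order of spot peak height.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .som import Portrait, SOMModel

__all__ = ["Spot", "SpotSet", "summary_map", "detect_spots", "spot_expression"]

_LETTERS = string.ascii_uppercase


@dataclass
class Spot:
    letter: str
    pixels: set[int]
    genes: set[str]
    seed_pixel: int  # pixel holding the spot's maximum
    peak: float


@dataclass
class SpotSet:
    spots: list[Spot]
    grid_rows: int
    grid_cols: int
    threshold: float
    threshold_quantile: float
    source: str = "summary"

    def __iter__(self):
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def __getitem__(self, letter: str) -> Spot:
        for s in self.spots:
            if s.letter == letter:
                return s
        raise KeyError(f"no spot {letter!r}")

    @property
    def letters(self) -> list[str]:
        return [s.letter for s in self.spots]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.letter, len(s.pixels), len(s.genes), s.peak, s.seed_pixel) for s in self.spots],
            columns=["letter", "n_pixels", "n_genes", "peak", "seed_pixel"],
        ).set_index("letter")


def summary_map(group_portraits: list[Portrait]) -> np.ndarray:
    """Pixel-wise maximum over group-mean portraits (flat pixel vector)."""
    if not group_portraits:
        raise ValueError("summary_map needs at least one group portrait")
    shapes = {(p.grid_rows, p.grid_cols) for p in group_portraits}
    if len(shapes) > 1:
        raise ValueError(f"mixed grid sizes: {sorted(shapes)}")
    return np.max([p.pixel_values for p in group_portraits], axis=0)


def _profile_clusters(profiles: np.ndarray, coherence: float) -> np.ndarray:
    """Average-linkage clustering of pixel prototype profiles on Pearson
    correlation distance, cut at 1 - coherence."""
    n = len(profiles)
    if n == 1:
        return np.zeros(1, dtype=int)
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    return hierarchy.fcluster(link, t=1.0 - coherence, criterion="distance")


def detect_spots(map_values: np.ndarray, model: SOMModel,
                 threshold_quantile: float = 0.98, min_size: int = 3,
                 coherence: float = 0.85) -> SpotSet:
    """Segment over-expression spots from a pixel map.

    Pixels strictly above the ``threshold_quantile`` quantile of the map are
    kept and partitioned into profile clusters (pairs of pixels cohere when
    their prototype profiles correlate at ``coherence`` or better under the
    average-linkage cut); 8-connected components are then formed within each
    cluster, components below ``min_size`` pixels are discarded, and the
    survivors are lettered A, B, ... in decreasing order of their peak value.
    A constant map yields an empty SpotSet (no pixel is strictly above the
    quantile), not an error. Raising the threshold quantile never enlarges
    any spot's pixel set.
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must lie in (0, 1)")
    if not 0.0 <= coherence < 1.0:
        raise ValueError("coherence must lie in [0, 1)")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    values = np.asarray(map_values, dtype=float)
    if values.size != model.n_pixels:
        raise ValueError("map size does not match the model grid")
    thr = float(np.quantile(values, threshold_quantile))
    mask_flat = values > thr
    pixels = np.flatnonzero(mask_flat)
    components = []
    if len(pixels):
        clusters = _profile_clusters(model.prototypes[pixels], coherence)
        for c in np.unique(clusters):
            cluster_mask = np.zeros(model.n_pixels, dtype=bool)
            cluster_mask[pixels[clusters == c]] = True
            img = cluster_mask.reshape(model.grid_rows, model.grid_cols)
            labeled, n = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
            for k in range(1, n + 1):
                idx = np.flatnonzero((labeled == k).ravel())
                if len(idx) < min_size:
                    continue
                peak_pixel = idx[np.argmax(values[idx])]
                components.append((float(values[peak_pixel]), int(peak_pixel),
                                   set(int(i) for i in idx)))
    components.sort(key=lambda c: (-c[0], c[1]))
    spots = []
    for rank, (peak, seed_pixel, pixels) in enumerate(components):
        letter = _LETTERS[rank] if rank < len(_LETTERS) else f"S{rank}"
        spots.append(Spot(letter, pixels, model.genes_of_pixels(pixels), seed_pixel, peak))
    return SpotSet(spots, model.grid_rows, model.grid_cols, thr, threshold_quantile)


def spot_expression(spotset: SpotSet, portrait_list: list[Portrait]) -> pd.DataFrame:
    """Mean portrait pixel value over each spot's pixels, per sample
    (spots x samples)."""
    rows = {}
    for spot in spotset:
        if not spot.pixels:
            raise ValueError(f"spot {spot.letter} has no pixels")
        idx = sorted(spot.pixels)
        rows[spot.letter] = [float(p.pixel_values[idx].mean()) for p in portrait_list]
    return pd.DataFrame(rows, index=[p.sample_id for p in portrait_list]).T
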