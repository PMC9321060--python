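"""End-to-end orchestration of the portrayal pipeline on a cohort.

``run_landscape`` chains preprocessing, SOM training, group portraits,
summary map and spot detection on any labeled expression matrix;
``run_synthetic_landscape`` does the same on a freshly drawn default
synthetic cohort and keeps the ground truth for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import auc_score
from .io import ExpressionMatrix
from .scoring import GSZProfile, gsz
from .simulate import CohortSpec, CohortTruth, DLBCL_LIKE, default_mmml_spec, generate_cohort
from .som import Portrait, SOMModel, group_mean_portrait, portraits, preprocess, train_som
from .spots import SpotSet, detect_spots, summary_map

__all__ = [
    "LandscapeResult", "run_landscape", "run_synthetic_landscape",
    "synthetic_spot_quantile", "match_spots_to_modules", "spot_auc",
]


def synthetic_spot_quantile(spec: CohortSpec, margin: float = 0.10) -> float:
    """Spot-detection quantile matched to the planted geometry.

    Planted modules occupy roughly their gene share of the map, so the
    summary-map threshold must sit just below the module plateaus: one minus
    the module gene share, minus a safety margin into the plateaus (which
    trades a sliver of the weakest module pixels against background halo
    pickup). For the default cohort this evaluates to ~0.80.
    """
    share = sum(m.gene_count for m in spec.modules) / spec.n_genes
    return round(1.0 - share - margin * share, 3)


@dataclass
class LandscapeResult:
    expression: ExpressionMatrix          # as loaded/generated (log2)
    centered: ExpressionMatrix            # after preprocess
    model: SOMModel
    sample_portraits: list[Portrait]
    group_portraits: dict[str, Portrait]
    summary: np.ndarray
    spots: SpotSet
    truth: CohortTruth | None = None
    spot_of_module: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, str]:
        assert self.expression.sample_labels is not None
        return self.expression.sample_labels

    def module_spot_genes(self, letter: str) -> set[str]:
        """Gene set of the recovered spot matched to planted module ``letter``."""
        return set(self.spots[self.spot_of_module[letter]].genes)


def run_landscape(em: ExpressionMatrix, rows: int = 50, cols: int = 50,
                  epochs: int = 20, seed: int = 0,
                  spot_quantile: float = 0.98, min_spot_size: int = 3,
                  quantile_normalize: bool = False) -> LandscapeResult:
    if em.sample_labels is None:
        raise ValueError("run_landscape needs sample labels for group portraits")
    centered = preprocess(em, quantile_normalize_flag=quantile_normalize)
    model = train_som(centered, rows=rows, cols=cols, epochs=epochs, seed=seed)
    sample_ports = portraits(model)
    groups = sorted(set(em.sample_labels.values()))
    group_ports = {g: group_mean_portrait(sample_ports, em.sample_labels, g) for g in groups}
    summary = summary_map(list(group_ports.values()))
    spots = detect_spots(summary, model, threshold_quantile=spot_quantile,
                         min_size=min_spot_size)
    return LandscapeResult(em, centered, model, sample_ports, group_ports, summary, spots)


def run_synthetic_landscape(seed: int = 1, total: int = 300,
                            rows: int = 20, cols: int = 20, epochs: int = 20,
                            spot_quantile: float | None = None,
                            min_spot_size: int = 3,
                            spec: CohortSpec | None = None) -> LandscapeResult:
    """Generate the default synthetic cohort and run the full landscape
    analysis on it, matching recovered spots to planted modules."""
    if spec is None:
        spec = default_mmml_spec(total=total, seed=seed)
    if spot_quantile is None:
        spot_quantile = synthetic_spot_quantile(spec)
    em, truth = generate_cohort(spec)
    result = run_landscape(em, rows=rows, cols=cols, epochs=epochs, seed=seed,
                           spot_quantile=spot_quantile, min_spot_size=min_spot_size)
    result.truth = truth
    result.spot_of_module = match_spots_to_modules(result.spots, truth)
    return result


def match_spots_to_modules(spotset: SpotSet, truth: CohortTruth) -> dict[str, str]:
    """Best recovered spot per planted module, by gene-set Jaccard."""
    out: dict[str, str] = {}
    for letter, genes in truth.module_genes.items():
        gset = set(genes)
        best, best_j = None, -1.0
        for spot in spotset:
            inter = len(gset & spot.genes)
            union = len(gset | spot.genes)
            j = inter / union if union else 0.0
            if j > best_j:
                best, best_j = spot.letter, j
        if best is not None:
            out[letter] = best
    return out


def recovery_jaccard(result: LandscapeResult) -> pd.Series:
    """Jaccard between each planted module and its matched recovered spot."""
    assert result.truth is not None
    rows = {}
    for letter, spot_letter in result.spot_of_module.items():
        gset = result.truth.genes_of(letter)
        sgenes = result.spots[spot_letter].genes
        rows[letter] = len(gset & sgenes) / len(gset | sgenes)
    return pd.Series(rows).sort_index()


def spot_auc(result: LandscapeResult, module_letter: str,
             positive, negative) -> float:
    """AUC of the recovered spot (matched to a planted module) as a GSZ
    classifier for a two-group contrast of stratum labels."""
    genes = result.module_spot_genes(module_letter)
    profile = gsz(result.centered, genes, name=f"spot~{module_letter}")
    labels = result.labels
    pos_set = {positive} if isinstance(positive, str) else set(positive)
    neg_set = {negative} if isinstance(negative, str) else set(negative)
    lab = np.array([labels[s] for s in profile.sample_ids])
    pos = np.isin(lab, sorted(pos_set))
    neg = np.isin(lab, sorted(neg_set))
    keep = pos | neg
    return auc_score(profile.scores[keep], pos[keep])
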