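"""Benchmarking spot and literature signatures as subtype classifiers.

GSZ profiles serve as the classifier scores: ROC/AUC for two-group
contrasts (AUC via the tie-corrected Mann-Whitney rank formula), sample
detection at the GSZ > 0 rule, mutual gene-overlap and joint-detection
matrices, random-subset resampling stability, GSZ-profile correlation
clustering, and combinatorial pattern-type (PAT) stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import ExpressionMatrix, Signature
from .scoring import GSZProfile, gsz
from .som import Portrait
from .spots import SpotSet, spot_expression

logger = logging.getLogger("lymphoscape")

__all__ = [
    "ROCResult", "PATLabel", "roc", "auc_score", "evaluate_signatures",
    "joint_detection", "gene_overlap", "resample_stability",
    "gsz_correlation_clusters", "pat_assign",
]

EMPTY_PAT = "∅"  # rendered for samples with no activated spot


@dataclass
class ROCResult:
    name: str
    positive: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def auc_score(scores: np.ndarray, positive_mask: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n_pos = int(positive_mask.sum())
    n_neg = int((~positive_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[positive_mask].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc(scores: np.ndarray, labels: np.ndarray, positive) -> ROCResult:
    """ROC curve by threshold sweep over the unique scores, plus rank AUC.

    A sample is called positive at threshold t when score >= t; the curve is
    monotone from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"positive class {positive!r} or its complement is absent")
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        called = scores >= t
        tpr.append(float((called & pos).sum() / n_pos))
        fpr.append(float((called & ~pos).sum() / n_neg))
    return ROCResult(
        name="", positive=str(positive),
        thresholds=thresholds, tpr=np.array(tpr), fpr=np.array(fpr),
        auc=auc_score(scores, pos), n_pos=n_pos, n_neg=n_neg,
    )


def _as_label_set(group) -> set[str]:
    if isinstance(group, str):
        return {group}
    return set(group)


def _contrast_masks(labels: np.ndarray, contrast) -> tuple[np.ndarray, np.ndarray]:
    pos_labels, neg_labels = (_as_label_set(g) for g in contrast)
    pos = np.isin(labels, sorted(pos_labels))
    neg = np.isin(labels, sorted(neg_labels))
    if not pos.any() or not neg.any():
        raise ValueError(f"contrast {contrast} matches no samples on one side")
    return pos, neg


def evaluate_signatures(em: ExpressionMatrix, sigs: list[Signature] | dict[str, set[str]],
                        labels: dict[str, str], contrast) -> pd.DataFrame:
    """One AUC row per signature for a two-group contrast.

    Samples outside the contrast are excluded (a BL-vs-DLBCL comparison
    ignores FL, etc.). Signatures with fewer than 2 matched genes are kept
    as flagged rows with NaN AUC rather than silently dropped.
    """
    if isinstance(sigs, dict):
        sigs = [Signature(n, "up", frozenset(g)) for n, g in sigs.items()]
    lab = np.array([labels[s] for s in em.sample_ids])
    pos, neg = _contrast_masks(lab, contrast)
    keep = pos | neg
    rows = []
    for sig in sigs:
        matched = len(sig.genes & set(em.gene_ids))
        if matched < 2:
            rows.append((sig.name, np.nan, int(pos.sum()), int(neg.sum()), matched, True))
            logger.warning("signature %r has %d matched gene(s); flagged", sig.name, matched)
            continue
        profile = gsz(em, sig)
        a = auc_score(profile.scores[keep], pos[keep])
        rows.append((sig.name, a, int(pos.sum()), int(neg.sum()), matched, False))
    return pd.DataFrame(rows, columns=["signature", "auc", "n_pos", "n_neg",
                                       "n_genes_matched", "flagged"]).set_index("signature")


def joint_detection(profiles: list[GSZProfile]) -> pd.DataFrame:
    """Jaccard overlap of detected samples (GSZ > 0) per signature pair."""
    if len(profiles) < 2:
        raise ValueError("joint_detection needs at least 2 profiles")
    names = [p.name for p in profiles]
    detected = [np.asarray(p.scores) > 0 for p in profiles]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, di in enumerate(detected):
        for j, dj in enumerate(detected):
            union = (di | dj).sum()
            if union == 0:
                out.iloc[i, j] = 1.0 if i == j else 0.0
            else:
                out.iloc[i, j] = (di & dj).sum() / union
    return out


def gene_overlap(sigs: list[Signature]) -> pd.DataFrame:
    """Raw |A intersect B| counts per signature pair."""
    names = [s.name for s in sigs]
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(sigs):
        for j, b in enumerate(sigs):
            out.iloc[i, j] = len(a.genes & b.genes)
    return out


def detection_rates(profile: GSZProfile, labels: dict[str, str],
                    group) -> float:
    """Fraction of the group's samples with GSZ strictly greater than 0."""
    members = _as_label_set(group)
    mask = np.array([labels[s] in members for s in profile.sample_ids])
    if not mask.any():
        raise ValueError(f"no samples in group {group!r}")
    return float((profile.scores[mask] > 0).mean())


def resample_stability(spot_genes: set[str], fractions, reps: int,
                       em: ExpressionMatrix, labels: dict[str, str], contrast,
                       seed: int = 0) -> pd.DataFrame:
    """AUC distribution over random gene subsets of a spot signature.

    For each fraction, ``reps`` subsets are drawn without replacement, scored
    by GSZ and evaluated as classifiers for the contrast; the table reports
    the median and interquartile range per fraction (individual AUCs in the
    ``aucs`` column). Fully seeded.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    genes = sorted(spot_genes & set(em.gene_ids))
    lab = np.array([labels[s] for s in em.sample_ids])
    pos, neg = _contrast_masks(lab, contrast)
    keep = pos | neg
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        k = int(round(frac * len(genes)))
        if k < 2:
            raise ValueError(f"fraction {frac} leaves a subset of {k} gene(s)")
        aucs = np.empty(reps)
        for r in range(reps):
            subset = set(rng.choice(genes, size=k, replace=False)) if k < len(genes) else set(genes)
            profile = gsz(em, subset, name=f"subset_{frac}_{r}")
            aucs[r] = auc_score(profile.scores[keep], pos[keep])
        rows.append((float(frac), k, float(np.median(aucs)),
                     float(np.percentile(aucs, 25)), float(np.percentile(aucs, 75)), aucs))
    return pd.DataFrame(rows, columns=["fraction", "subset_size", "median_auc",
                                       "q25", "q75", "aucs"]).set_index("fraction")


def gsz_correlation_clusters(profiles: list[GSZProfile]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pairwise Pearson matrix of GSZ profiles plus a 2-cluster split by
    average-linkage hierarchical clustering on correlation distance."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    names = [p.name for p in profiles]
    mat = np.array([p.scores for p in profiles])
    sd = mat.std(axis=1)
    if (sd == 0).any():
        logger.warning("constant GSZ profile(s); correlations set to 0")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    return (pd.DataFrame(corr, index=names, columns=names),
            {n: int(c) for n, c in zip(names, cut)})


@dataclass(frozen=True)
class PATLabel:
    """Pattern type of a sample: its activated spot letters, alphabetical."""

    sample_id: str
    letters: str  # e.g. "AD"; empty set rendered as the EMPTY_PAT glyph

    def __str__(self) -> str:
        return self.letters if self.letters else EMPTY_PAT


def pat_assign(portrait_list: list[Portrait], spotset: SpotSet,
               activation_quantile: float = 0.90) -> tuple[list[PATLabel], pd.DataFrame]:
    """Assign each sample its pattern type (combination of activated spots).

    A spot counts as activated in a sample when its mean portrait value is
    strictly positive AND strictly exceeds the ``activation_quantile``
    quantile of that sample's portrait pixels — a sign-plus-prominence rule
    that keeps PATs sparse and invariant to positive rescaling. Returns the
    per-sample labels and a PAT group table (counts per pattern).
    """
    if not 0.0 < activation_quantile < 1.0:
        raise ValueError("activation_quantile must lie in (0, 1)")
    expr = spot_expression(spotset, portrait_list)  # spots x samples
    labels_out = []
    for p in portrait_list:
        thr = float(np.quantile(p.pixel_values, activation_quantile))
        active = [s.letter for s in spotset
                  if expr.loc[s.letter, p.sample_id] > 0
                  and expr.loc[s.letter, p.sample_id] > thr]
        labels_out.append(PATLabel(p.sample_id, "".join(sorted(active))))
    counts = pd.Series([str(l) for l in labels_out]).value_counts()
    table = counts.rename_axis("pat").to_frame("n_samples")
    return labels_out, table
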