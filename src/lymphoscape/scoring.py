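"""Gene-set Z-score (GSZ) sample scoring, signature maps, and spot enrichment.

The GSZ gives one standardized activity value per sample for a gene set: the
z-score of the set's mean (centered) expression against drawing an equally
sized set at random from all genes of that sample, i.e. a finite-population
standardization of the set mean,

    GSZ_s = (m_set - m_all) / sqrt( (sd_all^2 / n) * (N - n) / (N - 1) )

with m_set the mean over the n matched set genes, and m_all / sd_all the
mean and (sample) standard deviation over all N genes in sample s. A sample
with sd_all = 0, or a set spanning the whole universe, scores 0. Under this
standardization the GSZ of a uniformly random gene set has mean ~0 and
variance ~1 for realistically large N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, Signature
from .som import SOMModel
from .spots import SpotSet

logger = logging.getLogger("lymphoscape")

__all__ = ["GSZProfile", "EnrichmentResult", "gsz", "gsz_table",
           "map_signature", "spot_enrichment"]


@dataclass
class GSZProfile:
    """Per-sample GSZ values for one signature."""

    name: str
    sample_ids: list[str]
    scores: np.ndarray
    n_matched: int
    n_universe: int

    def series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.name)


def _matched(genes, universe_index: dict[str, int]) -> np.ndarray:
    return np.array(sorted(universe_index[g] for g in genes if g in universe_index),
                    dtype=int)


def gsz(em: ExpressionMatrix, sig: Signature | set[str], name: str | None = None) -> GSZProfile:
    """GSZ profile of a signature over a per-gene centered matrix.

    Accepts a Signature or a bare gene set. Fewer than 2 matched genes is an
    error (listing the unmatched IDs); matching below 50% of the signature
    draws a warning.
    """
    if isinstance(sig, Signature):
        genes, sig_name = sig.genes, sig.name
    else:
        genes, sig_name = set(sig), name or "gene_set"
    index = {g: i for i, g in enumerate(em.gene_ids)}
    idx = _matched(genes, index)
    if len(idx) < 2:
        unmatched = sorted(set(genes) - set(index))
        raise ValueError(
            f"signature {sig_name!r}: only {len(idx)} gene(s) matched; "
            f"unmatched: {unmatched[:10]}{'...' if len(unmatched) > 10 else ''}"
        )
    if len(idx) < 0.5 * len(genes):
        logger.warning("signature %r: only %d/%d genes found in the universe",
                       sig_name, len(idx), len(genes))
    x = em.values
    n, N = len(idx), em.n_genes
    m_set = x[idx].mean(axis=0)
    m_all = x.mean(axis=0)
    sd_all = x.std(axis=0, ddof=1)
    denom = np.sqrt(sd_all**2 / n * (N - n) / (N - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, (m_set - m_all) / np.where(denom > 0, denom, 1.0), 0.0)
    return GSZProfile(sig_name, list(em.sample_ids), scores, n_matched=n, n_universe=N)


def gsz_table(em: ExpressionMatrix, sigs: list[Signature]) -> pd.DataFrame:
    """Samples x signatures table of GSZ values."""
    return pd.DataFrame({s.name: gsz(em, s).scores for s in sigs}, index=em.sample_ids)


def map_signature(sig: Signature | set[str], model: SOMModel,
                  spotset: SpotSet | None = None,
                  name: str | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-pixel counts of a signature's gene BMUs, plus a spot accumulation
    summary (spots ranked by contained signature genes) when a SpotSet is
    given. Counts sum to the number of matched genes."""
    genes = sig.genes if isinstance(sig, Signature) else set(sig)
    matched = [g for g in genes if g in model.bmu]
    if not matched:
        raise ValueError("no signature gene is assigned to the SOM")
    counts = np.zeros(model.n_pixels)
    for g in matched:
        counts[model.bmu[g]] += 1
    rows = []
    if spotset is not None:
        for spot in spotset:
            inside = len(set(matched) & spot.genes)
            rows.append((spot.letter, inside, len(matched), inside / len(matched)))
        rows.sort(key=lambda r: -r[1])
    summary = pd.DataFrame(rows, columns=["spot", "n_genes", "n_matched", "fraction"])
    return counts, summary


@dataclass
class EnrichmentResult:
    """Signature x spot over-representation (one-sided Fisher exact)."""

    overlap: pd.DataFrame  # counts
    p: pd.DataFrame        # one-sided p-values
    log10_p: pd.DataFrame
    p_bonferroni: pd.DataFrame | None = None


def fisher_upper_tail(overlap: int, n_sig: int, n_spot: int, n_universe: int) -> float:
    """P(X >= overlap) for X hypergeometric(N=universe, K=spot, n=sig)."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_spot, n_sig))


def spot_enrichment(sigs: list[Signature], spotset: SpotSet,
                    universe: set[str], bonferroni: bool = False) -> EnrichmentResult:
    """Fisher exact over-representation of each signature in each spot.

    The universe is the set of genes assigned to the SOM (the landscape
    conditions the test). No multiple-testing correction by default; a
    Bonferroni-adjusted table is reported alongside on request.
    """
    N = len(universe)
    letters = spotset.letters
    overlap = pd.DataFrame(0, index=[s.name for s in sigs], columns=letters, dtype=int)
    pvals = pd.DataFrame(1.0, index=overlap.index, columns=letters)
    for spot in spotset:
        spot_genes = spot.genes & universe
        if not spot_genes:
            raise ValueError(f"spot {spot.letter} has an empty gene set within the universe")
        for sig in sigs:
            sig_genes = sig.genes & universe
            k = len(sig_genes & spot_genes)
            overlap.loc[sig.name, spot.letter] = k
            pvals.loc[sig.name, spot.letter] = fisher_upper_tail(
                k, len(sig_genes), len(spot_genes), N)
    log10p = np.log10(pvals)
    bonf = None
    if bonferroni:
        bonf = (pvals * pvals.size).clip(upper=1.0)
    return EnrichmentResult(overlap=overlap, p=pvals, log10_p=log10p, p_bonferroni=bonf)
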