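"""Percentile-rank normalization against a reference tumor population.

Raw panel expression is not comparable across assays or batches; the
analysis therefore expresses every gene as a 0-100 percentile rank of the
sample's expression within a fixed reference population of tumors
(reference analogue: 167 multi-tumor patients). Signature scores are
arithmetic means of member-gene ranks, and scores are discretized into
fixed tertiles (low < 33, medium 33-66, high > 66 on the rank scale).

Ties between a sample and reference members take the midpoint convention:
rank = 100 * (#below + 0.5 * #equal) / n_ref, so a sample identical to a
reference member receives that member's mid-rank. Ranks are kept
continuous; nothing downstream requires integer ranks and rounding would
create artifacts at the 33/66 boundaries.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds

TERTILES = ("low", "medium", "high")


def rank_transform(values, reference_values):
    """Percentile rank (0-100) of value(s) within a reference sample.

    Parameters
    ----------
    values : float or array-like
    reference_values : array-like, the reference distribution (any order).

    Returns
    -------
    float or ndarray in [0, 100], midpoint tie convention. Monotone
    non-decreasing in the sample value; below all references -> 0,
    above all -> 100.
    """
    ref = np.sort(np.asarray(reference_values, dtype=float))
    if ref.size == 0:
        raise ValueError("reference_values must be non-empty")
    scalar = np.isscalar(values) or np.ndim(values) == 0
    v = np.atleast_1d(np.asarray(values, dtype=float))
    below = np.searchsorted(ref, v, side="left")
    below_or_equal = np.searchsorted(ref, v, side="right")
    ranks = 100.0 * (below + 0.5 * (below_or_equal - below)) / ref.size
    return float(ranks[0]) if scalar else ranks


class ReferencePopulation:
    """A genes x samples reference expression matrix with rank machinery.

    Parameters
    ----------
    expression : DataFrame, genes as rows (index = uppercase symbols),
        reference samples as columns. At least 3 samples.
    """

    def __init__(self, expression: pd.DataFrame):
        if expression.shape[1] < 3:
            raise ValueError("reference population needs >= 3 samples")
        if expression.index.duplicated().any():
            raise ValueError("duplicated gene symbols in reference")
        self.expression = expression.astype(float)
        # per-gene ascending reference values, one row per gene
        self._sorted = np.sort(self.expression.to_numpy(), axis=1)
        self._self_ranks: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def n_ref(self) -> int:
        return self.expression.shape[1]

    def rank_samples(self, expression: pd.DataFrame) -> pd.DataFrame:
        """Rank every gene of every sample against the reference.

        `expression` is genes x samples; all its genes must exist in the
        reference. Returns a genes x samples DataFrame of ranks in [0,100].
        """
        missing = expression.index.difference(self.genes)
        if len(missing):
            raise KeyError(f"genes absent from reference: {sorted(missing)[:10]}")
        sorted_ref = self._sorted[self.genes.get_indexer(expression.index)]
        vals = expression.to_numpy(dtype=float)
        ranks = np.empty_like(vals)
        for i in range(vals.shape[0]):  # per gene: vectorized over samples
            row = sorted_ref[i]
            lo = np.searchsorted(row, vals[i], side="left")
            hi = np.searchsorted(row, vals[i], side="right")
            ranks[i] = 100.0 * (lo + 0.5 * (hi - lo)) / row.size
        return pd.DataFrame(ranks, index=expression.index, columns=expression.columns)

    def self_ranks(self) -> pd.DataFrame:
        """Leave-one-in ranks of the reference samples against themselves (cached)."""
        if self._self_ranks is None:
            self._self_ranks = self.rank_samples(self.expression)
        return self._self_ranks

    def signature_scores(self, gene_set: Sequence[str]) -> pd.Series:
        """Signature score (mean member-gene self-rank) per reference sample.

        This is the reference distribution that a study sample's signature
        score is ranked against.
        """
        return signature_score_cohort(self.self_ranks(), list(gene_set))


def signature_score(ranks: Mapping[str, float], gene_set: Iterable[str]) -> float:
    """Arithmetic mean of member-gene ranks for one sample.

    `ranks` maps gene symbol -> rank in [0,100] (e.g. one column of a rank
    matrix). Raises if the set is empty or any member gene is missing.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in ranks]
    if missing:
        raise KeyError(f"genes missing from rank profile: {missing}")
    return float(np.mean([ranks[g] for g in genes]))


def signature_score_cohort(ranks: pd.DataFrame, gene_set: Sequence[str]) -> pd.Series:
    """Signature scores for every sample (column) of a rank matrix."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in ranks.index]
    if missing:
        raise KeyError(f"genes missing from rank matrix: {missing}")
    return ranks.loc[genes].mean(axis=0)


def tertile_of(score: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Fixed-cut tertile of a rank-scale score.

    low: score < 33; medium: 33 <= score <= 66 (both boundaries inclusive);
    high: score > 66.
    """
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    if score < thresholds.tertile_low:
        return "low"
    if score <= thresholds.tertile_high:
        return "medium"
    return "high"


def tertile_of_cohort(scores: pd.Series,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    vals = scores.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 100)
    if bad.any():
        raise ValueError(
            f"scores outside [0, 100] for samples {list(scores.index[bad])[:5]}")
    out = np.where(vals < thresholds.tertile_low, "low",
                   np.where(vals <= thresholds.tertile_high, "medium", "high"))
    return pd.Series(out, index=scores.index, name="tertile")


def reference_signature_rank(score: float, reference_scores) -> float:
    """Rank a sample's signature score against the reference score distribution."""
    return rank_transform(score, reference_scores)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    return df.astype(float)


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")
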