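"""Per-patient biomarker strata: proliferation, PD-L1 TPS and cold tumors.

Proliferation status is the tertile (poorly/moderately/highly) of the
patient's 10-gene signature score, where the score is itself re-ranked
against the distribution of signature scores in the reference population.
PD-L1 categories follow the standard TPS cuts (negative < 1%, weakly
positive 1-49%, strongly positive >= 50%). Cold tumors are flagged by a
low CD8 transcript rank at two cut-offs (an arbitrary strict < 15 and the
lower-tertile < 33).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds
from .gene_sets import CD8_GENES, PROLIFERATION_GENES
from .ranking import (ReferencePopulation, rank_transform, signature_score,
                      signature_score_cohort, tertile_of, tertile_of_cohort)

#: mapping from rank tertile to proliferation status
TERTILE_TO_STATUS = {"low": "poorly", "medium": "moderately", "high": "highly"}
PROLIFERATION_STATUSES = ("poorly", "moderately", "highly")
PDL1_CATEGORIES = ("negative", "weak_positive", "strong_positive")
PDL1_MISSING = "missing"


def pdl1_category(tps: Optional[float],
                  thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """PD-L1 category from the tumor proportion score (percent).

    Missing TPS returns ``"missing"``; such patients are excluded from
    PD-L1 analyses only.
    """
    if tps is None or (isinstance(tps, float) and math.isnan(tps)):
        return PDL1_MISSING
    if not (0.0 <= tps <= 100.0):
        raise ValueError(f"TPS {tps} outside [0, 100]")
    if tps < thresholds.tps_positive:
        return "negative"
    if tps < thresholds.tps_strong:
        return "weak_positive"
    return "strong_positive"


def proliferation_status(profile: Mapping[str, float],
                         reference: ReferencePopulation,
                         thresholds: Thresholds = DEFAULT_THRESHOLDS,
                         gene_set: Sequence[str] = PROLIFERATION_GENES,
                         rerank: bool = True) -> str:
    """Proliferation stratum of one sample's rank profile.

    With ``rerank`` (default) the sample's mean signature rank is ranked
    against the reference population's own signature-score distribution
    before the fixed 33/66 tertile cuts are applied; with ``rerank=False``
    the tertile cut is applied to the mean of gene ranks directly.
    """
    score = signature_score(profile, gene_set)
    if rerank:
        score = rank_transform(score, reference.signature_scores(gene_set))
    return TERTILE_TO_STATUS[tertile_of(score, thresholds)]


def signature_rank_cohort(ranks: pd.DataFrame,
                          reference: ReferencePopulation,
                          gene_set: Sequence[str] = PROLIFERATION_GENES,
                          rerank: bool = True) -> pd.Series:
    """Signature rank per sample (re-ranked against the reference by default)."""
    scores = signature_score_cohort(ranks, gene_set)
    if rerank:
        ref_scores = reference.signature_scores(gene_set)
        scores = pd.Series(rank_transform(scores.to_numpy(), ref_scores),
                           index=scores.index)
    return scores.rename("signature_rank")


def proliferation_status_cohort(ranks: pd.DataFrame,
                                reference: ReferencePopulation,
                                thresholds: Thresholds = DEFAULT_THRESHOLDS,
                                gene_set: Sequence[str] = PROLIFERATION_GENES,
                                rerank: bool = True) -> pd.Series:
    scores = signature_rank_cohort(ranks, reference, gene_set, rerank)
    return tertile_of_cohort(scores, thresholds).map(TERTILE_TO_STATUS) \
        .rename("proliferation")


def cold_tumor_flags(cd8_rank: float,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> Tuple[bool, bool]:
    """(cold at the strict <15 cut, cold at the lower-tertile <33 cut)."""
    if not (0.0 <= cd8_rank <= 100.0):
        raise ValueError(f"CD8 rank {cd8_rank} outside [0, 100]")
    return (cd8_rank < thresholds.cd8_cold_strict,
            cd8_rank < thresholds.cd8_cold_tertile)


def cd8_rank_cohort(ranks: pd.DataFrame,
                    genes: Sequence[str] = CD8_GENES) -> pd.Series:
    """CD8 transcript rank per sample (mean of CD8A/CD8B reference ranks).

    Configurable to a single transcript by passing ``genes=("CD8A",)``.
    """
    return signature_score_cohort(ranks, genes).rename("cd8_rank")


def assign_strata(ranks: pd.DataFrame,
                  clinical: pd.DataFrame,
                  reference: ReferencePopulation,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS,
                  cd8_genes: Sequence[str] = CD8_GENES) -> pd.DataFrame:
    """Full stratum table for a cohort.

    Returns one row per patient: proliferation status, signature rank,
    PD-L1 category, CD8 rank and both cold flags. Patient ids must match
    the rank-matrix columns.
    """
    ids = clinical["patient_id"]
    missing = set(ids) - set(ranks.columns)
    if missing:
        raise KeyError(f"patients without expression: {sorted(missing)[:5]}")
    sub = ranks[list(ids)]
    sig = signature_rank_cohort(sub, reference)
    prolif = tertile_of_cohort(sig, thresholds).map(TERTILE_TO_STATUS)
    cd8 = cd8_rank_cohort(sub, cd8_genes)
    pdl1 = [pdl1_category(t if pd.notna(t) else None, thresholds)
            for t in clinical["pd_l1_tps"]]
    out = pd.DataFrame({
        "patient_id": ids.to_numpy(),
        "proliferation": prolif.to_numpy(),
        "signature_rank": sig.to_numpy(),
        "pd_l1": pdl1,
        "cd8_rank": cd8.to_numpy(),
    })
    out["cold_15"] = out["cd8_rank"] < thresholds.cd8_cold_strict
    out["cold_33"] = out["cd8_rank"] < thresholds.cd8_cold_tertile
    return out


@dataclass(frozen=True)
class AccuracyRow:
    """Confusion counts of a single-gene (or mean-signature) DC prediction."""

    marker: str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def single_gene_accuracy(ranks: pd.DataFrame,
                         labels: pd.Series,
                         reference: ReferencePopulation,
                         thresholds: Thresholds = DEFAULT_THRESHOLDS,
                         gene_set: Sequence[str] = PROLIFERATION_GENES) -> pd.DataFrame:
    """Accuracy of each signature gene, and of the 10-gene mean, for DC.

    The classification rule predicts disease control for patients in the
    *moderately* stratum of the marker (single-gene reference rank, or the
    re-ranked 10-gene mean) and no disease control otherwise; accuracy is
    (TP + TN) / n against the observed DC/NDC labels. The rule is a
    deliberate, stated convention — see the package methods note for why
    alternative published accuracy figures may not be comparable.
    """
    use = labels[labels.isin(["DC", "NDC"])]
    obs_dc = (use == "DC").to_numpy()
    sub = ranks[use.index]
    rows = []
    for gene in gene_set:
        tert = tertile_of_cohort(sub.loc[gene], thresholds)
        pred_dc = (tert == "medium").to_numpy()
        rows.append(_confusion(gene, pred_dc, obs_dc))
    status = proliferation_status_cohort(sub, reference, thresholds, gene_set)
    pred_dc = (status == "moderately").to_numpy()
    rows.append(_confusion(f"{len(gene_set)}-gene mean", pred_dc, obs_dc))
    return pd.DataFrame(
        [{"marker": r.marker, "tp": r.tp, "tn": r.tn, "fp": r.fp, "fn": r.fn,
          "accuracy": r.accuracy} for r in rows]
    )


def _confusion(marker: str, pred_dc: np.ndarray, obs_dc: np.ndarray) -> AccuracyRow:
    return AccuracyRow(
        marker=marker,
        tp=int((pred_dc & obs_dc).sum()),
        tn=int((~pred_dc & ~obs_dc).sum()),
        fp=int((pred_dc & ~obs_dc).sum()),
        fn=int((~pred_dc & obs_dc).sum()),
    )
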