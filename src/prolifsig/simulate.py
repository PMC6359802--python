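"""Synthetic reference populations and ICI-treated NSCLC cohorts.

The generator produces data with the statistical structure the analysis
assumes, so every pipeline stage can be exercised end-to-end without any
external download:

* a reference population (default 167 samples) with log-normal per-gene
  expression in which the 10 proliferation-signature genes load on a
  shared latent proliferation axis;
* a patient cohort whose latent proliferation distribution is shifted and
  scaled so that the poorly/moderately/highly strata occur at realistic
  NSCLC frequencies (defaults 22.5 / 38.3 / 39.2%);
* PD-L1 tumor proportion scores from a zero-inflated mixture hitting the
  target prevalences (26.7% strongly positive, 46.7% positive at any
  level), with strong positivity enriched among moderately proliferative
  tumors on the logit scale;
* RECIST best responses drawn so that the disease-control rate in each
  proliferation-by-PD-L1 stratum matches its configured probability, with
  response labels kept consistent with the drawn survival (a DC patient
  whose observed follow-up is under 12 months is CR/PR, never SD);
* per-stratum survival with configured medians, administratively censored
  to a configured alive fraction, plus a small fraction of early deaths
  so that the 90-day exclusion logic is exercised rather than bypassed.

Everything is driven by one integer-seeded ``numpy`` Generator: the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import stratify
from .config import DEFAULT_THRESHOLDS, Thresholds
from .gene_sets import (CD8_GENES, PROLIFERATION_GENES, GeneSetCatalog,
                        printed_function_sets)
from .ranking import ReferencePopulation

#: DC probability per (proliferation status, PD-L1 strongly positive) cell.
DEFAULT_DC_PROBS: Dict[Tuple[str, bool], float] = {
    ("moderately", True): 0.588, ("moderately", False): 0.444,
    ("highly", True): 0.400, ("highly", False): 0.138,
    ("poorly", True): 0.400, ("poorly", False): 0.136,
}

#: Median overall survival (months) per (moderately?, strongly positive?) cell.
DEFAULT_SURVIVAL_MEDIANS: Dict[Tuple[bool, bool], float] = {
    (True, True): 14.6, (True, False): 12.6,
    (False, True): 11.5, (False, False): 7.6,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    n_reference: int = 167
    n_patients: int = 120
    n_genes: int = 394
    n_categories: int = 41
    category_size_jitter: Tuple[float, float] = (0.7, 1.3)
    latent_loading: float = 0.8
    gene_noise_sd: float = 0.10
    baseline_sd: float = 2.0
    tertile_targets: Tuple[float, float, float] = (0.225, 0.383, 0.392)
    tps_strong_target: float = 0.267
    tps_positive_target: float = 0.467
    strong_logit_shift_moderate: float = 0.97
    dc_probs: Dict[Tuple[str, bool], float] = field(
        default_factory=lambda: dict(DEFAULT_DC_PROBS))
    survival_medians: Dict[Tuple[bool, bool], float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_MEDIANS))
    alive_fraction: float = 0.5
    not_evaluable_fraction: float = 10 / 120
    early_death_fraction: float = 0.06
    cold15_fraction: Optional[float] = 0.50
    n_institutions: int = 10
    dominant_institution_share: float = 0.30
    histology_probs: Tuple[float, float, float] = (94 / 120, 25 / 120, 1 / 120)

    def __post_init__(self) -> None:
        if min(self.n_reference, self.n_patients, self.n_genes,
               self.n_categories) <= 0:
            raise ValueError("sizes must be positive")
        if self.n_reference < 3:
            raise ValueError("n_reference must be >= 3")
        for p in (*self.dc_probs.values(), self.tps_strong_target,
                  self.tps_positive_target, self.alive_fraction,
                  self.not_evaluable_fraction, self.early_death_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.tps_positive_target < self.tps_strong_target:
            raise ValueError("any-positive prevalence cannot be below strong prevalence")
        if any(m <= 0 for m in self.survival_medians.values()):
            raise ValueError("survival medians must be positive")
        if abs(sum(self.tertile_targets) - 1.0) > 1e-6:
            raise ValueError("tertile target fractions must sum to 1")
        if self.cold15_fraction is not None and not (0.0 < self.cold15_fraction < 1.0):
            raise ValueError("cold15_fraction must lie in (0, 1) or be None")

    def flat(self, dc_prob: float = 35 / 110) -> "SimulationConfig":
        """A null configuration: no latent loading, no DC or TPS structure.

        Used for false-positive studies of the function screen.
        """
        return replace(
            self,
            latent_loading=0.0,
            strong_logit_shift_moderate=0.0,
            cold15_fraction=None,
            dc_probs={k: dc_prob for k in self.dc_probs},
            survival_medians={k: 12.0 for k in self.survival_medians},
        )


@dataclass
class PanelModel:
    """Gene-level generative parameters shared by reference and cohort."""

    genes: List[str]
    baseline: np.ndarray        # per-gene log-expression baseline
    loading: np.ndarray         # per-gene loading on the latent axis
    noise_sd: float
    catalog: GeneSetCatalog


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulated study comprises."""

    config: SimulationConfig
    model: PanelModel
    reference_expression: pd.DataFrame
    cohort_expression: pd.DataFrame
    clinical: pd.DataFrame
    catalog: GeneSetCatalog

    @property
    def reference(self) -> ReferencePopulation:
        return ReferencePopulation(self.reference_expression)


def build_panel_model(config: SimulationConfig,
                      rng: np.random.Generator) -> PanelModel:
    """Gene symbols, per-gene baselines/loadings and the 41-set catalog.

    The catalog ships the three published categories plus a CD8 T-cell
    set; the remainder are synthetic categories drawn from filler symbols
    (no published membership exists for them).
    """
    printed = printed_function_sets()
    named = [g for genes in printed.values() for g in genes]
    named += [g for g in CD8_GENES if g not in named]
    if config.n_genes < len(named):
        raise ValueError(f"n_genes must be >= {len(named)} to hold the named genes")
    fillers = [f"IMMGENE{i:03d}" for i in range(1, config.n_genes - len(named) + 1)]
    genes = named + fillers

    # CD8A/CD8B are panel members (they drive the cold-tumor rank) but are
    # not one of the function categories screened
    catalog: GeneSetCatalog = {k: list(v) for k, v in printed.items()}
    n_extra = config.n_categories - len(catalog)
    # the panel is *divided* into function categories: the synthetic ones
    # partition the filler pool, with mild size variation around the mean
    jitter = rng.uniform(*config.category_size_jitter, size=n_extra)
    sizes = np.maximum(2, np.round(jitter / jitter.sum() * len(fillers)).astype(int))
    while sizes.sum() > len(fillers):
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < len(fillers):
        sizes[np.argmin(sizes)] += 1
    shuffled = list(rng.permutation(fillers))
    start = 0
    for i, size in enumerate(sizes, start=1):
        catalog[f"synthetic_function_{i:02d}"] = sorted(shuffled[start:start + size])
        start += size

    baseline = rng.normal(0.0, config.baseline_sd, size=len(genes))
    loading = np.zeros(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for g in PROLIFERATION_GENES:
        loading[idx[g]] = config.latent_loading
    return PanelModel(genes=genes, baseline=baseline, loading=loading,
                      noise_sd=config.gene_noise_sd, catalog=catalog)


def _expression(model: PanelModel, latent: np.ndarray, sample_ids: List[str],
                rng: np.random.Generator,
                mean_shift: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Log-normal expression: log x = baseline + loading * latent + noise."""
    n_genes, n = len(model.genes), latent.size
    log_x = (model.baseline[:, None]
             + model.loading[:, None] * latent[None, :]
             + rng.normal(0.0, model.noise_sd, size=(n_genes, n)))
    if mean_shift is not None:
        log_x += mean_shift[:, None]
    return pd.DataFrame(np.exp(log_x), index=pd.Index(model.genes, name="gene"),
                        columns=sample_ids)


def generate_reference(config: SimulationConfig, model: PanelModel,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Reference-population expression matrix (genes x n_reference)."""
    latent = rng.normal(0.0, 1.0, size=config.n_reference)
    ids = [f"REF{i:04d}" for i in range(1, config.n_reference + 1)]
    return _expression(model, latent, ids, rng)


def _patient_latent_params(config: SimulationConfig) -> Tuple[float, float]:
    """Mean/SD of the patient latent axis hitting the tertile targets.

    Uses the normal-quantile approximation rank ~= 100 * Phi(latent): the
    reference latent is standard normal, so a rank below 33 corresponds to
    latent below Phi^-1(0.33) etc.
    """
    p_low, p_med, _ = config.tertile_targets
    q33, q66 = norm.ppf(0.33), norm.ppf(0.66)
    z1, z2 = norm.ppf(p_low), norm.ppf(p_low + p_med)
    if not z2 > z1:
        raise ValueError("degenerate tertile targets")
    sigma = (q66 - q33) / (z2 - z1)
    mu = q33 - sigma * z1
    return mu, sigma


def _solve_strong_base(config: SimulationConfig, frac_moderate: float) -> float:
    """Base strong-positive probability so the marginal hits the target.

    Moderately proliferative patients get a logit shift on top of the
    base; the base is solved so that the mixture over the realized
    moderate fraction reproduces ``tps_strong_target``.
    """
    target, delta = config.tps_strong_target, config.strong_logit_shift_moderate
    if target in (0.0, 1.0) or delta == 0.0 or frac_moderate in (0.0,):
        return target

    def shifted(w: float) -> float:
        return 1.0 / (1.0 + math.exp(-(math.log(w / (1 - w)) + delta)))

    def gap(w: float) -> float:
        return frac_moderate * shifted(w) + (1 - frac_moderate) * w - target

    lo, hi = 1e-9, 1 - 1e-9
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("infeasible strong-prevalence target for this shift")
    return brentq(gap, lo, hi, xtol=1e-12)


def _solve_censor_max(times: np.ndarray, lower: float, alive_target: float) -> float:
    """Upper end of the uniform censoring window giving the alive fraction.

    Censoring times are Uniform(lower, c_max); patient i is alive with
    probability (c_max - T_i)+ / (c_max - lower). Solved against the mean.
    """
    if alive_target <= 0.0:
        return lower + 1e-6

    def alive_frac(c_max: float) -> float:
        width = c_max - lower
        return float(np.mean(np.clip(c_max - times, 0.0, None) / width))

    lo = lower + 1e-6
    hi = lower + 10.0 * float(np.max(times))
    if alive_frac(hi) < alive_target:
        return hi  # cannot censor more than everything; best effort
    return brentq(lambda c: alive_frac(c) - alive_target, lo, hi, xtol=1e-9)


AGE_BINS = (("<30", 20, 29), ("30-39", 30, 39), ("40-49", 40, 49),
            ("50-59", 50, 59), ("60-69", 60, 69), ("70-79", 70, 79),
            (">=80", 80, 89))
AGE_PROBS = (1 / 120, 1 / 120, 4 / 120, 28 / 120, 43 / 120, 34 / 120, 9 / 120)
RACE_LEVELS, RACE_PROBS = ("White", "Other", "Unknown"), (96 / 120, 17 / 120, 7 / 120)
AGENT_LEVELS = ("nivolumab", "pembrolizumab", "atezolizumab", "ipilimumab+nivolumab")
AGENT_PROBS = (79 / 120, 37 / 120, 2 / 120, 2 / 120)
HISTOLOGY_LEVELS = ("adenocarcinoma", "squamous", "other")


def generate_cohort(config: SimulationConfig, model: PanelModel,
                    reference_expression: pd.DataFrame,
                    rng: np.random.Generator,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical table + expression matrix for one simulated cohort.

    Returns ``(clinical, expression)``. ``n_patients`` patients pass the
    90-day eligibility window (their survival is a 90-day-shifted
    exponential per stratum, so the configured medians describe the
    eligible population the analysis actually sees); an extra
    ``early_death_fraction`` of patients die inside the window and are
    present so the exclusion logic is exercised.
    """
    n = config.n_patients
    n_extra = int(round(n * config.early_death_fraction))
    total = n + n_extra
    ids = [f"PT{i:04d}" for i in range(1, total + 1)]

    mu, sigma = _patient_latent_params(config)
    latent = rng.normal(mu, sigma, size=total)
    shift = np.zeros(len(model.genes))
    if config.cold15_fraction is not None:
        # CD8 genes are unloaded, so a cohort log-expression shift of
        # sd * (z_q - Phi^-1(target)) puts the target fraction of patients
        # below the strict cold rank cut (emulating a cold-heavy cohort)
        z_cut = norm.ppf(thresholds.cd8_cold_strict / 100.0)
        cd8_shift = model.noise_sd * (z_cut - norm.ppf(config.cold15_fraction))
        idx = {g: i for i, g in enumerate(model.genes)}
        for g in CD8_GENES:
            shift[idx[g]] = cd8_shift
    expr = _expression(model, latent, ids, rng, mean_shift=shift)

    # stratify with the actual analysis pipeline so drawn outcomes match
    # what the analysis will reconstruct
    reference = ReferencePopulation(reference_expression)
    ranks = reference.rank_samples(expr)
    prolif = stratify.proliferation_status_cohort(ranks, reference, thresholds)

    eligible = np.arange(total) < n  # first n patients are the eligible core
    frac_mod = float((prolif.iloc[:n] == "moderately").mean())
    w_base = _solve_strong_base(config, frac_mod)
    delta = config.strong_logit_shift_moderate
    logit = math.log(w_base / (1 - w_base)) if 0 < w_base < 1 else None
    p_strong = np.full(total, w_base)
    if logit is not None and delta != 0.0:
        p_strong[(prolif == "moderately").to_numpy()] = \
            1.0 / (1.0 + math.exp(-(logit + delta)))
    strong = rng.random(total) < p_strong
    w_weak = config.tps_positive_target - config.tps_strong_target
    with np.errstate(divide="ignore", invalid="ignore"):
        p_weak_given_not = np.clip(w_weak / np.maximum(1e-12, 1 - p_strong), 0, 1)
    weak = (~strong) & (rng.random(total) < p_weak_given_not)
    tps = np.zeros(total)
    tps[strong] = rng.uniform(thresholds.tps_strong, 100.0, size=int(strong.sum()))
    # keep weak TPS clear of the strong cut so rounding cannot cross it
    tps[weak] = rng.uniform(thresholds.tps_positive, thresholds.tps_strong - 0.1,
                            size=int(weak.sum()))

    # survival: shifted exponential per stratum for the eligible core
    cut = thresholds.early_exclusion_months
    medians = np.array([
        config.survival_medians[(prolif.iloc[i] == "moderately", bool(strong[i]))]
        for i in range(total)
    ])
    if (medians <= cut).any():
        raise ValueError("survival medians must exceed the 90-day window "
                         f"({cut:.3f} months)")
    death = cut + rng.exponential(scale=(medians - cut) / math.log(2), size=total)
    c_max = _solve_censor_max(death[:n], cut, config.alive_fraction)
    censor = rng.uniform(cut, c_max, size=total)
    alive = censor < death
    observed = np.minimum(death, censor)
    # extras: early deaths inside the exclusion window
    if n_extra:
        early = rng.uniform(0.3, cut - 0.05, size=n_extra)
        observed[n:] = early
        alive[n:] = False
    # response consistency below is checked against the value the clinical
    # table will actually carry (3-decimal months)
    observed = np.round(observed, 3)

    # disease control drawn per stratum, response kept consistent
    dc_p = np.array([
        config.dc_probs[(prolif.iloc[i], bool(strong[i]))] for i in range(total)
    ])
    dc = rng.random(total) < dc_p
    ne = np.zeros(total, dtype=bool)
    n_ne = int(round(n * config.not_evaluable_fraction))
    if n_ne:
        ne[rng.choice(n, size=n_ne, replace=False)] = True

    best = np.empty(total, dtype=object)
    u = rng.random(total)
    for i in range(total):
        if not eligible[i]:
            best[i] = "PD"  # excluded regardless of recorded response
        elif ne[i]:
            best[i] = "not_evaluable"
        elif dc[i]:
            if observed[i] >= thresholds.sd_dc_min_months:
                best[i] = "CR" if u[i] < 0.10 else ("PR" if u[i] < 0.55 else "SD")
            else:
                best[i] = "CR" if u[i] < 0.15 else "PR"
        else:
            if observed[i] < thresholds.sd_dc_min_months and u[i] < 0.25:
                best[i] = "SD"
            else:
                best[i] = "PD"

    inst_probs = np.full(config.n_institutions,
                         (1 - config.dominant_institution_share)
                         / (config.n_institutions - 1))
    inst_probs[0] = config.dominant_institution_share
    institutions = rng.choice(
        [f"site_{i:02d}" for i in range(1, config.n_institutions + 1)],
        p=inst_probs, size=total)

    age_idx = rng.choice(len(AGE_BINS), p=AGE_PROBS, size=total)
    age_cat = np.array([AGE_BINS[i][0] for i in age_idx])
    age_years = np.array([rng.uniform(AGE_BINS[i][1], AGE_BINS[i][2] + 1)
                          for i in age_idx])

    clinical = pd.DataFrame({
        "patient_id": ids,
        "institution": institutions,
        "age_years": np.round(age_years, 1),
        "age_category": age_cat,
        "sex": rng.choice(["F", "M"], p=(61 / 120, 59 / 120), size=total),
        "race": rng.choice(RACE_LEVELS, p=RACE_PROBS, size=total),
        "histology": rng.choice(HISTOLOGY_LEVELS, p=config.histology_probs,
                                size=total),
        "ici_agent": rng.choice(AGENT_LEVELS, p=AGENT_PROBS, size=total),
        "pd_l1_tps": np.round(tps, 1),
        "best_response": best,
        "survival_months": observed,
        "vital_status": np.where(alive, "alive", "dead"),
        "followup_months": observed,
    })
    return clinical, expr


def simulate_study(config: SimulationConfig = SimulationConfig(),
                   seed: int = 0,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS) -> SyntheticStudy:
    """Generate a complete study (reference + cohort) from one seed."""
    rng = np.random.default_rng(seed)
    model = build_panel_model(config, rng)
    ref_expr = generate_reference(config, model, rng)
    clinical, expr = generate_cohort(config, model, ref_expr, rng, thresholds)
    return SyntheticStudy(config=config, model=model,
                          reference_expression=ref_expr,
                          cohort_expression=expr, clinical=clinical,
                          catalog=model.catalog)
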