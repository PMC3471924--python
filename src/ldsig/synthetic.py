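"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes, so each downstream stage is testable without
any external accession:

* a two-strain (radiation-sensitive vs resistant), two-tissue (mammary gland,
  blood) mouse expression study across sham / low-dose (LD) / high-dose (HD)
  arms at an early and a late time point, with planted strain-baseline genes
  and dose x time x strain response genes (including "thresholded",
  "plateau" and "opposite-direction" dose-response subsets);
* a right-censored breast-cancer-style survival cohort whose hazard depends
  on a latent factor loading on the signature genes;
* a lossy mouse -> human ortholog table;
* binomial micronucleus counts with strain baselines and dose effects.

All randomness flows from one seeded :class:`numpy.random.Generator` per
call; no global state.  Defaults mirror the emulated study design: n = 4
arrays per dose group, n = 6 animals per micronucleus group, a 131-gene
systemic baseline signature, a 159-patient cohort, and micronucleus baselines
~36 % (reticulocytes) / ~57 % (normochromatic erythrocytes) higher in the
sensitive strain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionStudy, MNRecord, OrthologTable

logger = logging.getLogger("ldsig")

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_mouse_study",
    "gen_cohort",
    "gen_mn_counts",
    "gen_ortholog_table",
]


def _default_mn_baseline() -> dict:
    # rates per 10^4 cells; sensitive/resistant ratios 1.36 (RET) and 1.57 (NCE)
    return {
        "RET": {"sensitive": 27.2, "resistant": 20.0},
        "NCE": {"sensitive": 15.7, "resistant": 10.0},
    }


def _default_mn_dose_effects() -> dict:
    # multiplicative factors on the strain baseline rate, by dose and time;
    # late HD instability persists in the sensitive strain only
    return {
        "sham": {"early": {"sensitive": 1.0, "resistant": 1.0},
                 "late": {"sensitive": 1.0, "resistant": 1.0}},
        "LD": {"early": {"sensitive": 1.2, "resistant": 1.2},
               "late": {"sensitive": 1.0, "resistant": 1.0}},
        "HD": {"early": {"sensitive": 8.0, "resistant": 8.0},
               "late": {"sensitive": 3.0, "resistant": 1.0}},
        "LD+HD": {"early": {"sensitive": 8.0, "resistant": 8.0},
                  "late": {"sensitive": 3.0, "resistant": 1.0}},
    }


def _default_n_ld_response() -> dict:
    # ~4x more early LD-modulated genes in the sensitive strain
    return {"sensitive": 313, "resistant": 78}


@dataclass
class SynthConfig:
    """All knobs for the synthetic generators, with study-design defaults."""

    seed: int = 0
    # mouse expression study
    n_genes: int = 10_000
    n_reps_per_group: int = 4
    residual_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_spread: float = 1.5
    n_baseline_signature: int = 131
    baseline_effect: float = 1.0
    n_ld_response: dict = field(default_factory=_default_n_ld_response)
    n_thresholded: int = 28
    n_plateau: int = 76
    n_opposite: int = 35
    ld_effect: float = 1.0
    hd_effect: float = 1.5
    # survival cohort
    n_patients: int = 159
    n_cohort_genes: int = 1000
    cohort_loading: float = 1.0
    score_log_hr: float = math.log(2.5)
    baseline_hazard: float = 0.1
    censor_fraction: float = 0.3
    # micronucleus assay
    mn_animals_per_group: int = 6
    mn_cells_scored: dict = field(
        default_factory=lambda: {"RET": 20_000, "NCE": 20_000}
    )
    mn_baseline: dict = field(default_factory=_default_mn_baseline)
    mn_dose_effects: dict = field(default_factory=_default_mn_dose_effects)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_reps_per_group", "n_baseline_signature",
                     "n_patients", "n_cohort_genes", "mn_animals_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.n_baseline_signature > self.n_genes:
            raise ValueError("n_baseline_signature exceeds n_genes")
        for name in ("residual_sd", "baseline_effect", "ld_effect", "hd_effect",
                     "score_log_hr"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, keyed the way the recovery tests need it."""

    baseline_signature: dict[str, int] = field(default_factory=dict)
    ld_response: dict[tuple, dict[str, int]] = field(default_factory=dict)
    thresholded_genes: dict[str, int] = field(default_factory=dict)
    plateau_genes: dict[str, int] = field(default_factory=dict)
    opposite_genes: dict[str, int] = field(default_factory=dict)
    cohort_signature_genes: list[str] = field(default_factory=list)
    cohort_linear_predictor: np.ndarray | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"Sg{i:05d}" for i in range(n)]


def gen_mouse_study(config: SynthConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate the two-strain, two-tissue irradiation expression study.

    Independent normal residuals (``residual_sd``, log2 units) around a
    per-gene baseline.  Baseline-signature genes carry a strain offset of
    ``+/- baseline_effect`` (sensitive minus resistant) concordantly in both
    tissues and all arms.  Response genes carry dose x time x strain offsets
    in the mammary gland: per-strain plain LD responders at each time point,
    plus a thresholded subset (HD in both strains, LD only in the sensitive
    strain), a plateau subset (equal LD and HD effects) and an
    opposite-direction subset (LD and HD signs opposed), all at the early
    time point in the sensitive strain.
    """
    rng = np.random.default_rng([config.seed, 101])
    genes = _gene_ids(config.n_genes)
    n_special = (
        config.n_baseline_signature
        + sum(config.n_ld_response.values()) * 2
        + config.n_thresholded
        + config.n_plateau
        + config.n_opposite
    )
    if n_special > config.n_genes:
        raise ValueError(
            f"planted gene blocks ({n_special}) exceed n_genes ({config.n_genes})"
        )

    meta_rows = []
    for strain in ("sensitive", "resistant"):
        for tissue in ("mammary", "blood"):
            for dose in ("sham", "LD", "HD"):
                for time in ("early", "late"):
                    for rep in range(1, config.n_reps_per_group + 1):
                        meta_rows.append(
                            {
                                "sample_id": f"{strain[:3]}_{tissue[:2]}_{dose}_{time}_r{rep}",
                                "strain": strain,
                                "tissue": tissue,
                                "dose": dose,
                                "time": time,
                                "replicate": rep,
                            }
                        )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    n_samples = len(meta)

    base = rng.normal(config.baseline_mean, config.baseline_spread, config.n_genes)
    values = base[:, None] + rng.normal(
        0.0, config.residual_sd, (config.n_genes, n_samples)
    )

    strain_col = meta["strain"].to_numpy()
    tissue_col = meta["tissue"].to_numpy()
    dose_col = meta["dose"].to_numpy()
    time_col = meta["time"].to_numpy()
    is_sensitive = strain_col == "sensitive"
    is_mg = tissue_col == "mammary"

    truth = GroundTruth()
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    # systemic baseline signature: strain offset, both tissues, every arm
    idx = take(config.n_baseline_signature)
    signs = rng.choice([-1, 1], size=len(idx))
    values[np.ix_(idx, is_sensitive.nonzero()[0])] += (
        signs[:, None] * config.baseline_effect
    )
    truth.baseline_signature = {genes[i]: int(s) for i, s in zip(idx, signs)}

    # plain LD responders per strain and time point (mammary gland only)
    for strain in ("sensitive", "resistant"):
        for time in ("early", "late"):
            n_resp = int(config.n_ld_response.get(strain, 0))
            idx = take(n_resp)
            signs = rng.choice([-1, 1], size=len(idx))
            cols = (is_mg & (strain_col == strain) & (dose_col == "LD")
                    & (time_col == time)).nonzero()[0]
            values[np.ix_(idx, cols)] += signs[:, None] * config.ld_effect
            truth.ld_response[(strain, "LD", time)] = {
                genes[i]: int(s) for i, s in zip(idx, signs)
            }

    def _plant(idx, signs, strain, dose, time, effect):
        cols = (is_mg & (strain_col == strain) & (dose_col == dose)
                & (time_col == time)).nonzero()[0]
        values[np.ix_(idx, cols)] += signs[:, None] * effect

    # thresholded: HD response in both strains, LD only in the sensitive strain
    idx = take(config.n_thresholded)
    signs = rng.choice([-1, 1], size=len(idx))
    _plant(idx, signs, "sensitive", "LD", "early", config.ld_effect)
    _plant(idx, signs, "sensitive", "HD", "early", config.hd_effect)
    _plant(idx, signs, "resistant", "HD", "early", config.hd_effect)
    truth.thresholded_genes = {genes[i]: int(s) for i, s in zip(idx, signs)}

    # plateau: LD and HD effects equal in the sensitive strain
    idx = take(config.n_plateau)
    signs = rng.choice([-1, 1], size=len(idx))
    _plant(idx, signs, "sensitive", "LD", "early", config.ld_effect)
    _plant(idx, signs, "sensitive", "HD", "early", config.ld_effect)
    truth.plateau_genes = {genes[i]: int(s) for i, s in zip(idx, signs)}

    # opposite: LD and HD responses with opposing signs in the sensitive strain
    idx = take(config.n_opposite)
    signs = rng.choice([-1, 1], size=len(idx))
    _plant(idx, signs, "sensitive", "LD", "early", config.ld_effect)
    _plant(idx, -signs, "sensitive", "HD", "early", config.hd_effect)
    truth.opposite_genes = {genes[i]: int(s) for i, s in zip(idx, signs)}

    study = ExpressionStudy(gene_ids=genes, values=values, sample_meta=meta)
    logger.info(
        "gen_mouse_study: seed=%s genes=%d samples=%d planted=%d",
        config.seed, config.n_genes, n_samples, cursor,
    )
    return study, truth


def gen_cohort(
    config: SynthConfig,
    signature: Sequence[str],
    background_genes: Sequence[str] = (),
):
    """Simulate a right-censored survival cohort driven by a signature score.

    Each patient carries a standard-normal latent factor ``u``; signature
    genes read ``cohort_loading * u`` plus unit noise, background genes are
    standard normal.  Event times are exponential with log-hazard
    ``score_log_hr * z(u)``; censoring is independent uniform with its upper
    bound calibrated so the expected censored fraction matches
    ``censor_fraction``.  ``background_genes`` adds named genes with no
    loading (e.g. a negative-control signature) alongside the anonymous
    background fillers.
    """
    from .survival import SurvivalCohort

    if len(signature) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng([config.seed, 202])
    sig = list(dict.fromkeys(signature))
    named_bg = [g for g in dict.fromkeys(background_genes) if g not in set(sig)]
    n_bg = max(config.n_cohort_genes - len(sig) - len(named_bg), 0)
    bg = named_bg + [f"BG{i:05d}" for i in range(n_bg)]
    gene_ids = sig + bg
    n = config.n_patients

    u = rng.normal(size=n)
    expr = rng.normal(size=(len(gene_ids), n))
    expr[: len(sig)] += config.cohort_loading * u[None, :]

    z = (u - u.mean()) / u.std(ddof=0)
    linpred = config.score_log_hr * z
    hazard = config.baseline_hazard * np.exp(linpred)
    t_event = rng.exponential(1.0 / hazard)

    if config.censor_fraction > 0:
        tmax = _calibrate_uniform_censoring(t_event, config.censor_fraction)
        c = rng.uniform(0.0, tmax, size=n)
        time = np.minimum(t_event, c)
        event = t_event <= c
    else:
        time = t_event
        event = np.ones(n, dtype=bool)

    cohort = SurvivalCohort(
        patient_ids=[f"P{i:04d}" for i in range(n)],
        gene_ids=gene_ids,
        expression=expr,
        time=time,
        event=event,
    )
    truth = GroundTruth(
        cohort_signature_genes=sig,
        cohort_linear_predictor=linpred,
    )
    logger.info(
        "gen_cohort: seed=%s patients=%d signature=%d censored=%.2f",
        config.seed, n, len(sig), 1 - event.mean(),
    )
    return cohort, truth


def _calibrate_uniform_censoring(t_event: np.ndarray, target: float) -> float:
    """Upper bound of a U(0, tmax) censoring law giving expected censored
    fraction ``target`` for the drawn event times (bisection)."""

    def frac(tmax: float) -> float:
        return float(np.mean(np.minimum(t_event / tmax, 1.0)))

    lo, hi = 1e-9, float(t_event.max()) * 10
    # frac is decreasing in tmax; expand hi until below target
    while frac(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_mn_counts(config: SynthConfig) -> list[MNRecord]:
    """Simulate per-animal micronucleus counts.

    ``mn_cells ~ Binomial(cells_scored, rate)`` with the per-10^4 rate set by
    strain baseline times the dose x time multiplier.
    """
    rng = np.random.default_rng([config.seed, 303])
    records: list[MNRecord] = []
    for cell_class, per_strain in config.mn_baseline.items():
        scored = int(config.mn_cells_scored[cell_class])
        for strain, base_rate in per_strain.items():
            for dose, per_time in config.mn_dose_effects.items():
                for time_point, per_strain_mult in per_time.items():
                    rate = base_rate * per_strain_mult[strain] / 1e4
                    if not 0 <= rate <= 1:
                        raise ValueError(
                            f"MN rate {rate} outside [0, 1] for "
                            f"{cell_class}/{strain}/{dose}/{time_point}"
                        )
                    counts = rng.binomial(scored, rate, config.mn_animals_per_group)
                    for k, cnt in enumerate(counts, start=1):
                        records.append(
                            MNRecord(
                                animal_id=f"{strain[:3]}_{dose}_{time_point}_a{k}",
                                strain=strain,
                                dose=dose,
                                time_point=time_point,
                                cell_class=cell_class,
                                cells_scored=scored,
                                mn_cells=int(cnt),
                            )
                        )
    return records


def gen_ortholog_table(
    genes: Sequence[str], drop_fraction: float, seed: int = 0
) -> OrthologTable:
    """Map each retained mouse symbol to its upper-cased human symbol,
    randomly dropping a ``drop_fraction`` of genes (lossy orthology)."""
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    rng = np.random.default_rng([seed, 404])
    keep = rng.random(len(genes)) >= drop_fraction
    pairs = {g: [g.upper()] for g, k in zip(genes, keep) if k}
    return OrthologTable(pairs=pairs)
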