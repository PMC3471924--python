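"""Signature sum-scores, median split, Kaplan-Meier and log-rank, COA genes.

The survival association chain: per-patient sum of (normalized) signature-gene
expression -> dichotomize at the cohort median -> Kaplan-Meier disease-free
survival per group -> two-group log-rank test -> per-gene refinement of the
signature into cancer-outcome-associated (COA) genes (Welch t between the
above- and below-median patient groups at alpha = 0.01), with the
inverse-direction subset (lower expression in the above-median group)
exported as a directed sub-signature.

The product-limit estimator and the log-rank statistic (observed minus
expected events with hypergeometric variance at tied event times) are
implemented here directly so tie handling and small-sample behaviour are
auditable against permutation oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ldsig")

__all__ = [
    "SurvivalCohort",
    "ScoreSplit",
    "KMCurve",
    "LogRankResult",
    "COAResult",
    "signature_score",
    "median_split",
    "km_estimate",
    "logrank_test",
    "coa_refine",
    "survival_pipeline",
    "plot_km",
]


@dataclass
class SurvivalCohort:
    """Patient x gene expression with right-censored follow-up."""

    patient_ids: list[str]
    gene_ids: list[str]
    expression: np.ndarray  # genes x patients, normalized intensity units
    time: np.ndarray  # follow-up, arbitrary time units
    event: np.ndarray  # True = disease event/death, False = censored

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.patient_ids)
        if self.expression.shape != (len(self.gene_ids), n):
            raise ValueError(
                f"expression shape {self.expression.shape} does not match "
                f"{len(self.gene_ids)} genes x {n} patients"
            )
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event length does not match patient count")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def signature_score(
    cohort: SurvivalCohort,
    genes,
    directions=None,
    normalization: str = "zscore",
) -> np.ndarray:
    """Per-patient signature sum-score.

    ``zscore`` mode standardizes each gene across patients before summing
    (constant genes contribute 0, with a warning); ``raw`` sums the stored
    intensities.  ``directions`` (gene -> sign) multiplies each gene's
    contribution by +/-1; a 0 sign counts as +1.  Genes absent from the
    cohort are logged and skipped; an entirely missing signature is an error.
    """
    if normalization not in ("zscore", "raw"):
        raise ValueError("normalization must be 'zscore' or 'raw'")
    index = {g: i for i, g in enumerate(cohort.gene_ids)}
    rows, signs = [], []
    missing = []
    for g in genes:
        if g not in index:
            missing.append(g)
            continue
        rows.append(index[g])
        s = 1
        if directions is not None:
            s = int(directions.get(g, 1)) or 1
        signs.append(s)
    if missing:
        logger.warning("signature_score: %d gene(s) missing from cohort: %s%s",
                       len(missing), missing[:5], "..." if len(missing) > 5 else "")
    if not rows:
        raise ValueError("all requested signature genes missing from cohort")
    sub = cohort.expression[rows]
    if normalization == "zscore":
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        const = (sd == 0).ravel()
        if const.any():
            logger.warning("signature_score: %d constant gene(s) contribute 0",
                           const.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = np.where(sd == 0, 0.0, (sub - mean) / sd)
    return (np.asarray(signs, dtype=float)[:, None] * sub).sum(axis=0)


@dataclass
class ScoreSplit:
    """A median dichotomization of per-patient scores (ties go below)."""

    score: np.ndarray
    above: np.ndarray  # boolean per patient
    cut: float

    @property
    def n_above(self) -> int:
        return int(self.above.sum())

    @property
    def n_below(self) -> int:
        return int((~self.above).sum())


def median_split(scores) -> ScoreSplit:
    """Dichotomize at the sample median; strictly greater goes above."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 patients")
    if np.all(scores == scores[0]):
        raise ValueError("all scores identical; median split undefined")
    cut = float(np.median(scores))
    return ScoreSplit(score=scores, above=scores > cut, cut=cut)


@dataclass
class KMCurve:
    """Product-limit survival estimate tabulated at distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored exactly at an event time are counted at risk at that
    time (the standard convention: the risk set at t is everyone with
    follow-up >= t).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) != len(event):
        raise ValueError("time and event lengths differ")
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    etimes = np.unique(time[event])
    surv, risk, ev = [], [], []
    s = 1.0
    for t in etimes:
        n = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / n
        surv.append(s)
        risk.append(n)
        ev.append(d)
    return KMCurve(
        event_times=etimes,
        survival=np.asarray(surv),
        at_risk=np.asarray(risk, dtype=int),
        n_events=np.asarray(ev, dtype=int),
    )


@dataclass
class LogRankResult:
    chi_sq: float
    p_value: float
    df: int = 1
    flagged: str | None = None


def logrank_test(group1, group2) -> LogRankResult:
    """Two-group log-rank test.

    ``group1`` / ``group2`` are ``(time, event)`` pairs.  Observed minus
    expected events are summed over distinct event times with the
    hypergeometric variance (exact under tied events); p from chi-square
    with 1 df.  Zero events overall returns p = 1, flagged.
    """
    t1, e1 = (np.asarray(a) for a in group1)
    t2, e2 = (np.asarray(a) for a in group2)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be non-empty")
    e1 = e1.astype(bool)
    e2 = e2.astype(bool)
    time = np.concatenate([t1, t2]).astype(float)
    event = np.concatenate([e1, e2])
    in1 = np.concatenate([np.ones(len(t1), bool), np.zeros(len(t2), bool)])
    etimes = np.unique(time[event])
    if len(etimes) == 0:
        logger.warning("logrank_test: no events in either group")
        return LogRankResult(chi_sq=0.0, p_value=1.0, flagged="no events")
    o_minus_e = 0.0
    var = 0.0
    for t in etimes:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        dying = (time == t) & event
        d = int(dying.sum())
        d1 = int((dying & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        logger.warning("logrank_test: zero variance (degenerate risk sets)")
        return LogRankResult(chi_sq=0.0, p_value=1.0, flagged="zero variance")
    chi = o_minus_e**2 / var
    return LogRankResult(chi_sq=float(chi), p_value=float(stats.chi2.sf(chi, 1)))


@dataclass
class COAResult:
    """Per-gene above- vs below-median t-tests over a signature.

    ``table`` has one row per tested gene: ``gene, t_stat, p_value,
    direction`` (``higher_in_above`` / ``lower_in_above``) and a boolean
    ``coa`` flag for ``p < alpha``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def coa_genes(self) -> list[str]:
        return self.table.loc[self.table["coa"], "gene"].tolist()

    @property
    def inverse_genes(self) -> list[str]:
        sel = self.table["coa"] & (self.table["direction"] == "lower_in_above")
        return self.table.loc[sel, "gene"].tolist()

    def directed_subsignature(self) -> dict[str, int]:
        """COA genes signed so each contributes in its risk direction."""
        sel = self.table[self.table["coa"]]
        return {
            g: (1 if d == "higher_in_above" else -1)
            for g, d in zip(sel["gene"], sel["direction"])
        }


def coa_refine(
    cohort: SurvivalCohort, split: ScoreSplit, genes, alpha: float = 0.01
) -> COAResult:
    """Refine a signature to its cancer-outcome-associated (COA) genes.

    Per-gene Welch t between the above- and below-median patient groups;
    genes with p < alpha are flagged COA, with direction from the sign of
    mean(above) - mean(below).
    """
    if len(split.score) != cohort.n_patients:
        raise ValueError("split does not match cohort size")
    if split.n_above < 2 or split.n_below < 2:
        raise ValueError("each patient group needs at least 2 members")
    index = {g: i for i, g in enumerate(cohort.gene_ids)}
    present = [g for g in genes if g in index]
    rows = [index[g] for g in present]
    sub = cohort.expression[rows]
    a = sub[:, split.above]
    b = sub[:, ~split.above]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.nan_to_num(np.asarray(res.statistic, float), nan=0.0)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    diff = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": present,
            "t_stat": t,
            "p_value": p,
            "direction": np.where(diff >= 0, "higher_in_above", "lower_in_above"),
            "coa": p < alpha,
        }
    )
    return COAResult(table=table, alpha=alpha)


def survival_pipeline(
    cohort: SurvivalCohort,
    mouse_signature,
    ortholog_table,
    directions=None,
    normalization: str = "zscore",
    coa_alpha: float = 0.01,
) -> dict:
    """Run the full survival-association chain on one cohort.

    Maps the mouse signature to human space, scores patients, splits at the
    median, estimates KM per group, log-rank tests the split, refines the
    signature to COA genes, and re-tests the directed COA sub-signature
    (inverse genes weighted -1).  Returns a report dict.
    """
    from .orthologs import map_signature

    mapped = map_signature(mouse_signature, ortholog_table, directions=directions)
    score = signature_score(cohort, mapped.human_genes, normalization=normalization)
    split = median_split(score)
    above = (cohort.time[split.above], cohort.event[split.above])
    below = (cohort.time[~split.above], cohort.event[~split.above])
    km_above = km_estimate(*above)
    km_below = km_estimate(*below)
    lr = logrank_test(above, below)
    coa = coa_refine(cohort, split, mapped.human_genes, alpha=coa_alpha)

    directed = coa.directed_subsignature()
    directed_report = None
    if directed:
        d_score = signature_score(
            cohort, list(directed), directions=directed, normalization=normalization
        )
        d_split = median_split(d_score)
        d_lr = logrank_test(
            (cohort.time[d_split.above], cohort.event[d_split.above]),
            (cohort.time[~d_split.above], cohort.event[~d_split.above]),
        )
        directed_report = {"n_genes": len(directed), "logrank": d_lr}

    inverse_report = None
    if coa.inverse_genes:
        inv = {g: -1 for g in coa.inverse_genes}
        i_score = signature_score(
            cohort, coa.inverse_genes, directions=inv, normalization=normalization
        )
        i_split = median_split(i_score)
        i_lr = logrank_test(
            (cohort.time[i_split.above], cohort.event[i_split.above]),
            (cohort.time[~i_split.above], cohort.event[~i_split.above]),
        )
        inverse_report = {"n_genes": len(inv), "logrank": i_lr}

    logger.info(
        "survival_pipeline: %d human genes (%d dropped), log-rank p=%.3g, "
        "%d COA (%d inverse), normalization=%s",
        len(mapped.human_genes), len(mapped.dropped), lr.p_value,
        len(coa.coa_genes), len(coa.inverse_genes), normalization,
    )
    return {
        "mapped": mapped,
        "score": score,
        "split": split,
        "km_above": km_above,
        "km_below": km_below,
        "logrank": lr,
        "coa": coa,
        "directed_subset": directed_report,
        "inverse_subset": inverse_report,
        "normalization": normalization,
    }


def plot_km(curves: dict[str, KMCurve], path=None):  # pragma: no cover - thin plotting
    """Step-plot one or more KM curves; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for label, km in curves.items():
        x = np.concatenate([[0.0], km.event_times])
        y = np.concatenate([[1.0], km.survival])
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
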