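"""Per-gene two-group statistics, graded gene lists, and dose-response classes.

All two-group contrasts use the unequal-variance (Welch) t-test on log2
intensities.  Gene lists use the graded criteria: absolute fold change >= 1.5
(|log2 fc| >= log2 1.5) with p <= 0.01 for high-dose contrasts, p <= 0.1 for
low-dose contrasts, and p <= 0.05 for strain-baseline contrasts.  No multiple
testing correction enters list membership; Benjamini-Hochberg q-values are
reported alongside for information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ldsig")

FC_CUT = float(np.log2(1.5))
P_CUTOFFS = {"HD": 0.01, "LD": 0.1, "baseline": 0.05}

__all__ = [
    "FC_CUT",
    "P_CUTOFFS",
    "GeneLists",
    "welch_t",
    "contrast",
    "gene_list",
    "classify_dose_response",
    "classify_calls",
    "magnitude_comparison",
]


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sided Welch t-test.

    Returns ``(t_stat, df, p_value)`` with Welch-Satterthwaite degrees of
    freedom.  If both groups have zero variance and equal means, ``(0, df,
    1)`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        df = float(len(x) + len(y) - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def contrast(study, group_a, group_b) -> pd.DataFrame:
    """Per-gene Welch contrast between two disjoint sample groups.

    ``group_a`` / ``group_b`` are either boolean sample masks or factor-filter
    dicts passed to :meth:`ExpressionStudy.select`.  ``log2_fc`` is
    mean(A) - mean(B) on the stored log2 scale.  Returns one row per gene
    with columns ``gene, log2_fc, t_stat, p_value, q_value, direction``.
    """
    mask_a = study.select(**group_a) if isinstance(group_a, dict) else np.asarray(group_a, bool)
    mask_b = study.select(**group_b) if isinstance(group_b, dict) else np.asarray(group_b, bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("empty sample selection")
    if (mask_a & mask_b).any():
        raise ValueError("overlapping sample selections")
    a = study.values[:, mask_a]
    b = study.values[:, mask_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    fc = a.mean(axis=1) - b.mean(axis=1)
    # zero variance in both groups: p = 1 when means agree, p -> 0 otherwise
    degen = ~np.isfinite(t)
    if degen.any():
        logger.warning("contrast: %d gene(s) with zero variance in both groups", degen.sum())
        t = np.where(degen, np.where(fc == 0, 0.0, np.sign(fc) * np.inf), t)
        p = np.where(degen, np.where(fc == 0, 1.0, 0.0), p)
    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0))
    return pd.DataFrame(
        {
            "gene": study.gene_ids,
            "log2_fc": fc,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "direction": np.sign(fc).astype(int),
        }
    )


@dataclass
class GeneLists:
    """A graded gene list partitioned by direction of change."""

    up: list[str]
    down: list[str]
    p_cutoff: float
    fc_cutoff: float

    @property
    def all(self) -> list[str]:
        return self.up + self.down

    def directions(self) -> dict[str, int]:
        return {**{g: 1 for g in self.up}, **{g: -1 for g in self.down}}


def gene_list(
    contrasts: pd.DataFrame,
    dose: str,
    p_cutoff: float | None = None,
    fc_cutoff: float = FC_CUT,
) -> GeneLists:
    """Apply the graded list criteria to a contrast table.

    ``dose`` selects the p cutoff (HD -> 0.01, LD -> 0.1, baseline -> 0.05)
    unless ``p_cutoff`` overrides it.
    """
    if p_cutoff is None:
        try:
            p_cutoff = P_CUTOFFS[dose]
        except KeyError:
            raise ValueError(f"unknown dose class {dose!r}; expected {sorted(P_CUTOFFS)}") from None
    hit = (contrasts["p_value"] <= p_cutoff) & (contrasts["log2_fc"].abs() >= fc_cutoff)
    up = contrasts.loc[hit & (contrasts["log2_fc"] > 0), "gene"].tolist()
    down = contrasts.loc[hit & (contrasts["log2_fc"] < 0), "gene"].tolist()
    return GeneLists(up=up, down=down, p_cutoff=p_cutoff, fc_cutoff=fc_cutoff)


def classify_calls(
    fc: dict[str, float], sig: dict[str, bool]
) -> str:
    """Classify one gene's dose-response pattern from its four per-condition
    fold changes and significance flags.

    Keys of both dicts: ``ld_sensitive, hd_sensitive, ld_resistant,
    hd_resistant``.  Classes, checked in order:

    * ``thresholded`` — significant HD response with the same sign in both
      strains, LD significant in the sensitive strain only;
    * ``plateau`` — within either strain, LD and HD significant with the same
      sign and |fc| ratio inside [2/3, 3/2];
    * ``opposite`` — within either strain, LD and HD significant with
      opposing signs;
    * ``other`` — remainder.
    """
    ls, hs = fc["ld_sensitive"], fc["hd_sensitive"]
    lr, hr = fc["ld_resistant"], fc["hd_resistant"]
    s_ls, s_hs = sig["ld_sensitive"], sig["hd_sensitive"]
    s_lr, s_hr = sig["ld_resistant"], sig["hd_resistant"]

    if s_hs and s_hr and np.sign(hs) == np.sign(hr) != 0 and s_ls and not s_lr:
        return "thresholded"
    for ld, hd, s_ld, s_hd in ((ls, hs, s_ls, s_hs), (lr, hr, s_lr, s_hr)):
        if s_ld and s_hd and np.sign(ld) == np.sign(hd) != 0:
            ratio = abs(ld) / abs(hd) if hd != 0 else np.inf
            if 2 / 3 <= ratio <= 3 / 2:
                return "plateau"
    for ld, hd, s_ld, s_hd in ((ls, hs, s_ls, s_hs), (lr, hr, s_lr, s_hr)):
        if s_ld and s_hd and np.sign(ld) == -np.sign(hd) != 0:
            return "opposite"
    return "other"


_CONDITIONS = ("ld_sensitive", "hd_sensitive", "ld_resistant", "hd_resistant")


def classify_dose_response(contrasts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Classify every gene's dose-response nonlinearity pattern.

    ``contrasts`` maps each of ``ld_sensitive, hd_sensitive, ld_resistant,
    hd_resistant`` to a :func:`contrast` table over the same gene universe
    (dose-vs-sham within one strain at one time point).  Significance uses
    the dose-appropriate graded criteria (LD cutoff for LD conditions, HD
    cutoff for HD conditions, fold-change 1.5 everywhere).  The returned
    frame stores the per-condition fold changes and flags, so every class is
    re-derivable from its own row.
    """
    missing = [c for c in _CONDITIONS if c not in contrasts]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")
    genes = contrasts["ld_sensitive"]["gene"].tolist()
    frames = {}
    for cond in _CONDITIONS:
        df = contrasts[cond]
        if df["gene"].tolist() != genes:
            raise ValueError(f"condition {cond!r} covers a different gene universe")
        cutoff = P_CUTOFFS["LD" if cond.startswith("ld") else "HD"]
        frames[cond] = pd.DataFrame(
            {
                f"fc_{cond}": df["log2_fc"].to_numpy(),
                f"sig_{cond}": (
                    (df["p_value"].to_numpy() <= cutoff)
                    & (np.abs(df["log2_fc"].to_numpy()) >= FC_CUT)
                ),
            }
        )
    out = pd.concat([pd.DataFrame({"gene": genes}), *frames.values()], axis=1)
    out["dose_class"] = [
        classify_calls(
            {c: row[f"fc_{c}"] for c in _CONDITIONS},
            {c: bool(row[f"sig_{c}"]) for c in _CONDITIONS},
        )
        for row in out.to_dict("records")
    ]
    return out


def magnitude_comparison(values_a, values_b, paired: bool = True) -> float:
    """Two-sided t-test comparing response magnitudes (|log2 fc| vectors).

    Paired by default (same gene set in both conditions); identical vectors
    return p = 1.
    """
    a = np.abs(np.asarray(values_a, dtype=float))
    b = np.abs(np.asarray(values_b, dtype=float))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length vectors")
        if np.array_equal(a, b):
            return 1.0
        return float(stats.ttest_rel(a, b).pvalue)
    if np.array_equal(a, b):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
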