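"""Micronucleus-assay statistics.

Per-animal micronucleus frequencies (MN cells per 10^4 cells scored),
baseline strain comparison by unequal-variance t-test, and dose-group
comparisons against the sham control by one-way ANOVA with Dunnett
adjustment.  The Dunnett family-wise reference distribution (the maximum of
equicorrelated t variates) is evaluated by seeded Monte Carlo rather than
from printed tables, so it is testable against resampling oracles and
handles unbalanced designs through the exact pairwise correlations
``rho_ij = sqrt(n_i n_j / ((n_i + n_c)(n_j + n_c)))``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import MNRecord
from .de import welch_t

logger = logging.getLogger("ldsig")

__all__ = ["mn_frequencies", "baseline_compare", "dunnett_vs_control"]


def mn_frequencies(records: Sequence[MNRecord], arcsine: bool = False) -> pd.DataFrame:
    """Per-animal MN frequencies, ``1e4 * mn_cells / cells_scored``.

    With ``arcsine=True`` an arcsine-square-root transformed proportion is
    added (off by default; frequencies are analyzed untransformed on the
    per-10^4 scale).
    """
    rows = []
    for r in records:
        prop = r.mn_cells / r.cells_scored
        row = {
            "animal_id": r.animal_id,
            "strain": r.strain,
            "dose": r.dose,
            "time_point": r.time_point,
            "cell_class": r.cell_class,
            "freq": 1e4 * prop,
        }
        if arcsine:
            row["arcsine"] = float(np.arcsin(np.sqrt(prop)))
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_compare(freqs_a, freqs_b) -> dict:
    """Percent difference of group means (A relative to B) with a Welch p.

    ``percent_diff = 100 * (mean_a - mean_b) / mean_b``.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 animals")
    if b.mean() == 0:
        raise ValueError("reference group mean is zero; percent difference undefined")
    _, _, p = welch_t(a, b)
    return {"percent_diff": float(100 * (a.mean() - b.mean()) / b.mean()), "p_value": p}


def dunnett_vs_control(
    groups: Sequence[Sequence[float]],
    control: Sequence[float],
    n_mc: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided Dunnett many-to-one comparisons against a control.

    Per-comparison t statistics use the pooled ANOVA mean-squared error over
    all groups; each family-wise adjusted p-value is
    ``P(max_j |T_j| >= |t_i|)`` under the joint null, where ``(T_1..T_k)``
    follow the equicorrelated multivariate t reference distribution,
    evaluated by ``n_mc`` seeded Monte-Carlo draws.  Adjusted p-values are
    never below the per-comparison p.
    """
    control = np.asarray(control, dtype=float)
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) == 0:
        raise ValueError("need at least one treatment group")
    if len(control) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 observations")
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    nc = len(control)
    df = int(nc + ns.sum() - (k + 1))
    sse = ((control - control.mean()) ** 2).sum() + sum(
        ((g - g.mean()) ** 2).sum() for g in gs
    )
    mse = sse / df
    if mse == 0:
        # all observations identical within groups: any mean difference is exact
        diffs = np.array([g.mean() - control.mean() for g in gs])
        return np.where(diffs == 0, 1.0, 0.0)
    t_obs = np.array(
        [(g.mean() - control.mean()) / np.sqrt(mse * (1 / len(g) + 1 / nc)) for g in gs]
    )

    # joint null: T_i = (Z_i - lam_i * Z_0-like shared term) / sqrt(W/df) via
    # the standard representation with correlation sqrt(n_i n_j /((n_i+nc)(n_j+nc)))
    lam = np.sqrt(ns / (ns + nc))
    rng = np.random.default_rng([seed, 505])
    z0 = rng.standard_normal(n_mc)
    zi = rng.standard_normal((n_mc, k))
    zmat = np.sqrt(1 - lam**2) * zi - lam * z0[:, None]  # equicorrelated normals
    w = rng.chisquare(df, n_mc)
    tmat = zmat / np.sqrt(w / df)[:, None]
    max_abs = np.abs(tmat).max(axis=1)

    from scipy import stats as _st

    adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    raw = 2 * _st.t.sf(np.abs(t_obs), df)
    return np.maximum(adj, raw)
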