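"""Cross-tissue "systemic" strain signature and its negative control.

A gene enters the systemic baseline signature when it is differentially
expressed between the sensitive and resistant strain in *both* blood and
mammary gland, with the same sign of change in both tissues.  Ratios are
oriented sensitive minus resistant.  The squared Pearson correlation of the
qualifying genes' blood vs mammary log-ratios is reported descriptively.

The negative control takes the genes *least* differentially expressed in
both tissues (smallest worst-tissue |log2 fc|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import FC_CUT

logger = logging.getLogger("ldsig")

__all__ = ["SystemicSignature", "derive_systemic_signature", "negative_control_signature"]


@dataclass
class SystemicSignature:
    """Qualifying genes with per-tissue log-ratios and the descriptive r^2.

    ``genes`` has columns ``gene, blood_log2_ratio, mg_log2_ratio,
    direction``; ``r_squared`` is NaN (flagged) when fewer than 3 genes
    qualify.
    """

    genes: pd.DataFrame
    r_squared: float

    @property
    def symbols(self) -> list[str]:
        return self.genes["gene"].tolist()

    def directions(self) -> dict[str, int]:
        return dict(zip(self.genes["gene"], self.genes["direction"]))


def derive_systemic_signature(
    blood: pd.DataFrame,
    mg: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = FC_CUT,
) -> SystemicSignature:
    """Derive the systemic baseline signature from per-tissue strain contrasts.

    ``blood`` and ``mg`` are :func:`ldsig.de.contrast` tables over the same
    gene universe (sensitive minus resistant).  A gene qualifies iff it
    passes ``p <= p_cut`` and ``|log2_fc| >= fc_cut`` in both tissues with
    the same sign.
    """
    if blood["gene"].tolist() != mg["gene"].tolist():
        raise ValueError("blood and mammary contrasts cover different gene universes")
    b_fc = blood["log2_fc"].to_numpy()
    m_fc = mg["log2_fc"].to_numpy()
    qual = (
        (blood["p_value"].to_numpy() <= p_cut)
        & (mg["p_value"].to_numpy() <= p_cut)
        & (np.abs(b_fc) >= fc_cut)
        & (np.abs(m_fc) >= fc_cut)
        & (np.sign(b_fc) == np.sign(m_fc))
        & (np.sign(b_fc) != 0)
    )
    genes = pd.DataFrame(
        {
            "gene": blood.loc[qual, "gene"].to_numpy(),
            "blood_log2_ratio": b_fc[qual],
            "mg_log2_ratio": m_fc[qual],
            "direction": np.sign(b_fc[qual]).astype(int),
        }
    )
    if len(genes) < 3:
        logger.warning(
            "systemic signature: only %d qualifying gene(s); r^2 undefined", len(genes)
        )
        r2 = float("nan")
    elif np.allclose(np.std(genes["blood_log2_ratio"]), 0) or np.allclose(
        np.std(genes["mg_log2_ratio"]), 0
    ):
        r2 = float("nan")
    else:
        r = stats.pearsonr(genes["blood_log2_ratio"], genes["mg_log2_ratio"]).statistic
        r2 = float(r * r)
    return SystemicSignature(genes=genes, r_squared=r2)


def negative_control_signature(blood: pd.DataFrame, mg: pd.DataFrame, k: int) -> list[str]:
    """The k genes least differentially expressed in both tissues.

    Ranks genes by ``max(|blood log2_fc|, |mg log2_fc|)`` ascending; ties
    broken by larger min p-value, then lexicographic symbol.
    """
    if blood["gene"].tolist() != mg["gene"].tolist():
        raise ValueError("blood and mammary contrasts cover different gene universes")
    if k > len(blood):
        raise ValueError(f"k={k} exceeds gene universe size {len(blood)}")
    rank = pd.DataFrame(
        {
            "gene": blood["gene"].to_numpy(),
            "worst_fc": np.maximum(
                blood["log2_fc"].abs().to_numpy(), mg["log2_fc"].abs().to_numpy()
            ),
            "neg_min_p": -np.minimum(
                blood["p_value"].to_numpy(), mg["p_value"].to_numpy()
            ),
        }
    )
    rank = rank.sort_values(["worst_fc", "neg_min_p", "gene"], kind="mergesort")
    return rank["gene"].head(k).tolist()
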