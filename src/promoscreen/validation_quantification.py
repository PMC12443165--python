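"""Single-vector validation arithmetic: dCt expression, ddPCR dose, Q scores.

In the validation cohort each promoter construct is injected alone, so
barcode counting is replaced by per-sample qPCR/ddPCR:

* relative expression  C = 2^-(Ct_target - Ct_housekeeper), technical
  duplicates averaged on the Ct (log) scale;
* vector dose          G = eyfp copies / (Rpp30 copies / 2), i.e. vector
  genomes per diploid genome (Rpp30 is a two-copy autosomal gene);
* normalized expression Q = C / G, expression per delivered vector copy.

Efficiency and specificity scores are computed from Q exactly as the
library screen computes them from R, except that the replicate structure
differs: each promoter has its own animals, so specificity is computed
per animal while efficiency uses the per-promoter mean Q* across the
replicate animals of each construct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .screen_quantification import ScoreMatrix

logger = logging.getLogger("promoscreen")


@dataclass(frozen=True)
class QpcrResult:
    """Outcome of one dCt computation."""

    c: float  # 2^-dCt; NaN when target or housekeeper never amplified
    delta_ct: float
    discordant: bool  # any duplicate pair spread beyond the concordance window


def _clean(reps: Sequence[float]) -> list[float]:
    return [float(x) for x in reps if x is not None and not math.isnan(float(x))]


def relative_expression(
    ct_target: Sequence[float],
    ct_housekeeper: Sequence[float],
    concordance_window: float = 1.0,
) -> QpcrResult:
    """C = 2^-dCt from technical-duplicate Ct values.

    Duplicates are averaged on the Ct scale before exponentiation.
    Undetermined Ct (NaN, "no amplification") is treated as missing: with
    no valid target replicate C is NaN, not an imputed ceiling value.
    Duplicate spreads beyond ``concordance_window`` cycles are flagged
    but the value is still computed.
    """
    t = _clean(ct_target)
    h = _clean(ct_housekeeper)
    if not h:
        logger.warning("no valid housekeeper Ct; expression undefined")
        return QpcrResult(c=float("nan"), delta_ct=float("nan"), discordant=False)
    if any(x <= 0 for x in t + h):
        raise ValueError("Ct values must be positive")
    discordant = (len(t) >= 2 and max(t) - min(t) > concordance_window) or (
        len(h) >= 2 and max(h) - min(h) > concordance_window
    )
    if discordant:
        logger.warning(
            "discordant qPCR duplicates (target %s / housekeeper %s)", t, h
        )
    if not t:
        # target never amplified: expression is missing, not zero
        return QpcrResult(c=float("nan"), delta_ct=float("nan"), discordant=discordant)
    delta_ct = float(np.mean(t) - np.mean(h))
    return QpcrResult(c=2.0 ** (-delta_ct), delta_ct=delta_ct, discordant=discordant)


def vg_per_diploid_genome(eyfp_copies: float, rpp30_copies: float) -> float:
    """G = eyfp copies / (Rpp30 copies / 2): vector genomes per diploid genome.

    Rpp30 is diploid, so half its copy count is the number of diploid
    genomes in the reaction.  A zero Rpp30 count means the sample carried
    no measurable genomic input; G is returned as NaN (masked) with a
    warning.  Because G is a ratio of the two channels, the DNA input
    mass cancels and needs no correction.
    """
    if eyfp_copies < 0 or rpp30_copies < 0:
        raise ValueError("copy counts must be >= 0")
    if rpp30_copies == 0:
        logger.warning("Rpp30 copies == 0; vector dose undefined, masking sample")
        return float("nan")
    return eyfp_copies / (rpp30_copies / 2.0)


def normalized_single(c: float, g: float) -> float:
    """Q = C / G; masked (NaN) when the vector dose is zero or missing."""
    if g is None or math.isnan(g) or g == 0:
        if g == 0:
            logger.warning("vector dose G == 0; Q masked")
        return float("nan")
    return c / g


def quantify_validation(
    qpcr: pd.DataFrame,
    ddpcr: pd.DataFrame,
    concordance_window: float = 1.0,
) -> pd.DataFrame:
    """Join qPCR and ddPCR tables into a long C/G/Q table.

    ``qpcr`` columns: animal_id, tissue, promoter_id, ct_target_rep1,
    ct_target_rep2, ct_hk_rep1, ct_hk_rep2.  ``ddpcr`` columns:
    animal_id, tissue, promoter_id, eyfp_copies, rpp30_copies.  Returns
    one row per (promoter, animal, tissue) with C, G, Q and the
    duplicate-discordance flag.
    """
    keys = ["promoter_id", "animal_id", "tissue"]
    merged = qpcr.merge(ddpcr, on=keys, how="outer", validate="one_to_one")
    rows = []
    for r in merged.itertuples():
        q_res = relative_expression(
            [r.ct_target_rep1, r.ct_target_rep2],
            [r.ct_hk_rep1, r.ct_hk_rep2],
            concordance_window=concordance_window,
        )
        g = vg_per_diploid_genome(r.eyfp_copies, r.rpp30_copies)
        rows.append(
            {
                "promoter_id": r.promoter_id,
                "animal_id": r.animal_id,
                "tissue": r.tissue,
                "C": q_res.c,
                "G": g,
                "Q": normalized_single(q_res.c, g),
                "qpcr_discordant": q_res.discordant,
            }
        )
    return pd.DataFrame(rows)


def validation_scores(q_table: pd.DataFrame) -> tuple[ScoreMatrix, ScoreMatrix]:
    """Efficiency and specificity scores from a long Q table.

    Specificity is per animal: S = 100 * Q / sum-over-tissues for that
    animal.  Efficiency is per tissue from the construct means:
    Q*[a,b] = mean over the replicate animals of promoter a, then
    E[a,b] = 100 * Q*[a,b] / sum-over-promoters.  Promoters missing a
    tissue stay masked (NaN) with a warning.
    """
    q = q_table.pivot(index=["promoter_id", "animal_id"], columns="tissue", values="Q")
    n_missing = int(q.isna().to_numpy().sum())
    if n_missing:
        logger.warning("validation: %d missing Q entries remain masked", n_missing)

    sums = q.sum(axis=1, skipna=True)
    usable = q.notna().any(axis=1) & (sums > 0)
    if (~usable).any():
        logger.warning(
            "specificity: animals with no usable Q: %s", list(q.index[~usable])
        )
    s_vals = 100.0 * q.div(sums.where(usable), axis=0)
    specificity = ScoreMatrix(values=s_vals, axis="tissues", kind="specificity")
    grouped = s_vals.groupby(level="promoter_id")
    specificity.mean = grouped.mean()
    specificity.sd = grouped.std(ddof=1)
    specificity.n = grouped.count()

    q_star = q.groupby(level="promoter_id").mean()  # mean over each construct's animals
    col_sums = q_star.sum(axis=0, skipna=True)
    ok = q_star.notna().any(axis=0) & (col_sums > 0)
    if (~ok).any():
        logger.warning(
            "efficiency: dropping tissues with no usable mean Q: %s",
            list(q_star.columns[~ok]),
        )
    q_star = q_star.loc[:, ok]
    e_vals = 100.0 * q_star / q_star.sum(axis=0, skipna=True)
    efficiency = ScoreMatrix(
        values=e_vals, axis="promoters", kind="efficiency", mean=e_vals
    )
    return efficiency, specificity
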