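"""Library-screen normalization: proportions, R, efficiency and specificity.

The screen reads out each promoter's barcode abundance twice per tissue:
in genomic DNA (vector delivery) and in cDNA (transcriptional output).
Within a sample, counts are converted to proportions over assigned
reads.  Normalized expression is then

    R[a,b] = (P_cDNA[a,b] / P_gDNA[a,b]) * C[b]

where C[b] is the bulk relative reporter expression of tissue b measured
by qPCR (2^-dCt against a housekeeper).  Dividing cDNA by gDNA
proportions cancels biodistribution; multiplying by C[b] restores the
tissue's absolute expression scale so that values are comparable across
tissues.

R is deconstructed into two 0-100 scores:

* efficiency  E[a,b] = 100 * R[a,b] / sum_over_promoters R[.,b]
  ("which promoter is strongest in this tissue"), and
* specificity S[a,b] = 100 * R[a,b] / sum_over_tissues R[a,.]
  ("where does this promoter act").

Scores are computed per animal and then aggregated (mean, SD, n) over
the replicate animals.

Zero handling is masking, never pseudocounts: promoters below the gDNA
detection floor in a sample are masked there (a low gDNA denominator
makes the ratio explosive), and masked entries are excluded from every
downstream sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode_extraction import BarcodeCountTable

logger = logging.getLogger("promoscreen")

MATERIALS = ("gDNA", "cDNA", "library_stock")

#: Sum-to-100 tolerance of the score invariants.
SCORE_SUM_ATOL = 1e-9


class SampleSheet:
    """Maps sequencing samples to (animal, tissue, material).

    Every cDNA sample must have a gDNA partner for the same
    (animal, tissue); library_stock rows carry no animal/tissue pairing
    requirement.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "animal_id", "tissue", "material"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        frame = frame.reset_index(drop=True)
        bad = set(frame["material"]) - set(MATERIALS)
        if bad:
            raise ValueError(f"unknown material values: {sorted(bad)}")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id: {dups}")
        keyed = frame[frame["material"] != "library_stock"]
        key = keyed[["animal_id", "tissue", "material"]]
        if key.duplicated().any():
            raise ValueError("duplicate (animal, tissue, material) combination")
        have_g = {
            (r.animal_id, r.tissue)
            for r in keyed.itertuples()
            if r.material == "gDNA"
        }
        for r in keyed.itertuples():
            if r.material == "cDNA" and (r.animal_id, r.tissue) not in have_g:
                raise ValueError(
                    f"cDNA sample {r.sample_id!r} has no gDNA partner for "
                    f"({r.animal_id!r}, {r.tissue!r})"
                )
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path))

    def pairs(self) -> list[tuple[str, str, str, str]]:
        """(animal, tissue, gdna_sample, cdna_sample) for every paired tissue."""
        by_key: dict[tuple[str, str], dict[str, str]] = {}
        for r in self.frame.itertuples():
            if r.material in ("gDNA", "cDNA"):
                by_key.setdefault((r.animal_id, r.tissue), {})[r.material] = r.sample_id
        out = []
        for (animal, tissue), mats in sorted(by_key.items()):
            if "gDNA" in mats and "cDNA" in mats:
                out.append((animal, tissue, mats["gDNA"], mats["cDNA"]))
        return out

    def library_stock_samples(self) -> list[str]:
        return self.frame.loc[
            self.frame["material"] == "library_stock", "sample_id"
        ].tolist()


class BulkExpression:
    """Bulk relative reporter expression C[b] per (animal, tissue).

    C is measured as 2^-dCt of the reporter against a housekeeper on the
    whole-tissue cDNA.  If only per-tissue means are supplied (no
    animal_id column), they are broadcast to all animals with a logged
    notice.
    """

    def __init__(self, values: pd.Series):
        # index: MultiIndex (animal_id, tissue)
        if (values <= 0).any():
            bad = values[values <= 0]
            raise ValueError(f"C values must be positive; offending: {bad.to_dict()}")
        self.values = values

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, animals: Sequence[str] | None = None
    ) -> "BulkExpression":
        if "animal_id" in frame.columns:
            s = frame.set_index(["animal_id", "tissue"])["c_beta"].astype(float)
            return cls(s)
        if animals is None:
            raise ValueError(
                "bulk expression has no animal_id column; pass `animals` to broadcast"
            )
        logger.info("broadcasting per-tissue C values to %d animals", len(animals))
        rows = {
            (a, r.tissue): float(r.c_beta) for a in animals for r in frame.itertuples()
        }
        return cls(pd.Series(rows).rename_axis(["animal_id", "tissue"]))

    @classmethod
    def from_csv(cls, path: str | Path, animals: Sequence[str] | None = None):
        return cls.from_frame(pd.read_csv(path), animals=animals)

    def lookup(self, animal_id: str, tissue: str) -> float:
        try:
            return float(self.values.loc[(animal_id, tissue)])
        except KeyError:
            raise KeyError(f"no bulk expression for ({animal_id!r}, {tissue!r})")


class LowCoverageError(ValueError):
    """Sample's assigned-read total is below the configured minimum."""


def proportions(
    counts: BarcodeCountTable, min_reads_per_sample: int = 0
) -> pd.Series:
    """Promoter proportions over assigned reads of one sample.

    Ambiguous and unassigned reads are excluded from the denominator, so
    the returned proportions sum to 1 whenever any read was assigned.
    """
    s = pd.Series(counts.counts, dtype=float)
    total = s.sum()
    if total < max(min_reads_per_sample, 1):
        raise LowCoverageError(
            f"sample {counts.sample_id!r}: {int(total)} assigned reads "
            f"< minimum {max(min_reads_per_sample, 1)}"
        )
    return s / total


@dataclass
class NormalizedExpression:
    """R matrix over promoters x (animal, tissue); NaN entries are masked."""

    values: pd.DataFrame  # index: promoter_id; columns: MultiIndex (animal, tissue)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("R values must be >= 0 (or masked)")

    @property
    def animals(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns.get_level_values(1).unique())

    def subset(self, promoter_ids: Sequence[str]) -> "NormalizedExpression":
        missing = set(promoter_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown promoters: {sorted(missing)}")
        return NormalizedExpression(self.values.loc[list(promoter_ids)])

    def mean_over_animals(self) -> pd.DataFrame:
        """Promoters x tissues mean of R over animals (masked cells skipped)."""
        return self.values.T.groupby(level=1).mean().T


def normalized_expression(
    p_cdna: pd.DataFrame,
    p_gdna: pd.DataFrame,
    c_bulk: BulkExpression,
    gdna_counts: pd.DataFrame | None = None,
    gdna_floor: int = 10,
) -> NormalizedExpression:
    """Compute R = (P_cDNA / P_gDNA) * C per (animal, tissue).

    ``p_cdna``/``p_gdna`` are promoters x (animal, tissue) proportion
    tables with identical column sets (an unpaired column is an error
    naming the pair).  When per-sample gDNA *counts* are supplied,
    promoters with fewer than ``gdna_floor`` assigned gDNA reads in a
    sample are masked (NaN) there rather than producing explosive or
    infinite ratios; without counts, only zero-gDNA entries are masked.
    """
    for df in (p_cdna, p_gdna):
        if not isinstance(df.columns, pd.MultiIndex):
            df.columns = pd.MultiIndex.from_tuples(df.columns)
    cols_c = set(p_cdna.columns)
    cols_g = set(p_gdna.columns)
    if cols_c != cols_g:
        odd = sorted(cols_c.symmetric_difference(cols_g))
        raise ValueError(f"unpaired cDNA/gDNA samples for (animal, tissue): {odd}")
    p_cdna = p_cdna.sort_index(axis=1)
    p_gdna = p_gdna.reindex(index=p_cdna.index, columns=p_cdna.columns)
    c = pd.Series(
        {col: c_bulk.lookup(col[0], col[1]) for col in p_cdna.columns}
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (p_cdna / p_gdna).mul(c, axis=1)
    mask = p_gdna <= 0
    if gdna_counts is not None:
        if not isinstance(gdna_counts.columns, pd.MultiIndex):
            gdna_counts.columns = pd.MultiIndex.from_tuples(gdna_counts.columns)
        gdna_counts = gdna_counts.reindex(index=p_cdna.index, columns=p_cdna.columns)
        mask |= gdna_counts < gdna_floor
    n_masked = int(mask.to_numpy().sum())
    if n_masked:
        logger.warning(
            "masking %d promoter/sample entries below the gDNA detection floor (%d reads)",
            n_masked,
            gdna_floor,
        )
    r = r.where(~mask)
    r = r.replace([np.inf, -np.inf], np.nan)
    return NormalizedExpression(r)


def quantify_screen(
    counts: Mapping[str, BarcodeCountTable],
    samples: SampleSheet,
    bulk: BulkExpression,
    min_reads_per_sample: int = 1000,
    gdna_floor: int = 10,
) -> NormalizedExpression:
    """Counts + sample sheet + bulk qPCR -> R matrix.

    Samples below ``min_reads_per_sample`` assigned reads are excluded
    (with their pair) and logged; remaining pairs flow through
    :func:`normalized_expression`.
    """
    p_g: dict[tuple[str, str], pd.Series] = {}
    p_c: dict[tuple[str, str], pd.Series] = {}
    n_g: dict[tuple[str, str], pd.Series] = {}
    for animal, tissue, g_id, c_id in samples.pairs():
        try:
            pg = proportions(counts[g_id], min_reads_per_sample)
            pc = proportions(counts[c_id], min_reads_per_sample)
        except LowCoverageError as exc:
            logger.warning("excluding (%s, %s): %s", animal, tissue, exc)
            continue
        key = (animal, tissue)
        p_g[key], p_c[key] = pg, pc
        n_g[key] = pd.Series(counts[g_id].counts, dtype=float)
    if not p_g:
        raise ValueError("no sample pair passed the coverage threshold")
    return normalized_expression(
        pd.DataFrame(p_c),
        pd.DataFrame(p_g),
        bulk,
        gdna_counts=pd.DataFrame(n_g),
        gdna_floor=gdna_floor,
    )


@dataclass
class ScoreMatrix:
    """Efficiency or specificity scores with optional replicate statistics.

    ``values`` holds per-animal scores (promoters x (animal, tissue) for
    the library screen; other layouts are allowed as long as ``axis``
    names the normalized index).  ``axis`` records which index each score
    group sums to 100 over: "promoters" for efficiency, "tissues" for
    specificity.  ``mean``/``sd``/``n`` (promoters x tissues) are filled
    by :func:`aggregate_replicates`.
    """

    values: pd.DataFrame
    axis: str  # "promoters" | "tissues"
    kind: str  # "efficiency" | "specificity"
    mean: pd.DataFrame | None = None
    sd: pd.DataFrame | None = None
    n: pd.DataFrame | None = None


def efficiency_scores(r: NormalizedExpression) -> ScoreMatrix:
    """E = 100 * R / sum-over-promoters, per (animal, tissue) column.

    Columns (tissue samples) with no unmasked entry or an all-zero sum
    are dropped with a warning.
    """
    vals = r.values
    sums = vals.sum(axis=0, skipna=True)
    usable = vals.notna().any(axis=0) & (sums > 0)
    dropped = [c for c, ok in usable.items() if not ok]
    if dropped:
        logger.warning("efficiency: dropping fully masked tissue samples: %s", dropped)
    vals = vals.loc[:, usable]
    e = 100.0 * vals / vals.sum(axis=0, skipna=True)
    return ScoreMatrix(values=e, axis="promoters", kind="efficiency")


def specificity_scores(r: NormalizedExpression) -> ScoreMatrix:
    """S = 100 * R / sum-over-tissues, per (animal, promoter) row.

    Promoters with no unmasked entry across an animal's tissues stay NaN
    for that animal (warned), so the promoters x (animal, tissue) layout
    is preserved.
    """
    blocks = []
    for animal in r.animals:
        block = r.values[animal]
        sums = block.sum(axis=1, skipna=True)
        usable = block.notna().any(axis=1) & (sums > 0)
        if (~usable).any():
            logger.warning(
                "specificity: animal %s: promoters fully masked: %s",
                animal,
                list(block.index[~usable]),
            )
        s = 100.0 * block.div(sums.where(usable), axis=0)
        s.columns = pd.MultiIndex.from_product([[animal], s.columns])
        blocks.append(s)
    return ScoreMatrix(
        values=pd.concat(blocks, axis=1), axis="tissues", kind="specificity"
    )


def aggregate_replicates(
    scores: ScoreMatrix | Iterable[ScoreMatrix],
) -> ScoreMatrix:
    """Element-wise mean, sample SD and n over replicate animals.

    Accepts either one ScoreMatrix whose columns carry an (animal, tissue)
    MultiIndex, or a collection of single-animal ScoreMatrix objects with
    identical promoter x tissue structure.
    """
    if isinstance(scores, ScoreMatrix):
        combined = scores
    else:
        mats = list(scores)
        if not mats:
            raise ValueError("no score matrices to aggregate")
        kinds = {m.kind for m in mats}
        axes = {m.axis for m in mats}
        if len(kinds) > 1 or len(axes) > 1:
            raise ValueError("cannot aggregate mixed score kinds")
        first = mats[0].values
        for m in mats[1:]:
            if not m.values.index.equals(first.index) or not m.values.columns.equals(
                first.columns
            ):
                raise ValueError("replicate score matrices have mismatched indexes")
        combined = ScoreMatrix(
            values=pd.concat({str(i): m.values for i, m in enumerate(mats)}, axis=1),
            axis=mats[0].axis,
            kind=mats[0].kind,
        )
    vals = combined.values
    if vals.columns.nlevels != 2:
        raise ValueError("expected (animal, tissue) columns for aggregation")
    grouped = vals.T.groupby(level=1)
    mean = grouped.mean().T
    sd = grouped.std(ddof=1).T
    n = grouped.count().T
    return ScoreMatrix(
        values=vals, axis=combined.axis, kind=combined.kind, mean=mean, sd=sd, n=n
    )
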