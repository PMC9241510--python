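"""Count-table preprocessing: rarefaction and occupancy filtering."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OccurrenceMatrix:
    """Binary taxa x site incidence plus carried per-taxon annotations.

    ``presence`` is 0/1 (taxa rows, site columns); ``occupancy`` is the row sum;
    ``mean_rel_abundance`` is the mean over sites of count/column-total computed
    on the counts supplied for annotation (pre-rarefaction by pipeline default).
    """

    presence: pd.DataFrame
    occupancy: pd.Series
    mean_rel_abundance: pd.Series

    @property
    def taxa(self) -> pd.Index:
        return self.presence.index

    @property
    def sites(self) -> pd.Index:
        return self.presence.columns

    @property
    def n_sites(self) -> int:
        return self.presence.shape[1]

    def annotation_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "occupancy": self.occupancy,
            "mean_rel_abundance": self.mean_rel_abundance,
        })


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("duplicate taxon or site ids in count table")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer) and not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integral")


def rarefy(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every site without replacement to a common ``depth``.

    Sites whose total is below ``depth`` are dropped with a warning; retained
    columns sum exactly to ``depth``.  Uses the multivariate hypergeometric
    sampler, i.e. classic rarefaction.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    _validate_counts(counts)
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = counts.shape[1] - len(keep)
    if len(keep) == 0:
        raise ValueError("all sites are below the rarefaction depth")
    if dropped:
        warnings.warn(f"dropping {dropped} site(s) below rarefaction depth {depth}")
    out = {}
    for site in keep:
        col = counts[site].to_numpy().astype(np.int64)
        out[site] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=counts.index)


def filter_and_binarize(
    counts: pd.DataFrame,
    min_occurrence_fraction: float,
    abundance_counts: pd.DataFrame | None = None,
) -> OccurrenceMatrix:
    """Binarize a count table and drop rare taxa.

    A taxon is retained iff it occurs (count > 0) in at least
    ``ceil(min_occurrence_fraction * n_sites)`` sites (the boundary is kept).
    Mean relative abundance is annotated from ``abundance_counts`` when given
    (e.g. the pre-rarefaction table), else from ``counts`` itself.
    """
    if not (0 < min_occurrence_fraction < 1):
        raise ValueError("min_occurrence_fraction must be in (0, 1)")
    _validate_counts(counts)
    presence = (counts > 0).astype(np.int8)
    n_sites = presence.shape[1]
    threshold = math.ceil(min_occurrence_fraction * n_sites)
    occupancy = presence.sum(axis=1)
    kept = occupancy[occupancy >= threshold].index
    if len(kept) == 0:
        raise ValueError(
            f"no taxon reaches the occupancy threshold ({threshold} of {n_sites} sites)")

    ab = counts if abundance_counts is None else abundance_counts
    col_tot = ab.sum(axis=0).replace(0, np.nan)
    rel = ab.div(col_tot, axis=1)
    mean_rel = rel.mean(axis=1, skipna=True)

    return OccurrenceMatrix(
        presence=presence.loc[kept],
        occupancy=occupancy.loc[kept],
        mean_rel_abundance=mean_rel.reindex(kept),
    )
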