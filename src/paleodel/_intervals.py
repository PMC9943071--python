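"""Half-open genomic interval utilities shared by the depth and
annotation modules.

Intervals are BED-style: 0-based, half-open ``[start, end)``.  Two
intervals overlap when they share at least one base pair; adjacency
(``end == start``) is not overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ("chrom", "start", "end")


class MalformedIntervalError(ValueError):
    """Raised for an interval row with end <= start, reporting the row."""


def read_bed(path, names: tuple = BED_COLUMNS, n_extra: int = 0) -> pd.DataFrame:
    cols = list(names) + [f"col{i}" for i in range(n_extra)]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=cols, usecols=range(len(cols)),
                     dtype={"chrom": str})
    return df


def validate_intervals(df: pd.DataFrame, what: str = "interval") -> None:
    bad = np.nonzero((df["end"] <= df["start"]).to_numpy())[0]
    if len(bad):
        raise MalformedIntervalError(
            f"malformed {what} (end <= start) at row {int(bad[0]) + 1} "
            f"of {len(df)}")


def count_overlaps(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Number of subject intervals overlapping each query by >=1 bp.

    Per-chromosome counting via sorted endpoints: a subject [s, e)
    overlaps query [qs, qe) iff s < qe and e > qs, so the count is
    #(starts < qe) - #(ends <= qs).
    """
    validate_intervals(queries, "query interval")
    validate_intervals(subjects, "subject interval")
    out = np.zeros(len(queries), dtype=np.int64)
    for chrom, qgrp in queries.groupby("chrom", sort=False):
        sgrp = subjects[subjects["chrom"] == chrom]
        if sgrp.empty:
            continue
        starts = np.sort(sgrp["start"].to_numpy())
        ends = np.sort(sgrp["end"].to_numpy())
        qs = qgrp["start"].to_numpy()
        qe = qgrp["end"].to_numpy()
        n = np.searchsorted(starts, qe, side="left") \
            - np.searchsorted(ends, qs, side="right")
        out[qgrp.index.to_numpy()] = n
    return out


def overlap_pairs(queries: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """All (query_index, subject_index) pairs with >=1 bp overlap."""
    validate_intervals(queries, "query interval")
    validate_intervals(subjects, "subject interval")
    rows = []
    for chrom, qgrp in queries.groupby("chrom", sort=False):
        sgrp = subjects[subjects["chrom"] == chrom]
        if sgrp.empty:
            continue
        s_start = sgrp["start"].to_numpy()
        s_end = sgrp["end"].to_numpy()
        s_idx = sgrp.index.to_numpy()
        order = np.argsort(s_start, kind="stable")
        s_start, s_end, s_idx = s_start[order], s_end[order], s_idx[order]
        for qi, qs, qe in zip(qgrp.index.to_numpy(),
                              qgrp["start"].to_numpy(),
                              qgrp["end"].to_numpy()):
            hi = np.searchsorted(s_start, qe, side="left")
            hits = np.nonzero(s_end[:hi] > qs)[0]
            rows.extend((qi, s_idx[h]) for h in hits)
    return pd.DataFrame(rows, columns=["query_index", "subject_index"],
                        dtype=np.int64)
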