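"""Read-depth genotyping of deletion windows in archaic genomes.

A deletion segregating in present-day humans is genotyped in an archaic
genome by counting the reads intersecting the deletion window, dividing
by the window size (normalized depth ``r_i``), and scoring each window
with the modified Z-score

    ModZ_i = (r_i - median(R)) / MAD(R)

where R is the vector of normalized depths across all candidate windows
of that genome and MAD is the unscaled median absolute deviation
(no 0.6745 consistency constant: the calling threshold was chosen on the
unscaled score).  A window is called deleted when ModZ_i < -5; the
conventional outlier threshold for modified Z-scores is +-3.5, and the
stricter default is deliberately conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import count_overlaps, validate_intervals

__all__ = [
    "DeletionWindow",
    "DegenerateSpreadError",
    "DEFAULT_THRESHOLD",
    "MAD_CONSISTENCY",
    "count_intersecting_reads",
    "normalized_depth",
    "modified_z",
    "call_deletions",
    "genotype_windows",
    "presence_matrix",
    "shared_with_any_archaic",
    "windows_to_frame",
]

DEFAULT_THRESHOLD = -5.0
#: Conventional consistency constant relating MAD to the normal SD;
#: applied only when ``scale_mad=True``.
MAD_CONSISTENCY = 0.6745


@dataclass(frozen=True)
class DeletionWindow:
    """0-based half-open candidate deletion interval."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.id}: end must exceed start")

    @property
    def size(self) -> int:
        return self.end - self.start


class DegenerateSpreadError(ValueError):
    """MAD of the normalized depths is zero: modified Z-scores undefined."""


def windows_to_frame(windows: Sequence[DeletionWindow]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "id": [w.id for w in windows],
    })


def count_intersecting_reads(reads: pd.DataFrame,
                             windows: Sequence[DeletionWindow]) -> np.ndarray:
    """Reads overlapping each window by >=1 bp (a read spanning two
    windows counts in both).  ``reads``: BED-like frame with
    chrom/start/end columns."""
    validate_intervals(reads, "read")
    wf = windows_to_frame(windows)
    return count_overlaps(wf, reads)


def normalized_depth(count, window_size_bp):
    """Reads per base pair of window: count / window size."""
    size = np.asarray(window_size_bp, dtype=float)
    if np.any(size <= 0):
        raise ValueError("window size must be positive")
    return np.asarray(count, dtype=float) / size


def modified_z(depths: np.ndarray, scale_mad: bool = False) -> np.ndarray:
    """Modified Z-scores of normalized depths across windows of one genome.

    Raises :class:`DegenerateSpreadError` when the MAD is zero (e.g. a
    constant depth vector), since every score would be undefined.
    """
    r = np.asarray(depths, dtype=float)
    if r.size < 2:
        raise ValueError("need >=2 windows to measure spread")
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    if mad == 0:
        raise DegenerateSpreadError(
            "median absolute deviation of depths is zero")
    if scale_mad:
        mad = mad / MAD_CONSISTENCY
    return (r - med) / mad


def call_deletions(modz: np.ndarray,
                   threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Deleted iff ModZ strictly below the threshold."""
    return np.asarray(modz, dtype=float) < threshold


def genotype_windows(reads_by_genome: Mapping[str, pd.DataFrame],
                     windows: Sequence[DeletionWindow],
                     threshold: float = DEFAULT_THRESHOLD,
                     scale_mad: bool = False,
                     per_chromosome: bool = False) -> pd.DataFrame:
    """Full pipeline: counts, normalized depths, ModZ and calls for every
    (genome, window).

    ModZ is computed per genome across all windows by default; with
    ``per_chromosome=True`` the median/MAD are taken within each
    chromosome instead.
    """
    wf = windows_to_frame(windows)
    sizes = (wf["end"] - wf["start"]).to_numpy()
    frames = []
    for genome, reads in reads_by_genome.items():
        counts = count_intersecting_reads(reads, windows)
        r = normalized_depth(counts, sizes)
        if per_chromosome:
            modz = np.empty_like(r)
            for chrom in wf["chrom"].unique():
                sel = (wf["chrom"] == chrom).to_numpy()
                modz[sel] = modified_z(r[sel], scale_mad=scale_mad)
        else:
            modz = modified_z(r, scale_mad=scale_mad)
        frames.append(pd.DataFrame({
            "genome": genome,
            "window_id": wf["id"],
            "count": counts,
            "normalized_depth": r,
            "modz": modz,
            "deleted": call_deletions(modz, threshold),
        }))
    return pd.concat(frames, ignore_index=True)


def presence_matrix(genotyped: pd.DataFrame) -> pd.DataFrame:
    """Window x genome boolean deletion-presence matrix."""
    return genotyped.pivot(index="window_id", columns="genome",
                           values="deleted").astype(bool)


def shared_with_any_archaic(presence: pd.DataFrame) -> pd.Series:
    """Downstream reduction: a deletion is archaic-shared when called
    deleted in at least one archaic genome."""
    return presence.any(axis=1)
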