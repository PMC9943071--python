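"""LD companions of deletions and evolutionary classification.

A deletion shared between present-day humans and archaic genomes can be
ancient (maintained since the common ancestral population), recurrent
(arisen independently in each lineage), or introgressed (entered AMHs
through archaic admixture).  The diagnosis leans on the SNVs in linkage
disequilibrium with the deletion (haplotype r^2 > 0.9 within 50 kb):

- recurrent: no companion derived allele is present in any archaic
  genome that carries the deletion (the deletion travels without its
  human haplotype);
- introgressed: the deletion is absent in Yoruba and at least one
  companion is a published S*-significant introgressed SNV;
- ancient: every other shared deletion.

Deletions with no companion at all cannot be screened for recurrence or
introgression and are excluded from classification (reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvoCategory",
    "LDCompanion",
    "DeletionRecord",
    "SnvTable",
    "haplotype_r2",
    "find_companions",
    "classify_shared_deletion",
    "classify_all",
    "ClassificationResult",
]


class EvoCategory(str, Enum):
    HUMAN_SPECIFIC = "human_specific"
    RECURRENT = "recurrent"
    INTROGRESSED = "introgressed"
    ANCIENT = "ancient"


@dataclass(frozen=True)
class LDCompanion:
    """An SNV whose derived allele tags the deletion allele."""

    snv_id: str
    position: int
    r2: float
    distance: int


@dataclass
class DeletionRecord:
    """A biallelic deletion with its phased cohort haplotype vector."""

    id: str
    chrom: str
    start: int
    end: int
    haplotypes: np.ndarray  # 1 = deletion allele, per cohort haplotype
    populations: np.ndarray  # population label per haplotype
    companions: list[LDCompanion] = field(default_factory=list)
    category: EvoCategory | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.populations = np.asarray(self.populations)
        if self.end <= self.start:
            raise ValueError(f"deletion {self.id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def allele_count(self, population: str | None = None) -> int:
        if population is None:
            return int(self.haplotypes.sum())
        return int(self.haplotypes[self.populations == population].sum())

    @property
    def pooled_frequency(self) -> float:
        return float(self.haplotypes.mean())


@dataclass
class SnvTable:
    """Phased biallelic SNVs of the cohort (1 = derived allele)."""

    ids: np.ndarray  # (n_snvs,) str
    chroms: np.ndarray  # (n_snvs,) str
    positions: np.ndarray  # (n_snvs,) int
    haplotypes: np.ndarray  # (n_snvs, n_haplotypes) uint8
    populations: np.ndarray  # (n_haplotypes,) str

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        for name in ("ids", "chroms", "positions", "populations"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.haplotypes.shape[0] != len(self.ids):
            raise ValueError("one haplotype row per SNV required")

    @property
    def n_snvs(self) -> int:
        return len(self.ids)

    def minor_allele_counts(self) -> np.ndarray:
        derived = self.haplotypes.sum(axis=1)
        return np.minimum(derived, self.haplotypes.shape[1] - derived)


def haplotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Haplotype-based r^2 between two phased binary vectors.

    r^2 = D^2 / (p_a (1-p_a) p_b (1-p_b)) with D = f11 - p_a p_b.
    Returns NaN when either vector is monomorphic (r^2 undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must have equal length")
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _distance(deletion: DeletionRecord, position: int,
              mode: str = "breakpoint") -> int:
    """Distance from an SNV to the deletion (0 if inside the interval)."""
    if mode == "midpoint":
        return abs(int(position) - (deletion.start + deletion.end) // 2)
    if deletion.start <= position < deletion.end:
        return 0
    return int(min(abs(position - deletion.start),
                   abs(position - (deletion.end - 1))))


def find_companions(deletion: DeletionRecord, snvs: SnvTable,
                    radius: int = 50_000, r2_min: float = 0.9,
                    distance_mode: str = "breakpoint") -> list[LDCompanion]:
    """SNVs within ``radius`` whose derived allele has r^2 strictly above
    ``r2_min`` with the deletion allele.  Both boundary rules are strict:
    an SNV exactly at r^2 = r2_min or beyond the radius is excluded.
    Monomorphic or singleton (mac <= 1) SNVs are skipped."""
    mac = snvs.minor_allele_counts()
    same_chrom = snvs.chroms == deletion.chrom
    out = []
    for i in np.nonzero(same_chrom & (mac > 1))[0]:
        dist = _distance(deletion, int(snvs.positions[i]), distance_mode)
        if dist > radius:
            continue
        r2 = haplotype_r2(deletion.haplotypes, snvs.haplotypes[i])
        if np.isnan(r2) or r2 <= r2_min:
            continue
        out.append(LDCompanion(snv_id=str(snvs.ids[i]),
                               position=int(snvs.positions[i]),
                               r2=r2, distance=dist))
    return out


def classify_shared_deletion(
        deletion: DeletionRecord,
        companions: Sequence[LDCompanion],
        archaic_presence: Mapping[str, bool],
        archaic_snv_presence: Mapping[str, Iterable[str]],
        sstar_snvs: Iterable[str],
        yri_allele_count: int | None = None,
        yri_population: str = "YRI") -> EvoCategory:
    """Classify one archaic-shared deletion.

    Precedence: recurrence is tested first (no companion derived allele in
    any deletion-carrying archaic genome), then introgression (absent in
    Yoruba and >=1 companion on the published S* introgressed-SNV list),
    then the residual class, ancient.
    """
    carriers = [g for g, present in archaic_presence.items() if present]
    if not carriers:
        raise ValueError(
            f"deletion {deletion.id} is not archaic-shared; "
            "non-shared deletions are human-specific upstream")
    if not companions:
        raise ValueError(
            f"deletion {deletion.id} has no LD companions; it cannot be "
            "screened for recurrence/introgression")
    companion_ids = {c.snv_id for c in companions}
    present_in_carrier = any(
        companion_ids & set(archaic_snv_presence.get(g, ())) for g in carriers)
    if not present_in_carrier:
        return EvoCategory.RECURRENT
    if yri_allele_count is None:
        yri_allele_count = deletion.allele_count(yri_population)
    if yri_allele_count == 0 and companion_ids & set(sstar_snvs):
        return EvoCategory.INTROGRESSED
    return EvoCategory.ANCIENT


@dataclass
class ClassificationResult:
    """Partition of classified deletions plus the unclassifiable remainder."""

    table: pd.DataFrame  # deletion id, category, n_companions, yri_count
    excluded_no_companion: list[str]

    @property
    def counts(self) -> pd.Series:
        cats = [c.value for c in EvoCategory]
        return self.table["category"].value_counts().reindex(cats, fill_value=0)

    @property
    def proportions(self) -> pd.Series:
        return self.counts / max(len(self.table), 1)

    def ids_in(self, category: EvoCategory) -> list[str]:
        sel = self.table["category"] == category.value
        return self.table.loc[sel, "deletion_id"].tolist()


def classify_all(deletions: Sequence[DeletionRecord], snvs: SnvTable,
                 archaic_presence: pd.DataFrame,
                 archaic_snv_presence: Mapping[str, Iterable[str]],
                 sstar_snvs: Iterable[str],
                 radius: int = 50_000, r2_min: float = 0.9,
                 distance_mode: str = "breakpoint") -> ClassificationResult:
    """Assign every deletion exactly one category.

    ``archaic_presence``: deletion-id-indexed frame of per-genome boolean
    calls (from :mod:`paleodel.archaic_depth`).  Deletions without any LD
    companion are excluded and reported separately; non-shared deletions
    are human-specific.
    """
    sstar = set(sstar_snvs)
    snv_presence = {g: set(v) for g, v in archaic_snv_presence.items()}
    rows = []
    excluded = []
    for deletion in deletions:
        companions = find_companions(deletion, snvs, radius=radius,
                                     r2_min=r2_min,
                                     distance_mode=distance_mode)
        deletion.companions = companions
        if not companions:
            excluded.append(deletion.id)
            continue
        presence = archaic_presence.loc[deletion.id]
        shared = bool(presence.any())
        if not shared:
            category = EvoCategory.HUMAN_SPECIFIC
        else:
            category = classify_shared_deletion(
                deletion, companions, presence.to_dict(), snv_presence, sstar)
        deletion.category = category
        rows.append((deletion.id, category.value, len(companions),
                     deletion.allele_count("YRI")))
    table = pd.DataFrame(rows, columns=["deletion_id", "category",
                                        "n_companions", "yri_count"])
    return ClassificationResult(table=table, excluded_no_companion=excluded)
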