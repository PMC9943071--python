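"""Functional annotation of deletions and permutation enrichment tests.

Three definitions of phenotypic relevance are tested for enrichment in
ancient versus non-ancient deletions: exonic overlap, GWAS association
of an LD companion (p < 1e-8), and both combined.  The same machinery
tests 18 manually curated phenotype categories and the deletion-length
percentile profile.  Empirical p-values use label shuffling with the
add-one correction p = (1 + #{perm at least as extreme}) / (n_perm + 1),
two-sided on the difference of proportions (or percentile difference).
Analyses are restricted to deletions with pooled allele frequency > 5%
across YRI, CEU and CHB combined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import overlap_pairs, validate_intervals

__all__ = [
    "DEFAULT_PERCENTILES",
    "EnrichmentResult",
    "intersect_exons",
    "assign_gwas",
    "permutation_enrichment",
    "category_enrichment",
    "percentile_length_test",
    "pooled_frequency_filter",
]

DEFAULT_PERCENTILES = (2, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 98)
GWAS_P_THRESHOLD = 1e-8


@dataclass
class EnrichmentResult:
    """One permutation test: proportions, fold ratio and empirical p."""

    feature: str
    prop_ancient: float
    prop_non_ancient: float
    observed_diff: float
    p: float
    n_permutations: int

    @property
    def fold(self) -> float:
        if self.prop_non_ancient == 0:
            return float("inf") if self.prop_ancient > 0 else float("nan")
        return self.prop_ancient / self.prop_non_ancient


def intersect_exons(deletions: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Flag deletions overlapping >=1 exon by >=1 bp.

    ``deletions``: frame with chrom/start/end/id; ``exons``: BED-like
    frame with chrom/start/end/gene (0-based half-open).  Returns a frame
    indexed like ``deletions`` with columns ``exonic``, ``genes`` (sorted
    unique gene names) and ``exon_counts`` (per-gene overlapped-exon
    counts, aligned with ``genes``).
    """
    validate_intervals(deletions, "deletion")
    validate_intervals(exons, "exon")
    pairs = overlap_pairs(deletions.reset_index(drop=True),
                          exons.reset_index(drop=True))
    genes_by_del: dict[int, dict[str, int]] = {}
    gene_names = exons["gene"].to_numpy()
    for qi, si in pairs.itertuples(index=False):
        counts = genes_by_del.setdefault(qi, {})
        gene = gene_names[si]
        counts[gene] = counts.get(gene, 0) + 1
    rows = []
    for i in range(len(deletions)):
        counts = genes_by_del.get(i, {})
        genes = sorted(counts)
        rows.append((len(genes) > 0, genes, [counts[g] for g in genes]))
    out = pd.DataFrame(rows, columns=["exonic", "genes", "exon_counts"])
    out.index = deletions.index
    out.insert(0, "deletion_id", deletions["id"].to_numpy()
               if "id" in deletions else deletions.index)
    return out


def assign_gwas(companion_ids: Iterable[str], gwas_table: pd.DataFrame,
                p_threshold: float = GWAS_P_THRESHOLD):
    """GWAS relevance of a deletion through its LD companions.

    ``gwas_table``: frame with columns snv_id, trait, p.  The deletion is
    associated iff some companion has an association with p strictly
    below the threshold; the assigned trait is the one with the minimal p
    among all companion associations.  Returns (flag, trait, p) with
    (False, None, NaN) when nothing qualifies.
    """
    ids = set(companion_ids)
    if not ids:
        return False, None, float("nan")
    hits = gwas_table[gwas_table["snv_id"].isin(ids)
                      & (gwas_table["p"] < p_threshold)]
    if hits.empty:
        return False, None, float("nan")
    best = hits.loc[hits["p"].idxmin()]
    return True, str(best["trait"]), float(best["p"])


def _binary_permutation_p(labels: np.ndarray, feature: np.ndarray,
                          n_perm: int, rng: np.random.Generator):
    """Two-sided label-shuffling p for a difference of proportions.

    For a binary feature, shuffling labels is equivalent to drawing the
    number of feature-positive deletions among the 'ancient' labels from
    a hypergeometric distribution, which is how the null is sampled.
    """
    n = len(labels)
    na = int(labels.sum())
    nn = n - na
    big_k = int(feature.sum())
    obs = feature[labels].mean() - feature[~labels].mean()
    k = rng.hypergeometric(big_k, n - big_k, na, size=n_perm)
    diffs = k / na - (big_k - k) / nn
    p = (1.0 + np.sum(np.abs(diffs) >= abs(obs) - 1e-12)) / (n_perm + 1.0)
    return obs, p


def permutation_enrichment(labels, feature, n_perm: int = 10_000,
                           seed=None, name: str = "feature") -> EnrichmentResult:
    """Permutation enrichment of a binary feature in ancient deletions.

    ``labels``: boolean array, True = ancient; ``feature``: boolean array
    of the same length.  Callers are expected to pre-filter deletions to
    pooled frequency > 5% (see :func:`pooled_frequency_filter`).
    """
    labels = np.asarray(labels, dtype=bool)
    feature = np.asarray(feature, dtype=bool)
    if labels.shape != feature.shape:
        raise ValueError("labels and feature must align")
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be non-empty")
    rng = np.random.default_rng(seed)
    obs, p = _binary_permutation_p(labels, feature, n_perm, rng)
    return EnrichmentResult(
        feature=name,
        prop_ancient=float(feature[labels].mean()),
        prop_non_ancient=float(feature[~labels].mean()),
        observed_diff=float(obs), p=float(p), n_permutations=n_perm)


def category_enrichment(labels: pd.Series,
                        memberships: Mapping[str, Iterable[str]],
                        categories: Sequence[str],
                        n_perm: int = 10_000, seed=None) -> pd.DataFrame:
    """Per-category enrichment of phenotype-category membership.

    ``labels``: boolean Series indexed by deletion id (True = ancient);
    ``memberships``: deletion id -> subset of category labels;
    ``categories``: the full curated label set (typically 18).  A
    membership outside ``categories`` raises; categories with zero member
    deletions are skipped and reported with NaN p.
    """
    cat_set = set(categories)
    for del_id, cats in memberships.items():
        unknown = set(cats) - cat_set
        if unknown:
            raise ValueError(
                f"deletion {del_id} carries unknown categories: "
                f"{sorted(unknown)}")
    rng = np.random.default_rng(seed)
    label_arr = labels.to_numpy(dtype=bool)
    rows = []
    for cat in categories:
        member = np.array([cat in set(memberships.get(i, ()))
                           for i in labels.index])
        if member.sum() == 0:
            rows.append((cat, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        res = permutation_enrichment(
            label_arr, member, n_perm=n_perm,
            seed=rng.integers(0, 2**31 - 1), name=cat)
        rows.append((cat, int(member.sum()), res.prop_ancient,
                     res.prop_non_ancient, res.fold, res.p))
    return pd.DataFrame(rows, columns=["category", "n_members",
                                       "prop_ancient", "prop_non_ancient",
                                       "fold", "p"])


def percentile_length_test(lengths, labels,
                           percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                           n_perm: int = 10_000, seed=None,
                           min_class_size: int = 10) -> pd.DataFrame:
    """Ancient vs non-ancient deletion length comparison per percentile.

    For each percentile q the observed statistic is
    q(ancient) - q(non-ancient); the permutation p is two-sided on that
    difference; the ancient/non-ancient ratio is reported alongside.
    Percentiles use linear interpolation between order statistics.
    """
    lengths = np.asarray(lengths, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if lengths.shape != labels.shape:
        raise ValueError("lengths and labels must align")
    na = int(labels.sum())
    nn = len(labels) - na
    if min(na, nn) < min_class_size:
        raise ValueError(f"each class needs >= {min_class_size} deletions "
                         f"(got ancient={na}, non-ancient={nn})")
    rng = np.random.default_rng(seed)
    q = np.asarray(percentiles, dtype=float)
    obs_a = np.percentile(lengths[labels], q)
    obs_n = np.percentile(lengths[~labels], q)
    obs_diff = obs_a - obs_n
    exceed = np.zeros(len(q))
    chunk = 512
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, len(lengths))), axis=1)
        perm_lengths = lengths[idx]
        pa = np.percentile(perm_lengths[:, :na], q, axis=1)
        pn = np.percentile(perm_lengths[:, na:], q, axis=1)
        diffs = pa - pn
        exceed += np.sum(np.abs(diffs) >= np.abs(obs_diff)[:, None] - 1e-12,
                         axis=1)
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(obs_n != 0, obs_a / obs_n, np.nan)
    return pd.DataFrame({
        "percentile": q, "ancient": obs_a, "non_ancient": obs_n,
        "ratio": ratio, "observed_diff": obs_diff, "p": p,
    })


def pooled_frequency_filter(frequencies, threshold: float = 0.05,
                            log: list | None = None) -> np.ndarray:
    """Mask of deletions whose pooled cohort frequency exceeds the
    threshold; appends a before/after count entry to ``log`` if given."""
    freqs = np.asarray(frequencies, dtype=float)
    mask = freqs > threshold
    if log is not None:
        log.append({"before": int(len(freqs)), "after": int(mask.sum()),
                    "threshold": threshold})
    return mask
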