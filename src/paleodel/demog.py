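"""Neutral coalescent expectation for archaic allele sharing.

The question this module answers: what fraction of present-day (YRI)
polymorphisms would carry a derived allele that is also present in at
least one archaic hominin genome (three Neanderthals, one Denisovan)
under neutrality alone?  Each variant is simulated as its own
freely-recombining locus: one genealogy for 216 YRI haploid genomes plus
2 haploids per archaic genome, and a single mutation placed on the
genealogy with probability proportional to branch length.  A variant
enters the denominator when it is YRI-polymorphic with minor allele
count > 1 (both alleles carried by at least two YRI haplotypes) and the
numerator when, additionally, at least one archaic haplotype carries the
derived allele.

Two model families are supported: a clean split model (``DemographicModel``)
and a structured-ancestry model (``StructuredAncestryModel``) in which the
population ancestral to AMHs and archaics is an island model of three
subgroups exchanging migrants at per-generation fraction ``m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from . import _tree

__all__ = [
    "ARCHAIC_GENOMES",
    "ConfigurationError",
    "DemographicModel",
    "StructuredAncestryModel",
    "VariantMatrix",
    "SharingResult",
    "ScanResult",
    "simulate_variant_matrix",
    "sharing_proportion",
    "sharing_distribution",
    "simulate_structured_ancestry",
    "scan_migration",
    "default_m_grid",
    "binned_sharing",
    "sfs_compare",
    "site_frequency_spectrum",
    "lineage_trajectories",
]

ARCHAIC_GENOMES = ("Denisovan", "Altai", "Vindija", "Chagyrskaya")

#: Sampling ages (years before present) used when a model asks for
#: ancient archaic sampling.  Approximate specimen ages from the
#: literature; present-day sampling is the default (plain-ms usage).
DEFAULT_ARCHAIC_SAMPLING_TIMES = {
    "Denisovan": 70_000.0,
    "Altai": 120_000.0,
    "Vindija": 50_000.0,
    "Chagyrskaya": 80_000.0,
}


class ConfigurationError(ValueError):
    """Raised when a demographic model is internally inconsistent."""


@dataclass(frozen=True)
class DemographicModel:
    """Split model for AMHs and the four archaic hominin genomes.

    ``amh_ne`` is either a constant diploid size or a piecewise-constant
    trajectory given as ``[(time_years_bp, size), ...]`` whose first epoch
    must start at time 0.  All split times are in years before present and
    are converted to generations with ``generation_time``.
    """

    amh_ne: float | Sequence[tuple[float, float]] = 14_474.0
    archaic_ne: float = 1_000.0
    t_split_amh_archaic: float = 700_000.0
    t_split_denisovan: float = 400_000.0
    t_split_altai: float = 130_000.0
    t_split_vindija_chagyrskaya: float = 90_000.0
    generation_time: float = 29.0
    #: None -> all archaic genomes sampled at the present day.
    archaic_sampling_times: Mapping[str, float] | None = None
    n_yri: int = 216
    n_archaic_haploids: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.t_split_vindija_chagyrskaya < self.t_split_altai
                < self.t_split_denisovan < self.t_split_amh_archaic):
            raise ConfigurationError(
                "split times must satisfy 0 < vindija-chagyrskaya < altai "
                "< denisovan < amh-archaic")
        if self.archaic_ne <= 0 or self.generation_time <= 0:
            raise ConfigurationError("sizes and generation time must be positive")
        for _, size in self.amh_epochs():
            if size <= 0:
                raise ConfigurationError("AMH sizes must be positive")
        if self.n_yri < 4:
            raise ConfigurationError("need >=4 YRI haplotypes for a mac>1 site")
        if self.n_archaic_haploids < 0:
            raise ConfigurationError("n_archaic_haploids must be >= 0")

    def amh_epochs(self) -> list[tuple[float, float]]:
        """AMH size trajectory as [(time_years, size), ...] starting at 0."""
        if np.isscalar(self.amh_ne):
            return [(0.0, float(self.amh_ne))]
        epochs = [(float(t), float(s)) for t, s in self.amh_ne]
        if epochs[0][0] != 0.0:
            raise ConfigurationError("first AMH epoch must start at time 0")
        if any(b[0] <= a[0] for a, b in zip(epochs, epochs[1:])):
            raise ConfigurationError("AMH epoch times must be increasing")
        return epochs

    def to_demography(self) -> msprime.Demography:
        g = self.generation_time
        epochs = self.amh_epochs()
        dem = msprime.Demography()
        # YRI doubles as the AMH/ancestral lineage after all splits.
        dem.add_population(name="YRI", initial_size=epochs[0][1])
        for name in ARCHAIC_GENOMES:
            dem.add_population(name=name, initial_size=self.archaic_ne)
        for name in ("NVC", "NEA", "ARC"):
            dem.add_population(name=name, initial_size=self.archaic_ne)
        for t_years, size in epochs[1:]:
            dem.add_population_parameters_change(
                time=t_years / g, population="YRI", initial_size=size)
        dem.add_population_split(
            time=self.t_split_vindija_chagyrskaya / g,
            derived=["Vindija", "Chagyrskaya"], ancestral="NVC")
        dem.add_population_split(
            time=self.t_split_altai / g, derived=["Altai", "NVC"],
            ancestral="NEA")
        dem.add_population_split(
            time=self.t_split_denisovan / g, derived=["Denisovan", "NEA"],
            ancestral="ARC")
        dem.add_population_split(
            time=self.t_split_amh_archaic / g, derived=["ARC"],
            ancestral="YRI")
        # YRI doubles as the ancestral population, so it must stay active
        # from the present day onward
        dem["YRI"].initially_active = True
        dem.sort_events()
        return dem

    def sample_sets(self) -> list[msprime.SampleSet]:
        g = self.generation_time
        times = self.archaic_sampling_times
        samples = [msprime.SampleSet(self.n_yri, population="YRI", time=0,
                                     ploidy=1)]
        if self.n_archaic_haploids > 0:
            for name in ARCHAIC_GENOMES:
                t = 0.0 if times is None else times[name] / g
                samples.append(msprime.SampleSet(
                    self.n_archaic_haploids, population=name, time=t, ploidy=1))
        return samples


@dataclass(frozen=True)
class StructuredAncestryModel:
    """Split model with an island-structured ancestral population.

    Backward in time, at the AMH-archaic split the remaining AMH and
    archaic ancestral lineages enter a symmetric island model of
    ``n_subgroups`` demes (diploid size ``subgroup_ne`` each) exchanging a
    per-generation migrant fraction ``m`` between every ordered pair, and
    the structure persists indefinitely pastward.

    ``entry_mode`` controls how lineages enter the structured phase:

    - ``"scatter"`` (default): every lineage is placed in a deme uniformly
      at random, matching the ms ``-es`` encoding of splitting the
      ancestral population into latent subgroups.
    - ``"source_demes"``: all AMH lineages enter ``amh_source_deme`` and
      all archaic lineages enter ``archaic_source_deme``.
    """

    base: DemographicModel = field(default_factory=DemographicModel)
    n_subgroups: int = 3
    subgroup_ne: float = 10_000.0
    m: float = 7.5e-5
    entry_mode: str = "scatter"
    amh_source_deme: int = 0
    archaic_source_deme: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.m < 1):
            raise ConfigurationError("migrant fraction m must be in [0, 1)")
        if self.n_subgroups < 2:
            raise ConfigurationError("need >=2 ancestral subgroups")
        if self.subgroup_ne <= 0:
            raise ConfigurationError("subgroup_ne must be positive")
        if self.entry_mode not in ("scatter", "source_demes"):
            raise ConfigurationError("entry_mode must be scatter|source_demes")
        if self.entry_mode == "source_demes":
            for d in (self.amh_source_deme, self.archaic_source_deme):
                if not 0 <= d < self.n_subgroups:
                    raise ConfigurationError("source deme index out of range")
            if self.m == 0 and self.amh_source_deme != self.archaic_source_deme:
                warnings.warn(
                    "m=0 with disjoint source demes: AMH and archaic lineages "
                    "can never coalesce; the simulation may not terminate",
                    stacklevel=2)

    @property
    def total_migrant_fraction(self) -> float:
        """Fraction of each subgroup replaced by migrants per generation.

        ``m`` is the per-ordered-pair rate (msprime semantics); with
        n subgroups the total inflow is (n-1)*m.  This is the quantity
        the classic ms ``-I`` flag parameterizes: ms takes 4*N*m_total
        and splits it evenly among the other subpopulations.
        """
        return (self.n_subgroups - 1) * self.m

    @property
    def scaled_migration(self) -> float:
        """M = 4*N*m_total with N the subgroup size (ms parameterization)."""
        return 4.0 * self.subgroup_ne * self.total_migrant_fraction

    def to_demography(self) -> msprime.Demography:
        base = self.base
        g = base.generation_time
        t_split = base.t_split_amh_archaic / g
        dem = msprime.Demography()
        epochs = base.amh_epochs()
        dem.add_population(name="YRI", initial_size=epochs[0][1])
        for name in ARCHAIC_GENOMES:
            dem.add_population(name=name, initial_size=base.archaic_ne)
        for name in ("NVC", "NEA", "ARC"):
            dem.add_population(name=name, initial_size=base.archaic_ne)
        demes = [f"D{i + 1}" for i in range(self.n_subgroups)]
        for name in demes:
            dem.add_population(name=name, initial_size=self.subgroup_ne)
        for t_years, size in epochs[1:]:
            if t_years / g < t_split:
                dem.add_population_parameters_change(
                    time=t_years / g, population="YRI", initial_size=size)
        dem.add_population_split(
            time=base.t_split_vindija_chagyrskaya / g,
            derived=["Vindija", "Chagyrskaya"], ancestral="NVC")
        dem.add_population_split(
            time=base.t_split_altai / g, derived=["Altai", "NVC"],
            ancestral="NEA")
        dem.add_population_split(
            time=base.t_split_denisovan / g, derived=["Denisovan", "NEA"],
            ancestral="ARC")
        if self.entry_mode == "scatter":
            p = [1.0 / self.n_subgroups] * self.n_subgroups
            dem.add_admixture(time=t_split, derived="YRI", ancestral=demes,
                              proportions=p)
            # epsilon offset: msprime forbids two events moving lineages out
            # of distinct populations at the identical instant otherwise
            dem.add_admixture(time=t_split * (1 + 1e-12), derived="ARC",
                              ancestral=demes, proportions=p)
        else:
            dem.add_population_split(
                time=t_split, derived=["YRI"],
                ancestral=demes[self.amh_source_deme])
            dem.add_population_split(
                time=t_split * (1 + 1e-12), derived=["ARC"],
                ancestral=demes[self.archaic_source_deme])
        for i in demes:
            for j in demes:
                if i != j:
                    dem.set_migration_rate(source=i, dest=j, rate=self.m)
        dem.sort_events()
        return dem

    def sample_sets(self) -> list[msprime.SampleSet]:
        return self.base.sample_sets()


@dataclass
class VariantMatrix:
    """Binary haplotype-by-site matrix (1 = derived allele).

    Each column is one independent locus carrying exactly one segregating
    site.  ``populations`` labels every haplotype row; archaic haplotypes
    are labelled with their genome name.
    """

    genotypes: np.ndarray  # (n_haplotypes, n_sites) uint8
    populations: np.ndarray  # (n_haplotypes,) str
    sample_times: np.ndarray | None = None  # years before present

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        self.populations = np.asarray(self.populations)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (haplotypes x sites)")
        if len(self.populations) != self.genotypes.shape[0]:
            raise ValueError("one population label per haplotype required")

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def mask(self, population: str) -> np.ndarray:
        return self.populations == population

    def derived_counts(self, population: str | None = None) -> np.ndarray:
        if population is None:
            return self.genotypes.sum(axis=0).astype(np.int64)
        return self.genotypes[self.mask(population)].sum(axis=0).astype(np.int64)


@dataclass
class SharingResult:
    """Archaic-sharing proportion among YRI mac>1 polymorphisms."""

    numerator: int
    denominator: int
    bin_edges: np.ndarray | None = None
    bin_proportions: np.ndarray | None = None  # NaN marks an empty bin
    bin_counts: np.ndarray | None = None

    @property
    def empty(self) -> bool:
        return self.denominator == 0

    @property
    def proportion(self) -> float:
        """Shared fraction; NaN for the empty-denominator signal."""
        if self.empty:
            return float("nan")
        return self.numerator / self.denominator


@dataclass
class ScanResult:
    """Result of a migration scan: largest m reaching the target sharing."""

    critical_m: float | None  # None = no grid point reached the target
    table: pd.DataFrame  # columns: m, proportion, numerator, denominator

    @property
    def reached(self) -> bool:
        return self.critical_m is not None


# ---------------------------------------------------------------------------
# simulation core

def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _sim_kwargs(model) -> dict:
    # ploidy=2 sets the diploid coalescent timescale (rate 1/2N per pair);
    # the sample sets themselves are haploid genomes
    return dict(samples=model.sample_sets(),
                demography=model.to_demography(), ploidy=2)


def _site_arrays(model, n_loci: int, seed, *, want_masks: bool = False,
                 traj_times_gens: np.ndarray | None = None):
    """Simulate ``n_loci`` independent single-site genealogies.

    Returns (yri_derived, archaic_derived, masks, traj) where the first two
    are per-locus derived-allele counts in the YRI sample and in the pooled
    archaic haplotypes; ``masks`` (optional) holds per-locus boolean derived
    indicators over all samples, and ``traj`` (optional) per-locus
    (total, derived) YRI lineage counts at each requested grid time.
    """
    _tree.warm_up()
    rng = np.random.default_rng(seed)
    msp_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(**_sim_kwargs(model), num_replicates=n_loci,
                                random_seed=msp_seed)
    yri_derived = np.zeros(n_loci, dtype=np.int64)
    arch_derived = np.zeros(n_loci, dtype=np.int64)
    masks = [] if want_masks else None
    traj = [] if traj_times_gens is not None else None
    is_yri = is_arch = None
    n_samples = 0
    for k, ts in enumerate(reps):
        child = ts.edges_child
        parent = ts.edges_parent
        node_time = ts.nodes_time
        if is_yri is None:
            smp = ts.samples()
            n_samples = len(smp)
            pops = ts.nodes_population[smp]
            yri_id = [p.id for p in ts.populations()
                      if p.metadata.get("name") == "YRI"][0]
            is_yri = (pops == yri_id).astype(np.int8)
            is_arch = (pops != yri_id).astype(np.int8)
        bl = node_time[parent] - node_time[child]
        cum = np.cumsum(bl)
        e = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        e = min(e, len(child) - 1)
        u = child[e]
        dy, da = _tree.subtree_counts(child, parent, len(node_time),
                                      is_yri, is_arch, u)
        yri_derived[k] = dy
        arch_derived[k] = da
        if want_masks:
            masks.append(_tree.descendant_samples_mask(
                child, parent, len(node_time), n_samples, u))
        if traj is not None:
            tot, der = _tree.lineage_counts_at_times(
                child, parent, node_time, len(node_time), n_samples,
                is_yri, u, traj_times_gens)
            traj.append((tot, der))
    return yri_derived, arch_derived, masks, traj


def simulate_variant_matrix(model: DemographicModel | StructuredAncestryModel,
                            n_loci: int, seed) -> VariantMatrix:
    """Simulate independent variants: one branch-length-weighted mutation
    per genealogy, 216 YRI + 2 haploids per archaic genome by default."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    _, _, masks, _ = _site_arrays(model, n_loci, seed, want_masks=True)
    genotypes = np.array(masks, dtype=np.uint8).T
    base = model.base if isinstance(model, StructuredAncestryModel) else model
    labels = ["YRI"] * base.n_yri
    times = [0.0] * base.n_yri
    st = base.archaic_sampling_times
    for name in ARCHAIC_GENOMES:
        labels += [name] * base.n_archaic_haploids
        times += [0.0 if st is None else st[name]] * base.n_archaic_haploids
    return VariantMatrix(genotypes=genotypes, populations=np.array(labels),
                         sample_times=np.array(times))


def _sharing_from_counts(yri_derived, arch_derived, n_yri: int,
                         n_bins: int = 10) -> SharingResult:
    yri_derived = np.asarray(yri_derived)
    arch_derived = np.asarray(arch_derived)
    polymorphic = (yri_derived >= 2) & (n_yri - yri_derived >= 2)
    shared = polymorphic & (arch_derived >= 1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    freq = yri_derived[polymorphic] / n_yri
    shared_poly = shared[polymorphic]
    # bins partition (0, 1]: right-closed intervals
    idx = np.clip(np.ceil(freq * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    num = np.bincount(idx, weights=shared_poly.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        props = np.where(counts > 0, num / np.maximum(counts, 1), np.nan)
    return SharingResult(numerator=int(shared.sum()),
                         denominator=int(polymorphic.sum()),
                         bin_edges=edges, bin_proportions=props,
                         bin_counts=counts)


def sharing_proportion(matrix: VariantMatrix, n_bins: int = 10) -> SharingResult:
    """Proportion of YRI mac>1 variants with a derived allele in >=1
    archaic haplotype.  A zero denominator yields ``empty=True`` and a NaN
    proportion rather than a division error."""
    n_yri = int(matrix.mask("YRI").sum())
    if n_yri == 0:
        raise ValueError("matrix carries no YRI-labelled haplotypes")
    dy = matrix.derived_counts("YRI")
    arch = matrix.genotypes[~matrix.mask("YRI")]
    da = arch.sum(axis=0).astype(np.int64) if arch.shape[0] else np.zeros_like(dy)
    return _sharing_from_counts(dy, da, n_yri, n_bins=n_bins)


def binned_sharing(matrix: VariantMatrix, n_bins: int = 10):
    """Per-bin shared proportions over ``n_bins`` uniform YRI
    derived-frequency bins partitioning (0, 1].  Empty bins report NaN."""
    res = sharing_proportion(matrix, n_bins=n_bins)
    return res.bin_proportions, res.bin_counts


def sharing_distribution(model, n_reps: int, n_loci: int, seed) -> np.ndarray:
    """One sharing proportion per independent replicate of ``n_loci``
    unlinked variants (the per-model simulated distribution)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = _as_seedseq(seed).spawn(n_reps)
    out = np.empty(n_reps)
    base = model.base if isinstance(model, StructuredAncestryModel) else model
    for i, child_seed in enumerate(children):
        dy, da, _, _ = _site_arrays(model, n_loci, child_seed)
        out[i] = _sharing_from_counts(dy, da, base.n_yri).proportion
    return out


def simulate_structured_ancestry(model: StructuredAncestryModel, n_loci: int,
                                 seed) -> SharingResult:
    """Sharing under the structured-ancestry model (single replicate)."""
    dy, da, _, _ = _site_arrays(model, n_loci, seed)
    return _sharing_from_counts(dy, da, model.base.n_yri)


def default_m_grid(lo: float = 1.25e-8, hi: float = 1.25e-3,
                   n_points: int = 33) -> np.ndarray:
    """Log-spaced per-pair migrant-fraction grid.

    The bounds are the classic scan range of the ms parameterization
    M = 4*N*m_total in (0.01, 100) — i.e. total migrant fractions in
    (2.5e-8, 2.5e-3) — divided between the n-1 = 2 source subgroups.
    """
    return np.geomspace(lo, hi, n_points)


def scan_migration(model_template: StructuredAncestryModel,
                   m_grid: Sequence[float], n_loci_per_point: int,
                   target_proportion: float, seed,
                   smooth: str = "isotonic") -> ScanResult:
    """Scan symmetric ancestral migration and locate the largest migrant
    fraction whose simulated sharing still reaches ``target_proportion``.

    Sharing decreases monotonically with m (weaker structure preserves
    less deep polymorphism), so the returned value is the threshold below
    which structure suffices to explain the target.  Because the curve is
    monotone, per-point Monte-Carlo noise is pooled away by default with
    a decreasing isotonic regression (weighted by the per-point
    denominators) before thresholding; ``smooth="none"`` thresholds the
    raw per-point proportions instead.  The full (m, proportion) table is
    returned alongside.
    """
    m_grid = np.asarray(list(m_grid), dtype=float)
    if np.any(np.diff(m_grid) <= 0):
        raise ValueError("m_grid must be sorted ascending")
    if smooth not in ("isotonic", "none"):
        raise ValueError("smooth must be 'isotonic' or 'none'")
    children = _as_seedseq(seed).spawn(len(m_grid))
    rows = []
    for m, child_seed in zip(m_grid, children):
        model = replace(model_template, m=float(m))
        res = simulate_structured_ancestry(model, n_loci_per_point, child_seed)
        rows.append((m, res.proportion, res.numerator, res.denominator))
    table = pd.DataFrame(rows, columns=["m", "proportion", "numerator",
                                        "denominator"])
    if smooth == "isotonic":
        from sklearn.isotonic import IsotonicRegression
        valid = table["denominator"] > 0
        iso = IsotonicRegression(increasing=False)
        fitted = np.full(len(table), np.nan)
        fitted[valid.to_numpy()] = iso.fit_transform(
            np.log(table.loc[valid, "m"]), table.loc[valid, "proportion"],
            sample_weight=table.loc[valid, "denominator"])
        table["fitted"] = fitted
        level = table["fitted"]
    else:
        level = table["proportion"]
    ok = level >= target_proportion
    critical = float(table.loc[ok, "m"].max()) if ok.any() else None
    return ScanResult(critical_m=critical, table=table)


# ---------------------------------------------------------------------------
# site frequency spectra

def site_frequency_spectrum(matrix: VariantMatrix,
                            population: str = "YRI") -> np.ndarray:
    """Counts of variants by derived allele count 1..n-1 in ``population``
    (sites fixed or absent there are excluded)."""
    n = int(matrix.mask(population).sum())
    counts = matrix.derived_counts(population)
    seg = counts[(counts >= 1) & (counts <= n - 1)]
    return np.bincount(seg, minlength=n)[1:n]


def sfs_compare(simulated, observed, population: str = "YRI"):
    """Chi-square goodness of fit of an observed derived-allele-count
    spectrum against simulated-expected proportions.

    ``simulated`` may be a VariantMatrix or a spectrum array; ``observed``
    a spectrum array of the same sample size.  Adjacent cells are pooled
    until every expected count reaches 5.  Returns (statistic, p).
    """
    if isinstance(simulated, VariantMatrix):
        simulated = site_frequency_spectrum(simulated, population)
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(
            f"sample sizes differ: spectra of length {sim.shape} vs {obs.shape}")
    if sim.sum() <= 0 or obs.sum() < 1:
        raise ValueError("spectra must contain variants")
    expected = sim / sim.sum() * obs.sum()
    # pool adjacent frequency classes until each expected cell >= 5
    pooled_o, pooled_e = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if pooled_e:
            pooled_o[-1] += acc_o
            pooled_e[-1] += acc_e
        else:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
    pooled_o = np.asarray(pooled_o)
    pooled_e = np.asarray(pooled_e)
    statistic = float(np.sum((pooled_o - pooled_e) ** 2 / pooled_e))
    df = max(len(pooled_e) - 1, 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, p


# ---------------------------------------------------------------------------
# lineage-count trajectories (input to the chi-square stability statistic)

def lineage_trajectories(model: DemographicModel, n_variants: int,
                         time_grid_years: Sequence[float], seed,
                         min_derived: int = 2,
                         present_freq_range: tuple[float, float] | None = None
                         ) -> pd.DataFrame:
    """Neutral lineage-count trajectories for the focal (YRI) sample.

    For each simulated variant, reports at every grid time the number of
    ancestral lineages of the YRI sample remaining and how many of them
    carry the derived allele (lie below the mutation).  Variants with
    present-day derived count below ``min_derived`` (or with present-day
    frequency outside ``present_freq_range``, when given) are discarded
    and re-simulated until ``n_variants`` records are collected.

    Returns a tidy frame with columns: variant_id, time_years,
    derived_lineages, total_lineages, n_sample, present_derived.
    """
    times_gens = np.asarray(sorted(time_grid_years), dtype=float) \
        / model.generation_time
    years_sorted = np.asarray(sorted(time_grid_years), dtype=float)
    ss = _as_seedseq(seed)
    rows = []
    collected = 0
    batch = max(n_variants, 64)
    while collected < n_variants:
        (child_seed,) = ss.spawn(1)
        dy, _, _, traj = _site_arrays(model, batch, child_seed,
                                      traj_times_gens=times_gens)
        for k in range(batch):
            if collected >= n_variants:
                break
            if dy[k] < min_derived or dy[k] > model.n_yri - min_derived:
                continue
            if present_freq_range is not None:
                f = dy[k] / model.n_yri
                if not present_freq_range[0] <= f <= present_freq_range[1]:
                    continue
            tot, der = traj[k]
            for t_years, t_tot, t_der in zip(years_sorted, tot, der):
                rows.append((collected, t_years, int(t_der), int(t_tot),
                             model.n_yri, int(dy[k])))
            collected += 1
        batch = max(64, int((n_variants - collected) * 1.6) + 16)
    return pd.DataFrame(rows, columns=[
        "variant_id", "time_years", "derived_lineages", "total_lineages",
        "n_sample", "present_derived"])
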