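"""Overdominance signatures: trajectories, linked variation, separability.

Overdominance (heterozygote advantage) with genotype fitnesses
(w_aa, w_Aa, w_AA) = (1, 1+s*h, 1+s) and s*h > max(0, s) drives the
derived allele toward the internal equilibrium p* = h / (2h - 1) (for
the parameterization used here; more generally
p* = (w_Aa - w_aa) / (2 w_Aa - w_aa - w_AA)) and then holds it there.
This module simulates such trajectories forward in time (Wright-Fisher
binomial sampling with viability weights, conditioned by rejection on
segregating at a target age), draws haplotype samples around the focal
mutation from the structured coalescent conditioned on the trajectory
(two allelic classes communicating via recombination), computes the
classical summary-statistic panel (S, Watterson's theta, pi, Tajima's D,
ZnS, Fay & Wu's H, number of distinct haplotypes and haplotype
diversity), and summarizes scenario separability with a PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import msprime
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps

__all__ = [
    "FitnessModel",
    "Trajectory",
    "HaplotypeSample",
    "SummaryStatVector",
    "RejectionBudgetError",
    "genotype_fitness",
    "simulate_trajectory",
    "sample_trajectories",
    "trajectory_variability",
    "structured_coalescent_sample",
    "psecoal_sample",
    "summary_stats",
    "pca_separation",
    "SeparationReport",
]


class RejectionBudgetError(RuntimeError):
    """Rejection sampler exhausted its attempt budget."""


def genotype_fitness(s: float, h: float) -> tuple[float, float, float]:
    """Relative genotype fitnesses (w_aa, w_Aa, w_AA) = (1, 1+s*h, 1+s)."""
    return (1.0, 1.0 + s * h, 1.0 + s)


@dataclass(frozen=True)
class FitnessModel:
    """Selection (s) and dominance (h) coefficients of the focal allele."""

    s: float = 0.0
    h: float = 0.5

    @property
    def fitnesses(self) -> tuple[float, float, float]:
        return genotype_fitness(self.s, self.h)

    @property
    def is_overdominant(self) -> bool:
        w_aa, w_het, w_dd = self.fitnesses
        return w_het > max(w_aa, w_dd)

    @property
    def equilibrium(self) -> float:
        """Deterministic internal equilibrium frequency (NaN if none)."""
        w_aa, w_het, w_dd = self.fitnesses
        denom = 2 * w_het - w_aa - w_dd
        if denom == 0:
            return float("nan")
        p = (w_het - w_aa) / denom
        return p if 0 < p < 1 else float("nan")


@dataclass
class Trajectory:
    """Forward allele-frequency path from emergence to the present.

    ``freqs[0] = 1/(2N)`` at the allele's origin, ``freqs[-1]`` is the
    present-day frequency; all entries lie strictly inside (0, 1).
    """

    freqs: np.ndarray
    n_diploid: int
    fitness: FitnessModel
    attempts: int = 1

    @property
    def age_gens(self) -> int:
        return len(self.freqs) - 1

    @property
    def acceptance_rate(self) -> float:
        return 1.0 / self.attempts

    def backward_freqs(self) -> np.ndarray:
        """Frequencies indexed by generations before present."""
        return self.freqs[::-1].copy()


def _wf_step(p: np.ndarray, w: tuple[float, float, float],
             two_n: int, rng: np.random.Generator) -> np.ndarray:
    w_aa, w_het, w_dd = w
    q = 1.0 - p
    wbar = p * p * w_dd + 2 * p * q * w_het + q * q * w_aa
    p_sel = (p * p * w_dd + p * q * w_het) / wbar
    return rng.binomial(two_n, p_sel) / two_n


@njit(cache=True)
def _reject_wf(two_n, w_aa, w_het, w_dd, age, band_lo, band_hi,
               max_attempts, seed):
    """Rejection sampler: forward WF paths from 1/(2N), accepted when the
    path segregates through ``age`` generations (and lands inside the
    frequency band).  Returns (path, attempts); attempts = -1 signals an
    exhausted budget."""
    np.random.seed(seed)
    path = np.empty(age + 1)
    for attempt in range(1, max_attempts + 1):
        p = 1.0 / two_n
        path[0] = p
        alive = True
        for g in range(1, age + 1):
            q = 1.0 - p
            wbar = p * p * w_dd + 2.0 * p * q * w_het + q * q * w_aa
            p_sel = (p * p * w_dd + p * q * w_het) / wbar
            p = np.random.binomial(two_n, p_sel) / two_n
            if p <= 0.0 or p >= 1.0:
                alive = False
                break
            path[g] = p
        if alive and band_lo <= path[age] <= band_hi:
            return path.copy(), attempt
    return path, -1


def simulate_trajectory(n_diploid: int, fitness: FitnessModel, age_gens: int,
                        seed, final_freq_band: tuple[float, float] | None = None,
                        max_attempts: int = 2_000_000) -> Trajectory:
    """Forward Wright-Fisher trajectory conditioned on segregation.

    Starts at 1/(2N) ``age_gens`` generations before present; rejection
    continues until a path stays strictly inside (0, 1) through the
    present (optionally with present-day frequency inside
    ``final_freq_band``).  Raises :class:`RejectionBudgetError` with the
    observed acceptance rate once ``max_attempts`` paths were tried.
    """
    if age_gens < 1:
        raise ValueError("age_gens must be >= 1")
    if n_diploid < 50:
        raise ValueError("n_diploid must be >= 50")
    rng = np.random.default_rng(seed)
    w_aa, w_het, w_dd = fitness.fitnesses
    lo, hi = final_freq_band if final_freq_band is not None else (0.0, 1.0)
    path, attempts = _reject_wf(
        2 * n_diploid, w_aa, w_het, w_dd, age_gens, lo, hi, max_attempts,
        int(rng.integers(0, 2**31 - 1)))
    if attempts < 0:
        raise RejectionBudgetError(
            f"no segregating trajectory in {max_attempts} attempts "
            f"(acceptance rate < {1.0 / max_attempts:.2e}) for age "
            f"{age_gens} gens, N={n_diploid}, s={fitness.s}, "
            f"h={fitness.h}, band={final_freq_band}")
    return Trajectory(freqs=path, n_diploid=n_diploid, fitness=fitness,
                      attempts=int(attempts))


def sample_trajectories(n: int, n_diploid: int, fitness: FitnessModel,
                        age_gens: int, seed,
                        final_freq_band: tuple[float, float] | None = None,
                        max_attempts: int = 2_000_000) -> list[Trajectory]:
    """``n`` independent conditioned trajectories from spawned substreams."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [simulate_trajectory(n_diploid, fitness, age_gens, child,
                                final_freq_band=final_freq_band,
                                max_attempts=max_attempts)
            for child in children]


def trajectory_variability(trajectories, window: int) -> np.ndarray:
    """Variance of x(t) over the last ``window`` generations of each
    trajectory (the post-equilibration stability measure)."""
    out = []
    for traj in trajectories:
        freqs = traj.freqs if isinstance(traj, Trajectory) else np.asarray(traj)
        if len(freqs) <= window:
            raise ValueError("trajectory shorter than the requested window")
        out.append(float(np.var(freqs[-window:])))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# structured coalescent conditioned on a trajectory

@njit(cache=True)
def _backward_phase(xb, n_diploid, rho, cls0, seed):
    """Discrete-generation backward pass through the trajectory.

    ``xb[g]`` is the derived-allele frequency g generations before the
    present; ``cls0`` the class (1=derived, 0=ancestral) of each sampled
    lineage.  Returns merge events and the surviving lineage/node state at
    the allele's origin.  Within a class of k lineages the per-generation
    coalescence probability is k(k-1)/2 / (2N x_c); a lineage switches
    class by recombination with probability rho/(4N) times the frequency
    of the other class.
    """
    np.random.seed(seed)
    n = cls0.shape[0]
    age = xb.shape[0] - 1
    node_of = np.arange(n)
    cls = cls0.copy()
    active = np.ones(n, np.uint8)
    # merge event log: child_a, child_b, new_node, time
    ev_a = np.empty(2 * n, np.int64)
    ev_b = np.empty(2 * n, np.int64)
    ev_t = np.empty(2 * n)
    n_ev = 0
    next_node = n
    r = rho / (4.0 * n_diploid)
    two_n = 2.0 * n_diploid
    slots = np.empty(n, np.int64)
    for g in range(1, age + 1):
        x = xb[g]
        for c in (1, 0):
            xc = x if c == 1 else 1.0 - x
            k = 0
            for i in range(n):
                if active[i] == 1 and cls[i] == c:
                    slots[k] = i
                    k += 1
            if k >= 2 and xc > 0.0:
                p = 0.5 * k * (k - 1) / (two_n * xc)
                if p > 1.0:
                    p = 1.0
                if np.random.random() < p:
                    a = np.random.randint(k)
                    b = np.random.randint(k - 1)
                    if b >= a:
                        b += 1
                    ia = slots[a]
                    ib = slots[b]
                    ev_a[n_ev] = node_of[ia]
                    ev_b[n_ev] = node_of[ib]
                    ev_t[n_ev] = float(g)
                    node_of[ia] = next_node
                    next_node += 1
                    n_ev += 1
                    active[ib] = 0
        # recombination-driven class switching
        if r > 0.0:
            for i in range(n):
                if active[i] == 1:
                    other = 1.0 - x if cls[i] == 1 else x
                    if np.random.random() < r * other:
                        cls[i] = 1 - cls[i]
    return (ev_a[:n_ev], ev_b[:n_ev], ev_t[:n_ev], node_of, cls, active,
            next_node)


@dataclass
class HaplotypeSample:
    """Binary haplotype matrix around a focal site (1 = derived)."""

    matrix: np.ndarray  # (n_haplotypes, n_sites) uint8
    focal_index: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(np.int64)


def structured_coalescent_sample(trajectory: Trajectory, n: int, theta: float,
                                 rho: float, seed,
                                 n_derived: int | None = None) -> HaplotypeSample:
    """Haplotype sample at a neutral locus linked to the focal mutation.

    The sample is partitioned into derived/ancestral classes by the
    present-day frequency (binomially, unless ``n_derived`` fixes the
    count).  Backward in time lineages coalesce within their class at
    rates scaled by the class size 2N*x(t) (resp. 2N*(1-x(t))) and switch
    class by recombination at rate rho/(4N) times the other class's
    frequency.  At the allele's origin the derived class merges into a
    single lineage that joins the ancestral class; the remainder follows
    a neutral coalescent in a population of size 2N.  Neutral mutations
    are dropped on branches at rate theta/(4N) per generation; the focal
    site itself is appended and marked.
    """
    xb = trajectory.backward_freqs()
    if np.any(xb[:-1] <= 0) or np.any(xb[:-1] >= 1):
        raise ValueError("malformed trajectory: frequency leaves (0,1) "
                         "before the allele's origin")
    rng = np.random.default_rng(seed)
    n_dip = trajectory.n_diploid
    if n_derived is None:
        n_derived = int(rng.binomial(n, xb[0]))
    cls0 = np.zeros(n, dtype=np.int8)
    cls0[:n_derived] = 1
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    ev_a, ev_b, ev_t, node_of, cls, active, next_node = _backward_phase(
        xb, float(n_dip), float(rho), cls0, kernel_seed)
    events = [(int(a), int(b), float(t)) for a, b, t in zip(ev_a, ev_b, ev_t)]
    age = float(len(xb) - 1)
    # at the origin every surviving derived lineage merges into one node,
    # which then joins the ancestral class
    live = [i for i in range(n) if active[i]]
    derived_live = [i for i in live if cls[i] == 1]
    if len(derived_live) >= 2:
        root = derived_live[0]
        for other in derived_live[1:]:
            events.append((int(node_of[root]), int(node_of[other]), age))
            node_of[root] = next_node
            next_node += 1
            active[other] = 0
        live = [i for i in range(n) if active[i]]
    # neutral coalescent (size 2N) past the origin
    t = age
    remaining = [int(node_of[i]) for i in live]
    while len(remaining) > 1:
        k = len(remaining)
        rate = k * (k - 1) / 2 / (2.0 * n_dip)
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        events.append((remaining[i], remaining[j], t))
        remaining[i] = next_node
        next_node += 1
        remaining.pop(j)
    # assemble parent/time arrays
    parent = np.full(next_node, -1, dtype=np.int64)
    ntime = np.zeros(next_node)
    new = n
    for a, b, when in events:
        parent[a] = new
        parent[b] = new
        ntime[new] = when
        new += 1
    # leaf sets per node
    below = np.zeros((next_node, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for node in range(n, next_node):
        kids = np.nonzero(parent == node)[0]
        for kid in kids:
            below[node] |= below[kid]
    # mutations: Poisson on each branch at theta/(4N) per generation
    mu = theta / (4.0 * n_dip)
    columns = []
    for node in range(next_node - 1):  # root has no branch
        if parent[node] == -1:
            continue
        branch = ntime[parent[node]] - ntime[node]
        k_mut = rng.poisson(branch * mu)
        count = int(below[node].sum())
        if k_mut > 0 and 0 < count < n:
            for _ in range(k_mut):
                columns.append(below[node].astype(np.uint8))
    focal = cls0.astype(np.uint8)
    focal_index = None
    matrix_cols = columns
    if 0 < n_derived < n:
        matrix_cols = columns + [focal]
        focal_index = len(columns)
    if not matrix_cols:
        return HaplotypeSample(matrix=np.zeros((n, 0), dtype=np.uint8),
                               focal_index=None)
    return HaplotypeSample(matrix=np.array(matrix_cols, dtype=np.uint8).T,
                           focal_index=focal_index)


def psecoal_sample(n: int = 50, count_range: tuple[int, int] = (22, 28),
                   theta: float = 10.0, seed=None, n_diploid: int = 10_000,
                   min_acceptance: float = 1e-4,
                   condition: bool = True) -> HaplotypeSample:
    """Neutral coalescent sample conditioned on an intermediate-frequency
    site.

    Rejection-samples neutral samples of ``n`` haplotypes until at least
    one segregating site has derived count within ``count_range``; the
    first such site is marked focal.  Aborts with diagnostics if the
    acceptance rate falls below ``min_acceptance``.  With
    ``condition=False`` a single unconditioned sample is returned.
    """
    lo, hi = count_range
    if condition and not (1 <= lo <= hi < n):
        raise ValueError("need 1 <= lo <= hi < n")
    rng = np.random.default_rng(seed)
    max_tries = max(int(2.0 / min_acceptance), 100)
    for attempt in range(1, max_tries + 1):
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, ploidy=1)], ploidy=2,
            population_size=n_diploid,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        mts = msprime.sim_mutations(
            ts, rate=theta / (4.0 * n_diploid), discrete_genome=False,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31 - 1)))
        mat = mts.genotype_matrix().T.astype(np.uint8)
        if not condition:
            return HaplotypeSample(matrix=mat, focal_index=None)
        counts = mat.sum(axis=0)
        qualifying = np.nonzero((counts >= lo) & (counts <= hi))[0]
        if len(qualifying):
            return HaplotypeSample(matrix=mat, focal_index=int(qualifying[0]))
    raise RejectionBudgetError(
        f"pseCoal acceptance rate below {min_acceptance:.1e}: no sample with "
        f"a site at derived count in [{lo}, {hi}] after {max_tries} tries "
        f"(n={n}, theta={theta})")


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class SummaryStatVector:
    """Classical neutrality-test panel for one haplotype sample."""

    s: int
    theta_w: float
    pi: float
    tajimas_d: float
    zns: float
    fay_wu_h: float
    dvk: int
    dvh: float

    def as_series(self) -> pd.Series:
        return pd.Series({
            "S": self.s, "theta_w": self.theta_w, "pi": self.pi,
            "tajimas_d": self.tajimas_d, "zns": self.zns,
            "fay_wu_h": self.fay_wu_h, "dvk": self.dvk, "dvh": self.dvh,
        })


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def summary_stats(sample: HaplotypeSample) -> SummaryStatVector:
    """Compute the panel; monomorphic samples report NaN for the
    statistics that are undefined without segregating sites."""
    mat = sample.matrix
    n = mat.shape[0]
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    counts = mat.sum(axis=0).astype(np.int64)
    seg = (counts >= 1) & (counts <= n - 1)
    mat = mat[:, seg]
    counts = counts[seg]
    s = int(mat.shape[1])
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    # haplotype-level statistics are defined regardless of S
    _, uniq_counts = np.unique(mat, axis=0, return_counts=True)
    dvk = int(len(uniq_counts))
    p_k = uniq_counts / n
    dvh = float(n / (n - 1) * (1.0 - np.sum(p_k ** 2)))
    if s == 0:
        return SummaryStatVector(s=0, theta_w=0.0, pi=0.0,
                                 tajimas_d=float("nan"), zns=float("nan"),
                                 fay_wu_h=float("nan"), dvk=dvk, dvh=dvh)
    theta_w = s / a1
    pairs = n * (n - 1) / 2.0
    pi = float(np.sum(counts * (n - counts)) / pairs)
    theta_h = float(np.sum(2.0 * counts ** 2) / (n * (n - 1)))
    fay_wu_h = pi - theta_h
    e1, e2 = _tajima_constants(n)
    var_d = e1 * s + e2 * s * (s - 1)
    tajimas_d = float((pi - theta_w) / np.sqrt(var_d)) if var_d > 0 else float("nan")
    if s >= 2:
        f = counts / n
        cov = (mat.T @ mat) / n - np.outer(f, f)
        denom = np.sqrt(np.outer(f * (1 - f), f * (1 - f)))
        r2 = (cov / denom) ** 2
        iu = np.triu_indices(s, k=1)
        zns = float(r2[iu].mean())
    else:
        zns = float("nan")
    return SummaryStatVector(s=s, theta_w=float(theta_w), pi=pi,
                             tajimas_d=tajimas_d, zns=zns,
                             fay_wu_h=float(fay_wu_h), dvk=dvk, dvh=dvh)


# ---------------------------------------------------------------------------
# PCA separability

@dataclass
class SeparationReport:
    """Scenario separability on the summary-statistic panel."""

    projections: pd.DataFrame  # scenario, replicate, PC1, PC2
    stat_pvalues: pd.DataFrame  # statistic, p (rank-sum), p_bonferroni
    pc_overlap: dict  # PC name -> overlap coefficient in [0, 1]
    explained_variance_ratio: np.ndarray

    def any_statistic_separates(self, alpha: float = 0.05) -> bool:
        return bool((self.stat_pvalues["p_bonferroni"] < alpha).any())

    def to_dict(self) -> dict:
        return {
            "stat_pvalues": self.stat_pvalues.to_dict(orient="records"),
            "pc_overlap": self.pc_overlap,
            "explained_variance_ratio":
                [float(x) for x in self.explained_variance_ratio],
        }


def _range_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Mean fraction of each group's points inside the other's range."""
    fa = float(np.mean((a >= b.min()) & (a <= b.max())))
    fb = float(np.mean((b >= a.min()) & (b <= a.max())))
    return 0.5 * (fa + fb)


def pca_separation(stats_by_scenario: Mapping[str, pd.DataFrame],
                   n_components: int = 2) -> SeparationReport:
    """Standardize the statistic panel, project with PCA (correlation
    form) and report per-statistic rank-sum p-values with Bonferroni
    correction plus PC1/PC2 overlap between scenarios.

    Rows with undefined (NaN) statistics are dropped listwise.  A warning
    is raised (not an error) when replicates are fewer than statistics.
    """
    from sklearn.decomposition import PCA
    import warnings as _warnings

    scenarios = list(stats_by_scenario)
    if len(scenarios) < 2:
        raise ValueError("need >= 2 scenarios")
    frames = []
    for name in scenarios:
        df = stats_by_scenario[name].dropna().copy()
        if len(df) < 20:
            _warnings.warn(f"scenario {name}: only {len(df)} complete "
                           "replicates", stacklevel=2)
        df["scenario"] = name
        frames.append(df)
    allstats = pd.concat(frames, ignore_index=True)
    stat_cols = [c for c in allstats.columns if c != "scenario"]
    if min(len(f) for f in frames) < len(stat_cols):
        _warnings.warn("fewer replicates than statistics; PCA axes are "
                       "poorly determined", stacklevel=2)
    x = allstats[stat_cols].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - mean[keep]) / sd[keep]
    pca = PCA(n_components=min(n_components, z.shape[1]))
    proj = pca.fit_transform(z)
    projections = pd.DataFrame(
        proj, columns=[f"PC{i + 1}" for i in range(proj.shape[1])])
    projections.insert(0, "scenario", allstats["scenario"].to_numpy())
    rows = []
    a_name, b_name = scenarios[0], scenarios[1]
    a_mask = allstats["scenario"] == a_name
    b_mask = allstats["scenario"] == b_name
    kept_cols = [c for c, k in zip(stat_cols, keep) if k]
    for col in kept_cols:
        res = sps.mannwhitneyu(allstats.loc[a_mask, col],
                               allstats.loc[b_mask, col],
                               alternative="two-sided")
        rows.append((col, float(res.pvalue)))
    pvals = pd.DataFrame(rows, columns=["statistic", "p"])
    pvals["p_bonferroni"] = np.minimum(pvals["p"] * len(pvals), 1.0)
    overlap = {}
    for pc in projections.columns[1:]:
        overlap[pc] = _range_overlap(
            projections.loc[a_mask.to_numpy(), pc].to_numpy(),
            projections.loc[b_mask.to_numpy(), pc].to_numpy())
    return SeparationReport(projections=projections, stat_pvalues=pvals,
                            pc_overlap=overlap,
                            explained_variance_ratio=pca.explained_variance_ratio_)
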