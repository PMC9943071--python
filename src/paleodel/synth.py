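"""Seeded synthetic cohorts with planted ground truth.

Emulates the pipeline's real-data inputs without any download: a phased
three-population cohort (YRI/CEU/CHB at the 1000G phase-3 sample sizes)
carrying biallelic deletions and LD-tagging SNVs, archaic read coverage
with depth drops at planted deletions, archaic SNV genotype records, an
introgressed-SNV list, and the per-SNV annotation tables (ages, stdbeta2
scores, GWAS associations, exons, lineage-count trajectories).

Every deletion is planted with exactly one true evolutionary category:

- human_specific: present in the cohort, absent from all archaic genomes;
- recurrent: present in >=1 archaic genome, but no companion derived
  allele travels with it there;
- introgressed: absent in YRI, carried (with its companions) by >=1
  archaic genome, companions listed as S*-significant;
- ancient: deletion and >=1 companion derived allele on >=1 archaic
  genome, segregating in all three populations.

Coordinates are 0-based half-open internally; VCF emission converts to
1-based.  LD is planted by copying the deletion status onto companion
SNVs and flipping each haplotype with a small probability chosen to land
above the target r^2; the realized r^2 is verified and re-drawn when the
flips undershoot.  All randomness flows from the config seed through
named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import demog
from .ld_classify import DeletionRecord, EvoCategory, SnvTable

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "SyntheticCohort",
    "LDPlantingError",
    "generate_cohort",
    "generate_archaic_reads",
    "generate_annotation_tables",
    "AnnotationTables",
    "generate_all",
    "write_cohort_vcf",
]

CATEGORIES = ("human_specific", "recurrent", "introgressed", "ancient")

#: Observed category proportions in the real deletion dataset
#: (4,863 deletions: 4,288 human-specific, 53 recurrent, 92 introgressed,
#: 430 ancient) — the cohort composition the generator emulates.
DEFAULT_CATEGORY_MIX = (4288 / 4863, 53 / 4863, 92 / 4863, 430 / 4863)


class LDPlantingError(RuntimeError):
    """Companion planting could not reach the requested r^2."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic cohort."""

    n_deletions: int = 1000
    category_mix: tuple[float, float, float, float] = DEFAULT_CATEGORY_MIX
    n_snvs_per_locus: int = 8
    n_companions_per_locus: int = 3
    populations: tuple[tuple[str, int], ...] = (
        ("YRI", 108), ("CEU", 103), ("CHB", 99))
    archaic_genomes: tuple[str, ...] = demog.ARCHAIC_GENOMES
    mean_depth: float = 30.0
    read_length: int = 100
    window_size_range: tuple[int, int] = (1_000, 10_000)
    locus_spacing: int = 200_000
    snv_radius: int = 50_000
    ld_target_r2: float = 0.9
    residual_depth_fraction: float = 0.0
    exonic_fraction: float = 0.15
    gwas_fraction: float = 0.15
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if min(self.category_mix) < 0:
            raise ValueError("category_mix proportions must be >= 0")
        for name, value in (("n_deletions", self.n_deletions),
                            ("n_snvs_per_locus", self.n_snvs_per_locus),
                            ("n_companions_per_locus",
                             self.n_companions_per_locus),
                            ("read_length", self.read_length)):
            if value < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_companions_per_locus > self.n_snvs_per_locus:
            raise ValueError("more companions than SNVs per locus")
        if not 0 <= self.ld_target_r2 <= 1:
            raise ValueError("ld_target_r2 must lie in [0, 1]")
        if not 0 <= self.residual_depth_fraction <= 1:
            raise ValueError("residual_depth_fraction must lie in [0, 1]")
        if self.window_size_range[0] < 100 \
                or self.window_size_range[1] < self.window_size_range[0]:
            raise ValueError("invalid window_size_range")
        for _, n in self.populations:
            if n < 2:
                raise ValueError("each population needs >= 2 diploids")

    @property
    def n_haplotypes(self) -> int:
        return 2 * sum(n for _, n in self.populations)

    def haplotype_populations(self) -> np.ndarray:
        labels = []
        for name, n in self.populations:
            labels += [name] * (2 * n)
        return np.array(labels)

    def sample_names(self) -> list[str]:
        return [f"{name}{i:04d}" for name, n in self.populations
                for i in range(n)]

    def seed_for(self, stream: str) -> np.random.SeedSequence:
        """Named substream seed derived from the root seed."""
        key = zlib.crc32(stream.encode())
        return np.random.SeedSequence([self.seed, key])

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream derived from the root seed."""
        return np.random.default_rng(self.seed_for(stream))


@dataclass
class PlantedTruth:
    """Ground truth for every generated deletion."""

    table: pd.DataFrame  # deletion_id, category, length, exonic, gwas
    archaic_carriers: dict[str, tuple[str, ...]]  # deletion_id -> genomes
    companion_ids: dict[str, tuple[str, ...]]  # deletion_id -> snv ids

    def category_of(self, deletion_id: str) -> str:
        return self.table.set_index("deletion_id").loc[deletion_id, "category"]

    @property
    def categories(self) -> pd.Series:
        return self.table.set_index("deletion_id")["category"]


@dataclass
class SyntheticCohort:
    """Phased cohort plus the archaic-side records needed downstream."""

    snvs: SnvTable
    deletions: list[DeletionRecord]
    truth: PlantedTruth
    archaic_snv_presence: dict[str, set[str]]  # genome -> derived SNV ids
    introgressed_snv_ids: set[str]
    config: SynthConfig

    @property
    def populations(self) -> np.ndarray:
        return self.snvs.populations


def _draw_polymorphic(rng, n_hap: int, freq: float, pop_mask=None,
                      min_count: int = 2) -> np.ndarray:
    """Haplotype vector at ~freq, rejected until mac > 1 (on the masked
    subset when given)."""
    for _ in range(200):
        vec = (rng.random(n_hap) < freq).astype(np.uint8)
        sub = vec if pop_mask is None else vec[pop_mask]
        if min_count <= sub.sum() <= len(sub) - min_count:
            return vec
    raise RuntimeError("could not draw a polymorphic vector; frequency too "
                       f"extreme ({freq}) for n={n_hap}")


def _plant_companion(rng, deletion_vec: np.ndarray, target_r2: float,
                     locus_id: str) -> np.ndarray:
    """Copy the deletion status onto a companion SNV, then flip a balanced
    set of haplotypes to land just above ``target_r2``.

    Flipping c carriers to ancestral and c non-carriers to derived keeps
    the allele frequency p and gives r = 1 - c/(n p (1-p)) exactly in
    expectation, so c is chosen for the midpoint between the target and
    1; if the realized r^2 still undershoots (sampling noise at small
    counts), c shrinks toward a perfect copy.
    """
    from .ld_classify import haplotype_r2

    n = len(deletion_vec)
    p = deletion_vec.mean()
    if p in (0.0, 1.0):
        raise LDPlantingError(
            f"locus {locus_id}: deletion is monomorphic; no companion can "
            "tag it")
    r_target = np.sqrt(min(1.0, 0.5 * (1.0 + target_r2)))
    c = int(round(n * p * (1 - p) * (1.0 - r_target)))
    carriers = np.nonzero(deletion_vec == 1)[0]
    non_carriers = np.nonzero(deletion_vec == 0)[0]
    c = min(c, len(carriers) - 2, len(non_carriers) - 2)
    while c >= 0:
        vec = deletion_vec.copy()
        if c > 0:
            vec[rng.choice(carriers, size=c, replace=False)] = 0
            vec[rng.choice(non_carriers, size=c, replace=False)] = 1
        r2 = haplotype_r2(deletion_vec, vec)
        if not np.isnan(r2) and r2 > target_r2:
            return vec
        c -= 1
    raise LDPlantingError(
        f"locus {locus_id}: no companion reached r^2 > {target_r2} "
        f"(deletion allele count {int(deletion_vec.sum())} of {n})")


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate the phased cohort with planted deletions and companions."""
    rng = config.rng("cohort")
    n_hap = config.n_haplotypes
    pops = config.haplotype_populations()
    yri_mask = pops == "YRI"
    categories = rng.choice(len(CATEGORIES), size=config.n_deletions,
                            p=config.category_mix)
    deletions: list[DeletionRecord] = []
    snv_ids, snv_pos, snv_haps = [], [], []
    truth_rows = []
    carriers_map: dict[str, tuple[str, ...]] = {}
    companions_map: dict[str, tuple[str, ...]] = {}
    archaic_presence: dict[str, set[str]] = {g: set()
                                             for g in config.archaic_genomes}
    wmin, wmax = config.window_size_range
    for i in range(config.n_deletions):
        category = CATEGORIES[categories[i]]
        del_id = f"del{i:05d}"
        length = int(rng.integers(wmin, wmax + 1))
        center = (i + 1) * config.locus_spacing
        start = center - length // 2
        end = start + length
        if category == "introgressed":
            # absent from YRI by definition
            vec = _draw_polymorphic(rng, n_hap,
                                    rng.uniform(0.05, 0.35), ~yri_mask)
            vec[yri_mask] = 0
        elif category == "ancient":
            vec = _draw_polymorphic(rng, n_hap, rng.uniform(0.08, 0.6),
                                    yri_mask)
        else:
            vec = _draw_polymorphic(rng, n_hap, rng.uniform(0.05, 0.6))
        deletion = DeletionRecord(id=del_id, chrom=config.chrom, start=start,
                                  end=end, haplotypes=vec, populations=pops)
        # companions: copies of the deletion vector with flip noise
        comp_ids = []
        offsets = rng.integers(-config.snv_radius + 1000,
                               config.snv_radius - 1000,
                               size=config.n_snvs_per_locus)
        for j in range(config.n_snvs_per_locus):
            snv_id = f"snv{i:05d}_{j}"
            pos = int(center + offsets[j])
            if j < config.n_companions_per_locus:
                hap = _plant_companion(rng, vec, config.ld_target_r2, del_id)
                comp_ids.append(snv_id)
            else:
                hap = _draw_polymorphic(rng, n_hap, rng.uniform(0.05, 0.95))
            snv_ids.append(snv_id)
            snv_pos.append(pos)
            snv_haps.append(hap)
        # archaic side
        if category == "human_specific":
            carriers: tuple[str, ...] = ()
        else:
            k = int(rng.integers(1, 4)) if category == "ancient" \
                else int(rng.integers(1, 3))
            carriers = tuple(sorted(rng.choice(config.archaic_genomes,
                                               size=k, replace=False)))
        if category in ("ancient", "introgressed"):
            for genome in carriers:
                archaic_presence[genome].update(comp_ids)
        exonic = bool(rng.random() < config.exonic_fraction)
        gwas = bool(rng.random() < config.gwas_fraction)
        truth_rows.append((del_id, category, length, exonic, gwas))
        carriers_map[del_id] = carriers
        companions_map[del_id] = tuple(comp_ids)
        deletions.append(deletion)
    snvs = SnvTable(ids=np.array(snv_ids),
                    chroms=np.full(len(snv_ids), config.chrom),
                    positions=np.array(snv_pos, dtype=np.int64),
                    haplotypes=np.array(snv_haps, dtype=np.uint8),
                    populations=pops)
    truth = PlantedTruth(
        table=pd.DataFrame(truth_rows, columns=[
            "deletion_id", "category", "length", "exonic", "gwas"]),
        archaic_carriers=carriers_map, companion_ids=companions_map)
    introgressed_ids = {sid for del_id, cat in
                        zip(truth.table["deletion_id"], truth.table["category"])
                        if cat == "introgressed"
                        for sid in companions_map[del_id]}
    return SyntheticCohort(snvs=snvs, deletions=deletions, truth=truth,
                           archaic_snv_presence=archaic_presence,
                           introgressed_snv_ids=introgressed_ids,
                           config=config)


def generate_archaic_reads(cohort: SyntheticCohort,
                           margin: int = 2_000) -> dict[str, pd.DataFrame]:
    """Per-genome BED-like read intervals around every deletion window.

    Reads (uniform placement, fixed length) are generated at
    ``mean_depth`` over each window plus ``margin``; in a genome carrying
    the deletion, reads overlapping the deleted window are thinned to
    ``residual_depth_fraction`` of full depth (0 by default: a homozygous
    deletion leaves no reads).
    """
    config = cohort.config
    read_len = config.read_length
    residual = config.residual_depth_fraction
    out: dict[str, pd.DataFrame] = {}
    for genome in config.archaic_genomes:
        rng = config.rng(f"reads/{genome}")
        starts_all, ends_all = [], []
        for deletion in cohort.deletions:
            carried = genome in cohort.truth.archaic_carriers[deletion.id]
            lo = deletion.start - margin - (read_len - 1)
            hi = deletion.end + margin
            n_exp = config.mean_depth * (hi - lo) / read_len
            n_reads = rng.poisson(n_exp)
            starts = rng.integers(lo, hi, size=n_reads)
            if carried and residual < 1.0:
                overlaps = (starts < deletion.end) \
                    & (starts + read_len > deletion.start)
                keep = ~overlaps | (rng.random(n_reads) < residual)
                starts = starts[keep]
            starts_all.append(np.sort(starts))
            ends_all.append(starts_all[-1] + read_len)
        out[genome] = pd.DataFrame({
            "chrom": config.chrom,
            "start": np.concatenate(starts_all),
            "end": np.concatenate(ends_all),
        })
    return out


@dataclass
class AnnotationTables:
    """Per-SNV/per-deletion annotation tables keyed like the real inputs."""

    ages: pd.DataFrame  # snv_id, age_years
    scores: pd.DataFrame  # snv_id, stdbeta2
    gwas: pd.DataFrame  # snv_id, trait, p
    exons: pd.DataFrame  # chrom, start, end, gene (0-based half-open)
    introgressed: pd.DataFrame  # snv_id
    trajectories: pd.DataFrame  # demog.lineage_trajectories layout


TRAJECTORY_GRID_YEARS = (1_000.0, 5_000.0, 10_000.0, 50_000.0, 100_000.0)


def generate_annotation_tables(cohort: SyntheticCohort,
                               trajectory_model: demog.DemographicModel | None = None
                               ) -> AnnotationTables:
    """Annotation tables consistent with the planted truth.

    Companions of ancient deletions receive pre-split ages (> 700 ky);
    everything else is younger.  GWAS-flagged deletions get >=1 companion
    association at p < 1e-8 (plus sub-threshold noise rows elsewhere).
    Exonic deletions overlap >=1 emitted exon.  Trajectories are neutral
    coalescent lineage counts on a grid containing 5,000 and 50,000 years.
    """
    config = cohort.config
    rng = config.rng("annotations")
    truth = cohort.truth.table.set_index("deletion_id")
    age_rows, score_rows, gwas_rows, exon_rows = [], [], [], []
    trait_pool = [f"trait_{k:03d}" for k in range(40)]
    for deletion in cohort.deletions:
        info = truth.loc[deletion.id]
        comp_ids = cohort.truth.companion_ids[deletion.id]
        for sid in comp_ids:
            if info["category"] == "ancient":
                age = rng.uniform(8e5, 2e6)
            else:
                age = rng.uniform(2e4, 6e5)
            age_rows.append((sid, age))
            score_rows.append((sid, rng.gamma(2.0, 1.5)))
        if info["gwas"] and comp_ids:
            sid = comp_ids[int(rng.integers(len(comp_ids)))]
            gwas_rows.append((sid, trait_pool[int(rng.integers(len(trait_pool)))],
                              10.0 ** rng.uniform(-12, -8.2)))
        elif comp_ids and rng.random() < 0.3:
            # sub-threshold association noise
            sid = comp_ids[int(rng.integers(len(comp_ids)))]
            gwas_rows.append((sid, trait_pool[int(rng.integers(len(trait_pool)))],
                              10.0 ** rng.uniform(-7.5, -4.0)))
        if info["exonic"]:
            mid = (deletion.start + deletion.end) // 2
            exon_rows.append((config.chrom, mid - 100, mid + 100,
                              f"GENE{deletion.id[3:]}"))
        else:
            # background exon well outside the deletion (never overlaps)
            off = deletion.end + config.snv_radius + 10_000
            exon_rows.append((config.chrom, off, off + 150,
                              f"BGGENE{deletion.id[3:]}"))
    if trajectory_model is None:
        trajectory_model = demog.DemographicModel(n_archaic_haploids=0)
    trajectories = demog.lineage_trajectories(
        trajectory_model, n_variants=len(cohort.deletions),
        time_grid_years=TRAJECTORY_GRID_YEARS,
        seed=config.seed_for("trajectories"))
    # key trajectories by deletion id
    id_map = {i: d.id for i, d in enumerate(cohort.deletions)}
    trajectories["variant_id"] = trajectories["variant_id"].map(id_map)
    return AnnotationTables(
        ages=pd.DataFrame(age_rows, columns=["snv_id", "age_years"]),
        scores=pd.DataFrame(score_rows, columns=["snv_id", "stdbeta2"]),
        gwas=pd.DataFrame(gwas_rows, columns=["snv_id", "trait", "p"]),
        exons=pd.DataFrame(exon_rows, columns=["chrom", "start", "end",
                                               "gene"]),
        introgressed=pd.DataFrame(
            {"snv_id": sorted(cohort.introgressed_snv_ids)}),
        trajectories=trajectories)


# ---------------------------------------------------------------------------
# file emission

def write_cohort_vcf(cohort: SyntheticCohort, path) -> None:
    """Emit the cohort as a phased VCF: SNVs (with AA= ancestral allele)
    and deletions as SVTYPE=DEL records with END.  Internal 0-based
    half-open coordinates become 1-based inclusive on output."""
    config = cohort.config
    samples = config.sample_names()
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={config.chrom}>",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    records = []
    for deletion in cohort.deletions:
        records.append((deletion.start, deletion.id, "N", "<DEL>",
                        f"SVTYPE=DEL;END={deletion.end};AA=N",
                        deletion.haplotypes))
    for k in range(cohort.snvs.n_snvs):
        records.append((int(cohort.snvs.positions[k]),
                        str(cohort.snvs.ids[k]), "A", "G", "AA=A",
                        cohort.snvs.haplotypes[k]))
    records.sort(key=lambda r: (r[0], r[1]))
    for pos0, rec_id, ref, alt, info, haps in records:
        gts = "\t".join(f"{haps[2 * i]}|{haps[2 * i + 1]}"
                        for i in range(len(samples)))
        lines.append(f"{config.chrom}\t{pos0 + 1}\t{rec_id}\t{ref}\t{alt}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_bed(df: pd.DataFrame, path, columns: Sequence[str]) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(columns))


def generate_all(config: SynthConfig, outdir) -> dict[str, Path]:
    """Run every generator and write the full input bundle to ``outdir``.

    Emits: cohort VCF, per-genome read BEDs, deletion-window BED, archaic
    SNV presence TSV, and the annotation tables (ages, scores, GWAS,
    exons, introgressed SNVs, trajectories, planted truth).
    Returns the path of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    reads = generate_archaic_reads(cohort)
    tables = generate_annotation_tables(cohort)
    paths: dict[str, Path] = {}

    paths["cohort_vcf"] = outdir / "cohort.vcf"
    write_cohort_vcf(cohort, paths["cohort_vcf"])
    windows = pd.DataFrame({
        "chrom": [d.chrom for d in cohort.deletions],
        "start": [d.start for d in cohort.deletions],
        "end": [d.end for d in cohort.deletions],
        "id": [d.id for d in cohort.deletions]})
    paths["windows_bed"] = outdir / "deletion_windows.bed"
    _write_bed(windows, paths["windows_bed"], ["chrom", "start", "end", "id"])
    for genome, df in reads.items():
        key = f"reads_{genome}"
        paths[key] = outdir / f"reads_{genome}.bed"
        _write_bed(df, paths[key], ["chrom", "start", "end"])
    presence_rows = [(g, sid) for g, ids in cohort.archaic_snv_presence.items()
                     for sid in sorted(ids)]
    paths["archaic_snvs"] = outdir / "archaic_snv_presence.tsv"
    pd.DataFrame(presence_rows, columns=["genome", "snv_id"]).to_csv(
        paths["archaic_snvs"], sep="\t", index=False)
    for name, df in (("ages", tables.ages), ("scores", tables.scores),
                     ("gwas", tables.gwas), ("introgressed",
                                             tables.introgressed),
                     ("trajectories", tables.trajectories)):
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    paths["exons"] = outdir / "exons.bed"
    _write_bed(tables.exons, paths["exons"], ["chrom", "start", "end", "gene"])
    paths["truth"] = outdir / "planted_truth.tsv"
    truth = cohort.truth.table.copy()
    truth["archaic_carriers"] = truth["deletion_id"].map(
        lambda d: ",".join(cohort.truth.archaic_carriers[d]))
    truth["companions"] = truth["deletion_id"].map(
        lambda d: ",".join(cohort.truth.companion_ids[d]))
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
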