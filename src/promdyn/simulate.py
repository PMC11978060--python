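"""Synthetic annotation and junction-count generator with ground truth.

Emulates a multi-organ developmental RNA-seq design at desk scale: genes
with one to four promoters (non-overlapping first exons spliced onto
shared downstream exons, so each promoter owns distinct first-intron
junctions), negative-binomial unique junction counts whose means follow
planted cubic log2 trajectories over 16 developmental stages with 2
replicates in 2 organs, per-sample depth (size) factors spanning a 4x
range, and optional planted internal promoters, cross-gene shared
junctions, undefined-strand records and novel junctions to exercise the
pipeline's exclusion rules.

Per promoter and sample the expected count is
``size_factor * baseline * 2**c(u)`` with ``c`` a cubic in normalized
time ``u in [0, 1]`` drawn from the trajectory library (flat, up, down,
hump); counts are negative binomial with a common dispersion and are
split across the promoter's junctions by fixed proportions. The planted
major promoter carries the highest baseline; the per-gene pattern of
(major, minor) trends is drawn from a configurable mix over the eight
pair categories. All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    PromoterCatalog,
    TranscriptModel,
    build_promoters,
    flag_internal,
)

__all__ = [
    "SimulationConfig",
    "AnnotationTruth",
    "GroundTruth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_count_table",
    "end_to_end_fixture",
    "write_gtf",
]

DEFAULT_STAGES = (
    "e10.5", "e11.5", "e12.5", "e13.5", "e14.5", "e15.5", "e16.5", "e17.5",
    "e18.5", "P0", "P1", "P3", "P7", "P14", "P28", "P63",
)

PAIR_CATEGORIES_8 = (
    "Up_Up", "Up_Flat", "Flat_Up", "Down_Down",
    "Down_Flat", "Flat_Down", "Up_Down", "Down_Up",
)

_TREND_TO_TRAJ = {"Up": "up", "Down": "down", "Flat": "flat"}


def _trajectory_coefficients(name: str, a: float) -> tuple[float, float, float, float]:
    """Cubic coefficients (c0..c3) in normalized time u in [0,1], log2 units."""
    if name == "flat":
        return (0.0, 0.0, 0.0, 0.0)
    if name == "up":
        return (-a / 2.0, a, 0.0, 0.0)
    if name == "down":
        return (a / 2.0, -a, 0.0, 0.0)
    if name == "hump":
        return (0.0, 2.0 * a, -2.0 * a, 0.0)
    raise ValueError(f"unknown trajectory {name!r}")


def _eval_trajectory(coef: tuple[float, float, float, float], u: np.ndarray) -> np.ndarray:
    c0, c1, c2, c3 = coef
    return c0 + c1 * u + c2 * u**2 + c3 * u**3


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator (see module docstring)."""

    n_genes: int = 150
    # probability of a gene having 1..4 promoters (multi-promoter marginal ~24%)
    promoter_weights: tuple[float, ...] = (0.76, 0.15, 0.06, 0.03)
    organs: tuple[str, ...] = ("heart", "liver")
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 2
    baseline_mean: float = 100.0      # expected unique reads, major promoter
    minor_ratio: float = 0.3          # minor baseline relative to major
    weak_minor_rate: float = 0.15     # minors planted near-silent (inactive)
    weak_ratio: float = 0.002         # weak-minor baseline relative to major
    dispersion: float = 0.05          # NB dispersion (var = mu + disp*mu^2)
    effect_size: float = 2.0          # log2 amplitude of planted trajectories
    size_factor_log2_range: float = 1.0  # per-sample depth in 2^[-r, r]
    dynamic_fraction: float = 0.5     # genes with a planted non-flat pattern
    organ_specific_fraction: float = 0.3  # dynamic genes dynamic in one organ only
    pair_pattern_mix: dict | None = None  # over the eight categories; uniform if None
    first_tss_major_prob: float = 0.75    # P(planted major is the 5'-most promoter)
    merged_isoform_rate: float = 0.15     # extra transcript with overlapping first exon
    n_internal_genes: int = 2
    n_shared_junction_pairs: int = 1      # extra gene pairs sharing a junction
    noncoding_rate: float = 0.2
    undefined_strand_rate: float = 0.1    # SJ lines written with strand code 0
    n_novel_junctions: int = 3            # uncatalogued junctions per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.baseline_mean <= 0 or self.minor_ratio <= 0:
            raise ValueError("baseline means must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.stages) < 4:
            raise ValueError("need >= 4 stages for cubic dynamics")
        if abs(sum(self.promoter_weights) - 1.0) > 1e-9:
            raise ValueError("promoter_weights must sum to 1")
        if self.pair_pattern_mix is not None:
            bad = set(self.pair_pattern_mix) - set(PAIR_CATEGORIES_8)
            if bad:
                raise ValueError(f"unknown pair categories: {sorted(bad)}")

    def pattern_probs(self) -> tuple[np.ndarray, list[str]]:
        if self.pair_pattern_mix is None:
            p = np.full(len(PAIR_CATEGORIES_8), 1.0 / len(PAIR_CATEGORIES_8))
            return p, list(PAIR_CATEGORIES_8)
        cats = list(PAIR_CATEGORIES_8)
        p = np.array([self.pair_pattern_mix.get(c, 0.0) for c in cats], dtype=float)
        if p.sum() <= 0:
            raise ValueError("pair_pattern_mix has zero total weight")
        return p / p.sum(), cats


@dataclass
class AnnotationTruth:
    """Annotation-side truth: models, catalog, and planted promoter facts."""

    transcripts: list[TranscriptModel]
    catalog: PromoterCatalog
    promoters: pd.DataFrame  # indexed by promoter_id
    gtf_text: str


@dataclass
class GroundTruth:
    promoters: pd.DataFrame      # promoter_id -> gene, baseline, is_major_planted, ...
    trajectories: pd.DataFrame   # (promoter_id, organ) -> trajectory, trend
    pairs: pd.DataFrame          # planted (major, minor) category per gene and organ
    samples: pd.DataFrame        # design incl. true size_factor


_GENE_SPAN = 20_000


def _gene_geometry(gene_idx: int, n_promoters: int, strand: str):
    """Exon intervals for one gene; promoter k=0 is the 5'-most (rank 1)."""
    base = 10_000 + gene_idx * _GENE_SPAN
    w = 200  # exon width - 1
    if strand == "+":
        firsts = [
            (base + k * 1_200, base + k * 1_200 + w) for k in range(n_promoters)
        ]
        shared = [
            (base + n_promoters * 1_200 + 3_000, base + n_promoters * 1_200 + 3_000 + w),
            (base + n_promoters * 1_200 + 6_000, base + n_promoters * 1_200 + 6_000 + w),
        ]
    else:
        shared = [(base, base + w), (base + 2_000, base + 2_000 + w)]
        firsts = [
            (base + 5_000 + (n_promoters - 1 - k) * 1_200,
             base + 5_000 + (n_promoters - 1 - k) * 1_200 + w)
            for k in range(n_promoters)
        ]
        shared = shared[::-1]  # transcription order high->low: nearest shared first
    return firsts, shared


def simulate_annotation(cfg: SimulationConfig) -> AnnotationTruth:
    """Generate transcript models + GTF text and the promoter-level truth."""
    rng = np.random.default_rng([cfg.seed, 0])
    models: list[TranscriptModel] = []
    planted_rows = []  # (gene_id, planted_rank, representative tid, internal, n_junc)
    n_prom_choices = np.arange(1, len(cfg.promoter_weights) + 1)

    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    for i, gene_id in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        k_prom = int(rng.choice(n_prom_choices, p=cfg.promoter_weights))
        firsts, shared = _gene_geometry(i, k_prom, strand)
        for k in range(k_prom):
            fe = firsts[k]
            if strand == "+":
                exons = tuple(sorted([fe] + shared))
            else:
                exons = tuple(sorted(shared + [fe]))
            biotype = (
                "protein_coding"
                if rng.random() >= cfg.noncoding_rate
                else "retained_intron"
            )
            tid = f"t_{gene_id}_p{k + 1}_a"
            models.append(
                TranscriptModel(tid, gene_id, "chr1", strand, exons, biotype)
            )
            n_junc = 1
            if rng.random() < cfg.merged_isoform_rate:
                # second isoform with an overlapping (shifted) first exon:
                # merges into the same promoter but adds a distinct junction
                shift = 100
                fe2 = (fe[0] + shift, fe[1] + shift)
                if strand == "+":
                    exons2 = tuple(sorted([fe2] + shared))
                else:
                    fe2 = (fe[0] - shift, fe[1] - shift)
                    exons2 = tuple(sorted(shared + [fe2]))
                models.append(
                    TranscriptModel(
                        f"t_{gene_id}_p{k + 1}_b", gene_id, "chr1", strand,
                        exons2, biotype,
                    )
                )
                n_junc = 2
            planted_rows.append(
                dict(gene_id=gene_id, planted_rank=k + 1, rep_tid=tid,
                     internal_planted=False, n_junctions=n_junc)
            )
        if i < cfg.n_internal_genes:
            # extra isoform whose first exon sits inside the gene body,
            # overlapping a shared (non-first) exon: an internal promoter
            ds = sorted(shared)
            mid = ds[0] if strand == "+" else ds[-1]
            fe_int = (mid[0] - 50, mid[0] + 100)
            tail = ds[1] if strand == "+" else ds[0]
            exons = tuple(sorted([fe_int, tail]))
            tid = f"t_{gene_id}_int_a"
            models.append(
                TranscriptModel(tid, gene_id, "chr1", strand, exons, "protein_coding")
            )
            planted_rows.append(
                dict(gene_id=gene_id, planted_rank=None, rep_tid=tid,
                     internal_planted=True, n_junctions=1)
            )

    # extra gene pairs sharing an identical first-intron junction
    for j in range(cfg.n_shared_junction_pairs):
        base = 10_000 + (cfg.n_genes + j) * _GENE_SPAN
        ga, gb = f"gS{j:02d}a", f"gS{j:02d}b"
        fe_a = (base, base + 200)
        fe_b = (base + 50, base + 200)           # same end -> same junction start
        ex2_a = (base + 3_000, base + 3_200)
        ex2_b = (base + 3_000, base + 3_100)     # same start -> same junction end
        ta, tb = f"t_{ga}_p1_a", f"t_{gb}_p1_a"
        models.append(TranscriptModel(ta, ga, "chr1", "+", (fe_a, ex2_a), "protein_coding"))
        models.append(TranscriptModel(tb, gb, "chr1", "+", (fe_b, ex2_b), "protein_coding"))
        planted_rows.append(dict(gene_id=ga, planted_rank=1, rep_tid=ta,
                                 internal_planted=False, n_junctions=1))
        planted_rows.append(dict(gene_id=gb, planted_rank=1, rep_tid=tb,
                                 internal_planted=False, n_junctions=1))

    catalog = flag_internal(build_promoters(models))
    tid_to_pid = {
        tid: p.promoter_id for p in catalog for tid in p.transcript_ids
    }
    truth = pd.DataFrame(planted_rows)
    truth["promoter_id"] = truth["rep_tid"].map(tid_to_pid)
    truth = truth.set_index("promoter_id").drop(columns=["rep_tid"])
    return AnnotationTruth(
        transcripts=models,
        catalog=catalog,
        promoters=truth,
        gtf_text=write_gtf(models),
    )


def write_gtf(models: list[TranscriptModel]) -> str:
    """Render transcript models as Ensembl-dialect GTF text."""
    lines = []
    for m in sorted(models, key=lambda m: (m.gene_id, m.transcript_id)):
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'transcript_biotype "{m.biotype}";'
        )
        span = (m.exons[0][0], m.exons[-1][1])
        lines.append(
            "\t".join(
                [m.chromosome, "promdyn_sim", "transcript", str(span[0]),
                 str(span[1]), ".", m.strand, ".", attrs]
            )
        )
        for start, end in m.exons:
            lines.append(
                "\t".join(
                    [m.chromosome, "promdyn_sim", "exon", str(start), str(end),
                     ".", m.strand, ".", attrs]
                )
            )
    return "\n".join(lines) + "\n"


def _make_design(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for organ in cfg.organs:
        for t, stage in enumerate(cfg.stages):
            for rep in range(1, cfg.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{organ}_{stage}_r{rep}",
                        "organ": organ,
                        "stage_label": stage,
                        "time_ordinal": t,
                        "sex": "M" if rep % 2 == 1 else "F",
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    cfg: SimulationConfig, ann: AnnotationTruth
) -> tuple[dict[str, list[str]], GroundTruth]:
    """Draw per-sample junction counts for the simulated annotation.

    Returns ``(sj_lines_by_sample, truth)`` where each sample maps to the
    text lines of its STAR ``SJ.out.tab`` file.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    design = _make_design(cfg)
    design["size_factor"] = 2.0 ** rng.uniform(
        -cfg.size_factor_log2_range, cfg.size_factor_log2_range, size=len(design)
    )
    u = design["time_ordinal"].to_numpy(dtype=float) / max(len(cfg.stages) - 1, 1)

    pattern_probs, pattern_cats = cfg.pattern_probs()
    catalog = ann.catalog
    by_gene = catalog.by_gene()

    prom_rows = []
    traj_rows = []
    pair_rows = []
    # per promoter: dict organ -> trajectory coefficients
    coef_of: dict[str, dict[str, tuple]] = {}
    baseline_of: dict[str, float] = {}

    for gene_id, plist in sorted(by_gene.items()):
        regular = [p for p in plist if not p.internal]
        internal = [p for p in plist if p.internal]
        # planted major: 5'-most with prob first_tss_major_prob, else a
        # downstream promoter uniformly
        if len(regular) == 0:
            continue
        if len(regular) == 1 or rng.random() < cfg.first_tss_major_prob:
            major = regular[0]
        else:
            major = regular[int(rng.integers(1, len(regular)))]
        minors = [p for p in regular if p.promoter_id != major.promoter_id]

        dynamic = rng.random() < cfg.dynamic_fraction
        if dynamic and cfg.organs and rng.random() < cfg.organ_specific_fraction:
            dyn_organs = {cfg.organs[int(rng.integers(0, len(cfg.organs)))]}
        else:
            dyn_organs = set(cfg.organs)

        # trend labels per promoter (same planted pattern in every dynamic organ)
        if not dynamic:
            trends = {p.promoter_id: "Flat" for p in regular}
            planted_cat = None
        elif not minors:
            traj = ("up", "down", "hump")[int(rng.integers(0, 3))]
            trends = {major.promoter_id: {"up": "Up", "down": "Down", "hump": "Hump"}[traj]}
            planted_cat = None
        else:
            planted_cat = pattern_cats[int(rng.choice(len(pattern_cats), p=pattern_probs))]
            major_trend, minor_trend = planted_cat.split("_")
            trends = {major.promoter_id: major_trend}
            trends[minors[0].promoter_id] = minor_trend
            for extra in minors[1:]:
                trends[extra.promoter_id] = ("Up", "Down", "Flat")[int(rng.integers(0, 3))]

        # minors not carrying the planted pair pattern may be near-silent
        pair_minor = minors[0].promoter_id if (minors and planted_cat) else None
        weak: set[str] = set()
        for p in minors:
            if p.promoter_id != pair_minor and rng.random() < cfg.weak_minor_rate:
                weak.add(p.promoter_id)

        for p in regular + internal:
            if p.promoter_id == major.promoter_id:
                baseline = cfg.baseline_mean
            elif p.promoter_id in weak:
                baseline = cfg.baseline_mean * cfg.weak_ratio
            else:
                baseline = cfg.baseline_mean * cfg.minor_ratio
            baseline_of[p.promoter_id] = baseline
            trend = "Flat" if p.promoter_id in weak else trends.get(p.promoter_id, "Flat")
            traj_name = {"Up": "up", "Down": "down", "Flat": "flat", "Hump": "hump"}[trend]
            coef_of[p.promoter_id] = {}
            for organ in cfg.organs:
                organ_traj = traj_name if organ in dyn_organs else "flat"
                coef_of[p.promoter_id][organ] = _trajectory_coefficients(
                    organ_traj, cfg.effect_size
                )
                traj_rows.append(
                    dict(
                        promoter_id=p.promoter_id,
                        organ=organ,
                        trajectory=organ_traj,
                        trend=(trend if organ in dyn_organs else "Flat"),
                    )
                )
            prom_rows.append(
                dict(
                    promoter_id=p.promoter_id,
                    gene_id=gene_id,
                    baseline=baseline,
                    is_major_planted=bool(
                        p.promoter_id == major.promoter_id and not p.internal
                    ),
                    internal=p.internal,
                )
            )
        if minors and planted_cat is not None:
            for organ in dyn_organs:
                pair_rows.append(
                    dict(
                        gene_id=gene_id,
                        organ=organ,
                        major_promoter_id=major.promoter_id,
                        minor_promoter_id=minors[0].promoter_id,
                        category=planted_cat,
                    )
                )

    # draw counts per promoter x sample, split over its junctions
    all_junctions = sorted({j for p in catalog for j in p.first_intron_junctions})
    sj_lines: dict[str, list[str]] = {}
    sf = design["size_factor"].to_numpy()
    organ_arr = design["organ"].to_numpy()

    junc_counts: dict = {
        s: {} for s in design["sample_id"]
    }  # sample -> junction -> reads
    for p in catalog:
        pid = p.promoter_id
        if pid not in baseline_of:
            continue
        log2_traj = np.empty(len(design))
        for organ in cfg.organs:
            mask = organ_arr == organ
            log2_traj[mask] = _eval_trajectory(coef_of[pid][organ], u[mask])
        mu = sf * baseline_of[pid] * 2.0 ** log2_traj
        totals = _nb_draw(rng, mu, cfg.dispersion)
        juncs = sorted(p.first_intron_junctions)
        if not juncs:
            continue
        props = np.array([2.0 ** (-k) for k in range(len(juncs))])
        props /= props.sum()
        for si, sample in enumerate(design["sample_id"]):
            total = int(totals[si])
            if total == 0:
                continue
            if len(juncs) == 1:
                split = [total]
            else:
                split = rng.multinomial(total, props)
            for j, c in zip(juncs, split):
                if c > 0:
                    junc_counts[sample][j] = junc_counts[sample].get(j, 0) + int(c)

    # novel junctions in intergenic space, to be ignored by the pipeline
    novel_base = 10_000 + (cfg.n_genes + cfg.n_shared_junction_pairs + 2) * _GENE_SPAN
    novel = [
        (f"chr1", novel_base + 500 * k + 1, novel_base + 500 * k + 300, "+")
        for k in range(cfg.n_novel_junctions)
    ]

    strand_code = {"+": 1, "-": 2, ".": 0}
    for sample in design["sample_id"]:
        lines = []
        for j in sorted(junc_counts[sample]):
            count = junc_counts[sample][j]
            code = strand_code[j.strand]
            if rng.random() < cfg.undefined_strand_rate:
                code = 0
            multi = int(rng.poisson(1))
            lines.append(
                f"{j.chromosome}\t{j.intron_start}\t{j.intron_end}\t{code}\t1\t1\t"
                f"{count}\t{multi}\t30"
            )
        for chrom, s, e, strand in novel:
            c = int(rng.poisson(5))
            if c > 0:
                lines.append(
                    f"{chrom}\t{s}\t{e}\t{strand_code[strand]}\t0\t0\t{c}\t0\t20"
                )
        sj_lines[sample] = lines

    truth = GroundTruth(
        promoters=pd.DataFrame(prom_rows).set_index("promoter_id"),
        trajectories=pd.DataFrame(traj_rows),
        pairs=pd.DataFrame(
            pair_rows,
            columns=["gene_id", "organ", "major_promoter_id",
                     "minor_promoter_id", "category"],
        ),
        samples=design,
    )
    return sj_lines, truth


def simulate_count_table(cfg: SimulationConfig):
    """Simulate and quantify in memory: returns (annotation truth, ground
    truth, PromoterCountTable) without touching the filesystem."""
    from .quantification import assign_junctions, count_promoter_reads, parse_sj_lines

    ann = simulate_annotation(cfg)
    sj_lines, truth = simulate_counts(cfg, ann)
    index = assign_junctions(ann.catalog)
    table = count_promoter_reads(
        {s: parse_sj_lines(lines) for s, lines in sj_lines.items()}, index
    )
    return ann, truth, table


def end_to_end_fixture(
    cfg: SimulationConfig, outdir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write a self-contained fixture: GTF, per-sample SJ.out.tab files,
    design TSV (with paths) and truth TSVs. Refuses a non-empty output
    directory unless ``force``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    (outdir / "sj").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    ann = simulate_annotation(cfg)
    sj_lines, truth = simulate_counts(cfg, ann)

    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text(ann.gtf_text)

    design = truth.samples.copy()
    paths = []
    for sample in design["sample_id"]:
        p = outdir / "sj" / f"{sample}.SJ.out.tab"
        p.write_text("\n".join(sj_lines[sample]) + ("\n" if sj_lines[sample] else ""))
        paths.append(str(p.relative_to(outdir)))
    design["path"] = paths
    design_path = outdir / "design.tsv"
    design.drop(columns=["size_factor"]).to_csv(design_path, sep="\t", index=False)

    fmt = "%.10g"
    ann.promoters.to_csv(outdir / "truth" / "promoters_annotation.tsv", sep="\t")
    truth.promoters.to_csv(outdir / "truth" / "promoters.tsv", sep="\t", float_format=fmt)
    truth.trajectories.to_csv(
        outdir / "truth" / "trajectories.tsv", sep="\t", index=False
    )
    truth.pairs.to_csv(outdir / "truth" / "pairs.tsv", sep="\t", index=False)
    truth.samples.to_csv(
        outdir / "truth" / "samples.tsv", sep="\t", index=False, float_format=fmt
    )
    return {
        "gtf": gtf_path,
        "design": design_path,
        "sj_dir": outdir / "sj",
        "truth_dir": outdir / "truth",
    }
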