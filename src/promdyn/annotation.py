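"""Promoter catalog construction from a GTF annotation.

A *promoter* is a transcription-initiation unit: the group of a gene's
transcripts whose first exons overlap on the genome. Transcripts with
identical or closely spaced transcription start sites (TSSs) are assumed
to be driven by the same promoter, so first-exon intervals are merged by
single-linkage overlap and the 5'-most member TSS represents the group.
Promoters whose first exon overlaps a non-first (internal) exon of a
sibling isoform are flagged *internal* and excluded from quantification,
because junction reads over their first intron cannot be distinguished
from splicing of the longer isoform.

Coordinates are 1-based inclusive throughout (GTF convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionKey",
    "TranscriptModel",
    "Promoter",
    "PromoterCatalog",
    "GTFParseError",
    "AnnotationError",
    "parse_gtf",
    "build_promoters",
    "flag_internal",
    "build_catalog",
]


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


class AnnotationError(ValueError):
    """Raised when transcript models violate catalog preconditions."""


class JunctionKey(NamedTuple):
    """A first-intron splice junction, 1-based inclusive intron bounds."""

    chromosome: str
    intron_start: int
    intron_end: int
    strand: str


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons on the genome plus identity fields.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted by genomic
    coordinate. Transcription order runs left-to-right on '+' and
    right-to-left on '-'.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon start {start} > end {end}"
                )
            if prev_end is not None and start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def first_exon(self) -> tuple[int, int]:
        """First exon in transcription order (5' end of the transcript)."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def tss(self) -> int:
        start, end = self.first_exon
        return start if self.strand == "+" else end

    @property
    def non_first_exons(self) -> tuple[tuple[int, int], ...]:
        return self.exons[1:] if self.strand == "+" else self.exons[:-1]

    @property
    def first_intron_junction(self) -> JunctionKey | None:
        """Junction spanning the first intron, or None for mono-exonic models."""
        if len(self.exons) < 2:
            return None
        if self.strand == "+":
            up, down = self.exons[0], self.exons[1]
        else:
            up, down = self.exons[-1], self.exons[-2]
            up, down = down, up  # genomic left/right; intron lies between them
        return JunctionKey(self.chromosome, up[1] + 1, down[0] - 1, self.strand)


@dataclass(frozen=True)
class Promoter:
    promoter_id: str
    gene_id: str
    chromosome: str
    strand: str
    tss: int
    first_exon_span: tuple[int, int]
    tss_rank: int
    internal: bool
    transcript_ids: frozenset[str]
    first_intron_junctions: frozenset[JunctionKey]


@dataclass
class PromoterCatalog:
    """All promoters of an annotation plus the transcript models behind them."""

    promoters: list[Promoter]
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    def by_gene(self) -> dict[str, list[Promoter]]:
        out: dict[str, list[Promoter]] = {}
        for p in self.promoters:
            out.setdefault(p.gene_id, []).append(p)
        for plist in out.values():
            plist.sort(key=lambda p: p.tss_rank)
        return out

    def get(self, promoter_id: str) -> Promoter:
        for p in self.promoters:
            if p.promoter_id == promoter_id:
                return p
        raise KeyError(promoter_id)

    def gene_map(self) -> pd.Series:
        """promoter_id -> gene_id, in catalog order."""
        return pd.Series(
            {p.promoter_id: p.gene_id for p in self.promoters}, name="gene_id"
        )

    def transcript_biotypes(self) -> pd.Series:
        return pd.Series(
            {t.transcript_id: t.biotype for t in self.transcripts.values()},
            name="biotype",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.promoters:
            rows.append(
                {
                    "promoter_id": p.promoter_id,
                    "gene_id": p.gene_id,
                    "chrom": p.chromosome,
                    "strand": p.strand,
                    "tss": p.tss,
                    "tss_rank": p.tss_rank,
                    "internal": p.internal,
                    "n_transcripts": len(p.transcript_ids),
                    "junctions": ";".join(
                        f"{j.chromosome}:{j.intron_start}-{j.intron_end}:{j.strand}"
                        for j in sorted(p.first_intron_junctions)
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "promoter_id",
                "gene_id",
                "chrom",
                "strand",
                "tss",
                "tss_rank",
                "internal",
                "n_transcripts",
                "junctions",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def tss_bed(self) -> pd.DataFrame:
        """BED6 of TSS positions (0-based half-open single-base intervals)."""
        rows = [
            {
                "chrom": p.chromosome,
                "start": p.tss - 1,
                "end": p.tss,
                "name": p.promoter_id,
                "score": 0,
                "strand": p.strand,
            }
            for p in self.promoters
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    def to_bed(self, path: str | Path) -> None:
        self.tss_bed().to_csv(path, sep="\t", index=False, header=False)


def _validate_gtf_lines(path: str | Path) -> None:
    # pyranges does the heavy parsing; this pass exists to attribute
    # malformed lines to their line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )


def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF file into transcript models (exon features only).

    The transcript biotype is taken from the ``transcript_biotype``
    attribute when present, else ``"unknown"``. Transcripts without exon
    features are skipped with a warning.
    """
    import pyranges as pr

    _validate_gtf_lines(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    gr = pr.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else gr
    if df.empty:
        return []
    exons = df[df["Feature"] == "exon"].copy()
    declared = set()
    if "transcript_id" in df.columns:
        declared = set(
            df.loc[df["Feature"] == "transcript", "transcript_id"].dropna()
        )
    if exons.empty:
        if declared:
            warnings.warn(
                f"{len(declared)} transcript(s) with no exon features were skipped"
            )
        return []
    has_biotype = "transcript_biotype" in exons.columns
    models: list[TranscriptModel] = []
    for tid, grp in exons.groupby("transcript_id", sort=True, observed=True):
        grp = grp.sort_values("Start")
        biotype = "unknown"
        if has_biotype:
            vals = grp["transcript_biotype"].dropna()
            if len(vals):
                biotype = str(vals.iloc[0])
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(grp["gene_id"].iloc[0]),
                chromosome=str(grp["Chromosome"].iloc[0]),
                strand=str(grp["Strand"].iloc[0]),
                # pyranges uses 0-based half-open; GTF is 1-based inclusive
                exons=tuple(
                    (int(s) + 1, int(e)) for s, e in zip(grp["Start"], grp["End"])
                ),
                biotype=biotype,
            )
        )
    missing = declared - {m.transcript_id for m in models}
    if missing:
        warnings.warn(
            f"{len(missing)} transcript(s) with no exon features were skipped"
        )
    return models


def _merge_overlapping(
    items: list[tuple[tuple[int, int], str]]
) -> list[list[str]]:
    """Single-linkage merge of 1-based inclusive intervals; returns clusters
    of transcript ids. Two intervals merge when they share >= 1 base."""
    items = sorted(items, key=lambda iv: iv[0])
    clusters: list[list[str]] = []
    cur_end = None
    for (start, end), tid in items:
        if cur_end is not None and start <= cur_end:
            clusters[-1].append(tid)
            cur_end = max(cur_end, end)
        else:
            clusters.append([tid])
            cur_end = end
    return clusters


def build_promoters(transcripts: Iterable[TranscriptModel]) -> PromoterCatalog:
    """Group transcripts into promoters by overlapping first exons.

    Within each gene, first-exon intervals are merged by single-linkage
    overlap; the promoter TSS is the 5'-most member TSS and promoters are
    ranked 1..K from 5' to 3' in transcription order. Internal flags are
    not set here; see :func:`flag_internal`.
    """
    tmap = {t.transcript_id: t for t in transcripts}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in tmap.values():
        by_gene.setdefault(t.gene_id, []).append(t)

    promoters: list[Promoter] = []
    for gene_id in sorted(by_gene):
        gts = by_gene[gene_id]
        strands = {t.strand for t in gts}
        chroms = {t.chromosome for t in gts}
        if len(strands) > 1 or len(chroms) > 1:
            raise AnnotationError(
                f"gene {gene_id}: transcripts on conflicting strands/chromosomes"
            )
        strand = gts[0].strand
        clusters = _merge_overlapping(
            [(t.first_exon, t.transcript_id) for t in gts]
        )
        entries = []
        for tids in clusters:
            members = [tmap[tid] for tid in tids]
            starts = [m.first_exon[0] for m in members]
            ends = [m.first_exon[1] for m in members]
            tss = min(starts) if strand == "+" else max(ends)
            junctions = frozenset(
                m.first_intron_junction
                for m in members
                if m.first_intron_junction is not None
            )
            entries.append((tss, (min(starts), max(ends)), frozenset(tids), junctions))
        # rank 1..K from 5' to 3' in transcription order
        entries.sort(key=lambda e: e[0], reverse=(strand == "-"))
        for rank, (tss, span, tids, junctions) in enumerate(entries, start=1):
            promoters.append(
                Promoter(
                    promoter_id=f"{gene_id}:p{rank}",
                    gene_id=gene_id,
                    chromosome=gts[0].chromosome,
                    strand=strand,
                    tss=tss,
                    first_exon_span=span,
                    tss_rank=rank,
                    internal=False,
                    transcript_ids=tids,
                    first_intron_junctions=junctions,
                )
            )
    return PromoterCatalog(promoters=promoters, transcripts=tmap)


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def flag_internal(catalog: PromoterCatalog) -> PromoterCatalog:
    """Flag promoters whose first-exon span overlaps a non-first exon of
    any transcript of the same gene. Cross-gene overlaps are ignored."""
    internal_exons: dict[str, list[tuple[int, int]]] = {}
    for t in catalog.transcripts.values():
        internal_exons.setdefault(t.gene_id, []).extend(t.non_first_exons)
    flagged = []
    for p in catalog.promoters:
        hit = any(
            _intervals_overlap(p.first_exon_span, exon)
            for exon in internal_exons.get(p.gene_id, [])
        )
        flagged.append(replace(p, internal=hit))
    return PromoterCatalog(promoters=flagged, transcripts=dict(catalog.transcripts))


def build_catalog(path: str | Path) -> PromoterCatalog:
    """parse_gtf + build_promoters + flag_internal in one call."""
    return flag_internal(build_promoters(parse_gtf(path)))
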