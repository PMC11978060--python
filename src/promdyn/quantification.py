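"""Junction-file parsing and promoter-level unique-read counting.

Promoter activity is indexed by sequencing reads that span a promoter's
first intron. Only *unique* junction reads are counted, and only
junctions attributable to exactly one promoter ("promoter-unique") are
used; junctions shared between promoters are excluded rather than split.
A promoter is quantifiable iff it is not internal and has at least one
promoter-unique junction — promoters of mono-exonic transcripts have no
junction and are non-quantifiable. Non-quantifiable promoters carry
missing values (not zeros) in the count table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import JunctionKey, PromoterCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionRecord",
    "JunctionIndex",
    "PromoterCountTable",
    "JunctionParseError",
    "read_star_sj",
    "parse_sj_lines",
    "read_junction_bed",
    "read_design",
    "assign_junctions",
    "count_promoter_reads",
    "count_from_design",
]

STAR_STRAND = {0: ".", 1: "+", 2: "-"}

DESIGN_COLUMNS = ["sample_id", "organ", "stage_label", "time_ordinal", "sex", "replicate"]


class JunctionParseError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction observed in a sample.

    ``key.strand`` may be '.' (undefined, STAR code 0) and is resolved
    against the catalog at assignment time.
    """

    key: JunctionKey
    unique_reads: int
    multi_reads: int = 0
    annotated: bool = True


def read_star_sj(path: str | Path) -> list[JunctionRecord]:
    """Parse a STAR ``SJ.out.tab`` file.

    Columns: chrom, intron start (1-based), intron end (1-based), strand
    code (0 undefined / 1 '+' / 2 '-'), intron motif, annotated flag,
    unique reads, multi-mapping reads, max overhang.
    """
    with open(path) as fh:
        return parse_sj_lines(fh, source=str(path))


def parse_sj_lines(lines: Iterable[str], source: str = "<memory>") -> list[JunctionRecord]:
    """Parse STAR SJ.out.tab-format lines from any iterable of strings."""
    records: list[JunctionRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise JunctionParseError(
                f"{source}: line {lineno}: expected 9 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
            strand_code = int(fields[3])
            unique, multi = int(fields[6]), int(fields[7])
        except ValueError as exc:
            raise JunctionParseError(
                f"{source}: line {lineno}: non-integer field"
            ) from exc
        if unique < 0 or multi < 0:
            raise JunctionParseError(f"{source}: line {lineno}: negative read count")
        if strand_code not in STAR_STRAND:
            raise JunctionParseError(
                f"{source}: line {lineno}: bad strand code {strand_code}"
            )
        records.append(
            JunctionRecord(
                key=JunctionKey(fields[0], start, end, STAR_STRAND[strand_code]),
                unique_reads=unique,
                multi_reads=multi,
                annotated=bool(int(fields[5])),
            )
        )
    return records


def read_junction_bed(path: str | Path) -> list[JunctionRecord]:
    """Parse the 6-column junction BED dialect
    (chrom, start0, end0, name, unique_reads, strand), where the 0-based
    half-open interval covers the intron."""
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise JunctionParseError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            unique = int(fields[4])
            if unique < 0:
                raise JunctionParseError(f"{path}: line {lineno}: negative count")
            records.append(
                JunctionRecord(
                    key=JunctionKey(
                        fields[0], int(fields[1]) + 1, int(fields[2]), fields[5]
                    ),
                    unique_reads=unique,
                )
            )
    return records


def read_junction_file(path: str | Path) -> list[JunctionRecord]:
    """Dispatch on extension: ``.bed`` -> BED dialect, else STAR SJ.out.tab."""
    if str(path).endswith(".bed"):
        return read_junction_bed(path)
    return read_star_sj(path)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (TSV). Required columns:
    sample_id, organ, stage_label, time_ordinal, sex, replicate; a
    ``path`` column points at each sample's junction file."""
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("design table contains duplicate sample_id values")
    return design


@dataclass
class JunctionIndex:
    """Junction -> promoter assignment with uniqueness flags."""

    junction_to_promoters: dict[JunctionKey, frozenset[str]]
    unique_junctions: dict[str, frozenset[JunctionKey]]  # promoter -> its unique junctions
    quantifiable: pd.Series  # promoter_id -> bool, catalog order
    # (chrom, start, end) -> strands present, for resolving undefined strand
    _coords: dict[tuple[str, int, int], set[str]] = field(default_factory=dict)

    def resolve(self, key: JunctionKey) -> JunctionKey | None:
        """Resolve an input junction against the catalog; returns the
        catalog key or None if unmatched/ambiguous."""
        if key.strand in ("+", "-"):
            return key if key in self.junction_to_promoters else None
        strands = self._coords.get((key.chromosome, key.intron_start, key.intron_end))
        if not strands:
            return None
        if len(strands) > 1:
            warnings.warn(
                f"undefined-strand junction {key.chromosome}:{key.intron_start}-"
                f"{key.intron_end} matches catalog entries on both strands; dropped"
            )
            return None
        return JunctionKey(
            key.chromosome, key.intron_start, key.intron_end, next(iter(strands))
        )


def assign_junctions(catalog: PromoterCatalog) -> JunctionIndex:
    """Map each catalogued first-intron junction to the promoters that
    contain it; only junctions owned by exactly one promoter count.

    Internal promoters are non-quantifiable regardless of junctions, and
    their junctions still poison sharing (a junction seen in an internal
    promoter and one regular promoter is not promoter-unique).
    """
    j2p: dict[JunctionKey, set[str]] = {}
    for p in catalog:
        for j in p.first_intron_junctions:
            j2p.setdefault(j, set()).add(p.promoter_id)
    frozen = {j: frozenset(ps) for j, ps in j2p.items()}
    unique: dict[str, set[JunctionKey]] = {p.promoter_id: set() for p in catalog}
    for j, ps in frozen.items():
        if len(ps) == 1:
            unique[next(iter(ps))].add(j)
    quantifiable = pd.Series(
        {
            p.promoter_id: (not p.internal) and len(unique[p.promoter_id]) > 0
            for p in catalog
        },
        name="quantifiable",
    )
    coords: dict[tuple[str, int, int], set[str]] = {}
    for j in frozen:
        coords.setdefault((j.chromosome, j.intron_start, j.intron_end), set()).add(
            j.strand
        )
    return JunctionIndex(
        junction_to_promoters=frozen,
        unique_junctions={p: frozenset(js) for p, js in unique.items()},
        quantifiable=quantifiable,
        _coords=coords,
    )


@dataclass
class PromoterCountTable:
    """Raw unique-read counts, promoters x samples.

    ``counts`` holds NaN for non-quantifiable promoters (missing, not
    zero); quantifiable promoters always hold integers (as floats).
    """

    counts: pd.DataFrame
    quantifiable: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "quantifiable", self.quantifiable)
        out.to_csv(path, sep="\t", index_label="promoter_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PromoterCountTable":
        df = pd.read_csv(path, sep="\t", index_col="promoter_id")
        quantifiable = df.pop("quantifiable").astype(bool)
        return cls(counts=df, quantifiable=quantifiable)


def count_promoter_reads(
    sample_junctions: Mapping[str, Iterable[JunctionRecord]],
    index: JunctionIndex,
) -> PromoterCountTable:
    """Count unique junction reads per quantifiable promoter and sample.

    Each promoter's count is the sum of ``unique_reads`` over its
    promoter-unique junctions present in that sample (absent junction
    contributes 0). Multi-mapped reads and novel (uncatalogued)
    junctions are ignored.
    """
    promoter_ids = list(index.quantifiable.index)
    samples = list(sample_junctions)
    # junction -> owning promoter, restricted to promoter-unique junctions
    owner: dict[JunctionKey, str] = {}
    for pid, js in index.unique_junctions.items():
        for j in js:
            owner[j] = pid
    cols = {}
    for sample, records in sample_junctions.items():
        acc: dict[str, int] = {}
        for rec in records:
            key = index.resolve(rec.key)
            if key is None:
                continue
            pid = owner.get(key)
            if pid is not None:
                acc[pid] = acc.get(pid, 0) + rec.unique_reads
        cols[sample] = acc
    mat = pd.DataFrame(
        {s: pd.Series(c, dtype=float) for s, c in cols.items()},
        columns=samples,
    ).reindex(promoter_ids).fillna(0.0)
    mat.index.name = "promoter_id"
    mat[~index.quantifiable] = np.nan
    return PromoterCountTable(counts=mat, quantifiable=index.quantifiable.copy())


def count_from_design(
    design: pd.DataFrame, index: JunctionIndex, base_dir: str | Path | None = None
) -> PromoterCountTable:
    """Load each sample's junction file from the design table's ``path``
    column and count promoter reads."""
    if "path" not in design.columns:
        raise ValueError("design table has no 'path' column")
    per_sample: dict[str, list[JunctionRecord]] = {}
    for _, row in design.iterrows():
        p = Path(row["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        if not p.exists():
            raise FileNotFoundError(
                f"junction file for sample {row['sample_id']!r} not found: {p}"
            )
        per_sample[str(row["sample_id"])] = read_junction_file(p)
    return count_promoter_reads(per_sample, index)
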