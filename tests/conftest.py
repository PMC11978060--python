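import numpy as np
import pandas as pd
import pytest

from promdyn import (
    SimulationConfig,
    TranscriptModel,
    build_promoters,
    end_to_end_fixture,
    flag_internal,
    simulate_annotation,
    simulate_counts,
)


def tm(tid, gene, strand, exons, chrom="chr1", biotype="protein_coding"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons), biotype)


@pytest.fixture(scope="session")
def two_promoter_catalog():
    """One '+' gene with two promoters (disjoint first exons, shared
    downstream exon) -> distinct first-intron junctions."""
    transcripts = [
        tm("t1", "gA", "+", [(100, 200), (1000, 1100), (2000, 2100)]),
        tm("t2", "gA", "+", [(400, 500), (1000, 1100), (2000, 2100)]),
    ]
    return flag_internal(build_promoters(transcripts))


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_data(default_cfg):
    """Default synthetic study: annotation truth + SJ lines + ground truth."""
    ann = simulate_annotation(default_cfg)
    sj_lines, truth = simulate_counts(default_cfg, ann)
    return ann, sj_lines, truth


@pytest.fixture(scope="session")
def sim_fixture_dir(tmp_path_factory, default_cfg):
    out = tmp_path_factory.mktemp("fixture") / "sim"
    end_to_end_fixture(default_cfg, out)
    return out


def sj_lines_frame(lines):
    """Independent minimal reading of SJ.out.tab lines for oracles."""
    rows = []
    for line in lines:
        f = line.split("\t")
        rows.append(
            dict(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                strand={0: ".", 1: "+", 2: "-"}[int(f[3])],
                unique=int(f[6]),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "unique"])
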