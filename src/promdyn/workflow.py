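"""End-to-end orchestration: annotate -> quantify -> classify -> per-organ
dynamics -> patterns -> cross-organ labels, driven by one config.

Each stage writes plain TSV outputs into the run directory and the run
ends with a JSON manifest recording config, per-file SHA-256 digests and
sizes. Stage failures are re-raised as :class:`StageError` naming the
stage. Outputs are deterministic given identical config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import build_catalog
from .quantification import assign_junctions, count_from_design, read_design
from .activity import (
    classify_promoters,
    compute_activity,
    multi_active_genes,
)
from .dynamics import (
    DynamicPromoterDetector,
    bootstrap_trajectory,
    compare_ddp_vs_flat,
    stage_mean_profiles,
)
from .patterns import aggregate_categories, build_pattern_calls, relative_usage_trajectory, coding_fraction
from .comparative import ddp_id_sets, label_common_specific, split_by_direction

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all"]

_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    gtf: str
    design: str
    outdir: str
    inactive_threshold: float = 0.25
    contribution_threshold: float = 0.10
    degree: int = 3
    r2_min: float = 0.3
    alpha: float = 0.05
    n_bootstrap: int = 1000
    pseudocount: float = 1.0
    related_groups: list = field(default_factory=lambda: [["brain", "cerebellum"]])
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.inactive_threshold):
            raise ValueError("inactive_threshold must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must be in [0, 1]")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run the whole pipeline; returns the manifest dict (also written to
    ``<outdir>/manifest.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: list[Path] = []

    def _out(name: str) -> Path:
        p = outdir / name
        outputs.append(p)
        return p

    # -- annotate -----------------------------------------------------
    try:
        catalog = build_catalog(cfg.gtf)
        catalog.to_tsv(_out("promoters.tsv"))
        catalog.to_bed(_out("tss.bed"))
    except Exception as exc:  # noqa: BLE001 - reattributed with stage name
        raise StageError("annotate", exc) from exc
    stages.append("annotate")

    # -- quantify -----------------------------------------------------
    try:
        design = read_design(cfg.design)
        index = assign_junctions(catalog)
        table = count_from_design(design, index, base_dir=Path(cfg.design).parent)
        table.to_tsv(_out("counts.tsv"))
    except Exception as exc:
        raise StageError("quantify", exc) from exc
    stages.append("quantify")

    # -- classify -----------------------------------------------------
    try:
        counts = table.counts
        am = compute_activity(counts, catalog.gene_map(), pseudocount=cfg.pseudocount)
        am.to_dir(outdir)
        outputs += [
            outdir / "absolute_activity.tsv", outdir / "relative_activity.tsv",
            outdir / "gene_expression.tsv", outdir / "size_factors.tsv",
        ]
        labels = classify_promoters(
            am.absolute, catalog, inactive_threshold=cfg.inactive_threshold
        )
        labels.to_csv(_out("promoter_classes.tsv"), sep="\t", float_format=_FMT)
        multi = sorted(
            multi_active_genes(labels, am.relative, cfg.contribution_threshold)
        )
        pd.Series(multi, name="gene_id").to_csv(
            _out("multi_active_genes.tsv"), sep="\t", index=False
        )
    except Exception as exc:
        raise StageError("classify", exc) from exc
    stages.append("classify")

    # -- ddp (per organ) ---------------------------------------------
    ddp_results: dict[str, pd.DataFrame] = {}
    gene_results: dict[str, pd.DataFrame] = {}
    try:
        design_ix = design.set_index("sample_id")
        for organ in sorted(design["organ"].unique()):
            samples = design_ix.index[design_ix["organ"] == organ]
            times = design_ix.loc[samples, "time_ordinal"].to_numpy()
            det = DynamicPromoterDetector(
                degree=cfg.degree, alpha=cfg.alpha, r2_min=cfg.r2_min
            )
            det.fit(am.absolute[samples], times)
            ddp_results[organ] = det.results_
            det.results_.to_csv(
                _out(f"ddp_{organ}.tsv"), sep="\t", float_format=_FMT
            )
            profiles = stage_mean_profiles(
                am.absolute[samples], design_ix.loc[samples, "time_ordinal"]
            )
            compare_ddp_vs_flat(profiles, det.results_["is_ddp"]).to_csv(
                _out(f"ddp_vs_flat_{organ}.tsv"), sep="\t", float_format=_FMT
            )
            bands = []
            for direction in ("Up", "Down"):
                ids = det.results_.index[det.results_["direction"] == direction]
                if len(ids) == 0:
                    continue
                band = bootstrap_trajectory(
                    profiles.loc[ids], n_boot=cfg.n_bootstrap, seed=cfg.seed
                )
                band.insert(0, "group", direction)
                bands.append(band)
            if bands:
                pd.concat(bands).rename_axis("time_ordinal").to_csv(
                    _out(f"trajectory_bands_{organ}.tsv"), sep="\t",
                    float_format=_FMT,
                )
            gdet = DynamicPromoterDetector(
                degree=cfg.degree, alpha=cfg.alpha, r2_min=cfg.r2_min
            )
            gdet.fit(am.gene_expression[samples], times)
            gene_results[organ] = gdet.results_
    except Exception as exc:
        raise StageError("ddp", exc) from exc
    stages.append("ddp")

    # -- patterns (per organ) ----------------------------------------
    calls_by_organ: dict[str, pd.DataFrame] = {}
    try:
        for organ, results in ddp_results.items():
            calls = build_pattern_calls(labels, results, gene_results[organ])
            calls_by_organ[organ] = calls
            calls.to_csv(_out(f"patterns_{organ}.tsv"), sep="\t", index=False)
            aggregate_categories(calls).to_csv(
                _out(f"pattern_counts_{organ}.tsv"), sep="\t"
            )
            usage = relative_usage_trajectory(
                am.relative[design_ix.index[design_ix["organ"] == organ]],
                labels,
                design_ix[design_ix["organ"] == organ].reset_index(),
            )
            usage.to_csv(
                _out(f"relative_usage_{organ}.tsv"), sep="\t", float_format=_FMT
            )
            coding_fraction(catalog, calls).to_csv(
                _out(f"coding_fraction_{organ}.tsv"), sep="\t", float_format=_FMT
            )
    except Exception as exc:
        raise StageError("patterns", exc) from exc
    stages.append("patterns")

    # -- crossorgan ---------------------------------------------------
    try:
        if len(ddp_results) >= 2:
            gene_of = catalog.gene_map()
            ddp_genes = ddp_id_sets(ddp_results, gene_of, level="gene")
            cross = label_common_specific(
                ddp_genes,
                related_groups=[frozenset(g) for g in cfg.related_groups],
                known_organs=set(design["organ"]),
            )
            cross.to_csv(_out("cross_organ_labels.tsv"), sep="\t")
            split_by_direction(cross, ddp_results, gene_of).to_csv(
                _out("cross_organ_direction_counts.tsv"), sep="\t"
            )
            stages.append("crossorgan")
        else:
            logger.info("single organ: cross-organ stage skipped")
    except Exception as exc:
        raise StageError("crossorgan", exc) from exc

    manifest = {
        "promdyn_version": __version__,
        "config": asdict(cfg),
        "stages": stages,
        "outputs": {
            str(p.relative_to(outdir)): {
                "sha256": _digest(p),
                "bytes": p.stat().st_size,
            }
            for p in outputs
            if p.exists()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
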