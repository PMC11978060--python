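"""Common vs organ-specific classification of dynamic-promoter genes.

Genes carrying a DDP are compared across organs by gene identifier. A
gene dynamic in at least two organs is *common*, one dynamic in exactly
one organ is *organ-specific*, and — because the two tissues are so
closely related — a gene dynamic exclusively in the brain and cerebellum
is set aside (``excluded_pair``) rather than counted as common. The
related-organ group is configurable.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ddp_id_sets",
    "label_common_specific",
    "split_by_direction",
    "DEFAULT_RELATED_GROUP",
]

DEFAULT_RELATED_GROUP = frozenset({"brain", "cerebellum"})


def ddp_id_sets(
    ddp_tables_by_organ: dict[str, pd.DataFrame],
    gene_of_promoter: pd.Series | None = None,
    level: str = "gene",
) -> dict[str, set[str]]:
    """Per-organ DDP identifier sets from fit tables (rows indexed by
    promoter_id, with an ``is_ddp`` column).

    ``level='gene'`` (the default comparison unit) maps promoters to
    genes via ``gene_of_promoter``; ``level='promoter'`` keeps promoter
    identifiers for a stricter promoter-level comparison.
    """
    if level not in ("gene", "promoter"):
        raise ValueError("level must be 'gene' or 'promoter'")
    out = {}
    for organ, table in ddp_tables_by_organ.items():
        ids = table.index[table["is_ddp"]] if "is_ddp" in table.columns else []
        if level == "gene":
            if gene_of_promoter is None:
                raise ValueError("gene-level sets need gene_of_promoter")
            out[organ] = set(gene_of_promoter.reindex(ids).dropna())
        else:
            out[organ] = set(ids)
    return out


def label_common_specific(
    ddp_genes_by_organ: dict[str, set[str]],
    related_groups: list[frozenset[str]] | None = None,
    known_organs: set[str] | None = None,
) -> pd.DataFrame:
    """Label every DDP gene common / organ_specific:<organ> / excluded_pair.

    Parameters
    ----------
    ddp_genes_by_organ : organ name -> set of gene ids with >= 1 DDP there.
    related_groups : organ groups whose exclusive sharing does not count
        as common (default: the brain + cerebellum pair).
    known_organs : if given, organ names are validated against it.

    Returns a DataFrame indexed by gene_id with columns organs_with_ddp
    (comma-joined, sorted), n_organs, label.
    """
    if len(ddp_genes_by_organ) < 2:
        raise ValueError("cross-organ labelling needs at least 2 organs")
    if known_organs is not None:
        unknown = set(ddp_genes_by_organ) - set(known_organs)
        if unknown:
            raise ValueError(f"unknown organ name(s): {sorted(unknown)}")
    if related_groups is None:
        related_groups = [DEFAULT_RELATED_GROUP]
    related_groups = [frozenset(g) for g in related_groups]

    organs_of: dict[str, set[str]] = {}
    for organ, genes in ddp_genes_by_organ.items():
        for g in genes:
            organs_of.setdefault(g, set()).add(organ)

    rows = {}
    for gene, organs in organs_of.items():
        if len(organs) == 1:
            label = f"organ_specific:{next(iter(organs))}"
        elif frozenset(organs) in related_groups:
            label = "excluded_pair"
        else:
            label = "common"
        rows[gene] = {
            "organs_with_ddp": ",".join(sorted(organs)),
            "n_organs": len(organs),
            "label": label,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "gene_id"
    if out.empty:
        out = pd.DataFrame(columns=["organs_with_ddp", "n_organs", "label"])
        out.index.name = "gene_id"
    return out


def split_by_direction(
    labels: pd.DataFrame,
    ddp_tables_by_organ: dict[str, pd.DataFrame],
    gene_of_promoter: pd.Series,
) -> pd.DataFrame:
    """Contingency counts of common/specific x Up/Down DDPs per organ.

    ``ddp_tables_by_organ`` are per-organ fit tables (with is_ddp and
    direction); each DDP promoter contributes one count in its organ,
    bucketed by its own trend direction and its gene's cross-organ label
    (excluded_pair genes are tallied separately).
    """
    rows = []
    for organ, table in sorted(ddp_tables_by_organ.items()):
        counts = {
            ("common", "Up"): 0, ("common", "Down"): 0,
            ("specific", "Up"): 0, ("specific", "Down"): 0,
            ("excluded_pair", "Up"): 0, ("excluded_pair", "Down"): 0,
        }
        ddps = (
            table[table["is_ddp"]] if "is_ddp" in table.columns else table.iloc[0:0]
        )
        for pid, row in ddps.iterrows():
            gene = gene_of_promoter.get(pid)
            if gene is None or gene not in labels.index:
                continue
            lab = labels.loc[gene, "label"]
            bucket = (
                "common" if lab == "common"
                else "excluded_pair" if lab == "excluded_pair"
                else "specific"
            )
            if row["direction"] in ("Up", "Down"):
                counts[(bucket, row["direction"])] += 1
        rows.append(
            {
                "organ": organ,
                **{f"{b}_{d.lower()}": v for (b, d), v in counts.items()},
            }
        )
    cols = [
        "organ",
        "common_up", "common_down",
        "specific_up", "specific_down",
        "excluded_pair_up", "excluded_pair_down",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("organ")
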