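"""Integration of differential methylation with differential expression.

Cross-tabulates, per sequence context and genic region, the direction
of methylation change (hyper/hypo) of DMR-associated genes against the
direction of their expression change (up/down), and screens the
gene-body CG-hypermethylated & up-regulated cell against user-supplied
gene lists (process sets, QTL genes) to nominate candidates.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .io import CONTEXTS

REGIONS = ("upstream", "body", "downstream")


def dmr_deg_overlap(assignments: pd.DataFrame,
                    de_table: pd.DataFrame) -> dict:
    """Venn counts of DMR-associated genes vs differentially expressed
    genes, plus the sets themselves."""
    gene_assign = assignments[assignments["ftype"] == "gene"] \
        if "ftype" in assignments.columns else assignments
    dmr_genes = set(gene_assign["feature_id"])
    degs = set(de_table.loc[de_table["status"] != "ns", "gene_id"])
    inter = dmr_genes & degs
    return {
        "dmr_assoc_genes": dmr_genes,
        "degs": degs,
        "intersection": inter,
        "n_dmr_assoc": len(dmr_genes),
        "n_deg": len(degs),
        "n_intersection": len(inter),
        "n_union": len(dmr_genes | degs),
    }


def concordance_table(assignments: pd.DataFrame,
                      de_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of DMR-associated DEGs per (context, region, methylation
    direction, expression direction) cell.

    A gene contributes to every cell its assignments support (a
    boundary-spanning DMR puts the gene in two regions) but only once
    per cell.  Returns all 3 contexts x 3 regions x {hyper,hypo} x
    {up,down} cells, including empty ones, with the member gene ids.
    """
    status = de_table.set_index("gene_id")["status"]
    gene_assign = assignments[assignments["ftype"] == "gene"] \
        if "ftype" in assignments.columns else assignments
    merged = gene_assign.merge(status.rename("expr_dir"),
                               left_on="feature_id", right_index=True,
                               how="inner")
    merged = merged[merged["expr_dir"].isin(("up", "down"))]
    rows = []
    for context in CONTEXTS:
        for region in REGIONS:
            for mdir in ("hyper", "hypo"):
                for edir in ("up", "down"):
                    cell = merged[(merged["context"] == context)
                                  & (merged["region"] == region)
                                  & (merged["direction"] == mdir)
                                  & (merged["expr_dir"] == edir)]
                    genes = sorted(set(cell["feature_id"]))
                    rows.append({
                        "context": context, "region": region,
                        "meth_direction": mdir, "expr_direction": edir,
                        "n_genes": len(genes),
                        "gene_ids": ",".join(genes),
                    })
    return pd.DataFrame(rows)


def candidate_screen(concordance: pd.DataFrame,
                     de_table: pd.DataFrame,
                     gene_lists: Mapping[str, Iterable[str]],
                     context: str = "CG", region: str = "body",
                     meth_direction: str = "hyper",
                     expr_direction: str = "up") -> pd.DataFrame:
    """Candidate genes: the (CG, body, hyper, up) concordance cell
    intersected with user-supplied gene ID lists.

    ``gene_lists`` maps a list label (e.g. a process or QTL set) to
    gene ids; ids absent from the concordance universe are skipped.
    Returns one row per candidate with its log2 fold change and list
    memberships.
    """
    cell = concordance[(concordance["context"] == context)
                       & (concordance["region"] == region)
                       & (concordance["meth_direction"] == meth_direction)
                       & (concordance["expr_direction"] == expr_direction)]
    in_cell: set[str] = set()
    for ids in cell["gene_ids"]:
        if ids:
            in_cell.update(ids.split(","))
    log2fc = de_table.set_index("gene_id")["log2fc"]
    rows = []
    for label, ids in gene_lists.items():
        for gene_id in ids:
            if gene_id in in_cell:
                rows.append({
                    "gene_id": gene_id, "context": context,
                    "region": region, "meth_direction": meth_direction,
                    "expr_direction": expr_direction,
                    "log2fc": float(log2fc.get(gene_id, float("nan"))),
                    "list": label,
                })
    out = pd.DataFrame(rows, columns=["gene_id", "context", "region",
                                      "meth_direction", "expr_direction",
                                      "log2fc", "list"])
    if out.empty:
        return out
    out = (out.groupby(["gene_id", "context", "region", "meth_direction",
                        "expr_direction", "log2fc"], dropna=False)["list"]
           .apply(lambda s: ",".join(sorted(s))).reset_index()
           .rename(columns={"list": "lists"}))
    return out.sort_values("gene_id", ignore_index=True)
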