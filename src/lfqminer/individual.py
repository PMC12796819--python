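"""Single-protein lookup and bar-plot data (mean +/- SEM per condition).

Lookup accepts either a gene symbol (case-insensitive, ignoring the
``.N`` uniquification suffix — an ambiguous symbol returns every suffixed
row) or a UniProt accession from the protein-group id list.  Bar values are
on the log2 scale, the scale the statistics are computed on; SEM uses the
n-1 sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ContrastResult
from .errors import NotFoundError, ValidationError
from .pathway_miner import strip_suffix
from .preprocess import ExpressionDataset


@dataclass
class BarPlotData:
    protein_id: str
    stats: pd.DataFrame  # index condition (display order); columns mean, sem, n
    p_table: pd.DataFrame  # index contrast id; columns log2fc, p, padj, significant
    colors: dict[str, str] = field(default_factory=dict)


def lookup(ds: ExpressionDataset, query: str) -> list[str]:
    """Find dataset rows by gene symbol or UniProt accession.

    Returns all matching row ids (multiple when a duplicated symbol was
    suffix-uniquified); raises NotFoundError when nothing matches.
    """
    q = query.strip().casefold()
    if not q:
        raise NotFoundError(query)
    hits = [rid for rid in ds.ids if strip_suffix(rid).casefold() == q]
    if hits:
        return hits
    for rid, accs in zip(ds.ids, ds.annotations["protein_ids"]):
        if q in (a.strip().casefold() for a in str(accs).split(";")):
            hits.append(rid)
    if not hits:
        raise NotFoundError(query)
    return hits


def barplot_data(
    ds: ExpressionDataset,
    row_id: str,
    results: list[ContrastResult],
    order: list[str] | None = None,
    colors: dict[str, str] | None = None,
) -> BarPlotData:
    """Per-condition mean/SEM/n for one protein plus its full p-value table."""
    if row_id not in ds.matrix.index:
        raise NotFoundError(row_id)
    conditions = ds.design.conditions
    if order is not None:
        if sorted(order) != sorted(conditions):
            raise ValidationError(
                f"order {order} is not a permutation of conditions {conditions}"
            )
        conditions = list(order)
    row = ds.matrix.loc[row_id]
    recs = []
    for cond in conditions:
        vals = row[ds.design.samples_of(cond)].to_numpy(float)
        n = len(vals)
        recs.append(
            {
                "condition": cond,
                "mean": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "n": n,
            }
        )
    stats = pd.DataFrame(recs).set_index("condition")
    ptab = pd.DataFrame(
        [
            {
                "contrast": r.contrast_id,
                "log2fc": r.table.loc[row_id, "log2fc"],
                "p": r.table.loc[row_id, "p"],
                "padj": r.table.loc[row_id, "padj"],
                "significant": bool(r.table.loc[row_id, "significant"]),
            }
            for r in results
        ]
    ).set_index("contrast")
    return BarPlotData(
        protein_id=row_id, stats=stats, p_table=ptab, colors=dict(colors or {})
    )


def plot_bar(data: BarPlotData, basepath: str) -> list[str]:
    """Bar plot with SEM error bars; numbers written to TSVs alongside."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    conds = list(data.stats.index)
    colors = [data.colors.get(c, "steelblue") for c in conds]
    ax.bar(
        range(len(conds)),
        data.stats["mean"],
        yerr=data.stats["sem"],
        color=colors,
        capsize=4,
    )
    ax.set_xticks(range(len(conds)))
    ax.set_xticklabels(conds, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("log2 LFQ intensity")
    ax.set_title(data.protein_id)
    data.stats.to_csv(f"{basepath}.tsv", sep="\t")
    data.p_table.to_csv(f"{basepath}.pvalues.tsv", sep="\t")
    paths = [f"{basepath}.png", f"{basepath}.svg"]
    for p in paths:
        fig.savefig(p, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return paths
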