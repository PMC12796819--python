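"""Nuclear-receptor target mining from consensome tables.

A consensome ranks a nuclear receptor's candidate target genes by a
percentile score (0-100) compiled across transcriptomic and cistromic
experiments.  Thresholding at the default 95th percentile keeps
high-confidence targets; matched proteins are extracted like a pathway, and
the annotated export carries one percentile column per receptor with blanks
where a gene falls below that receptor's threshold.  The enrichment summary
contrasts the target fraction among up-/down-regulated proteins with the
base rate among all detected proteins.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ContrastResult, results_wide_table
from .errors import FormatError, ValidationError
from .global_viz import zscore_rows
from .pathway_miner import GeneSet, MiningResult, match_ids, strip_suffix
from .preprocess import ExpressionDataset

log = logging.getLogger(__name__)

#: receptors available in the reference consensome release
DEFAULT_RECEPTORS = [
    "AR", "ER", "ERR", "FXR", "GR", "MR", "PPAR",
    "PR", "RAR", "ROR", "THR", "TR", "CAR/PXR",
]


@dataclass
class ConsensomeTable:
    """Long-form (gene, receptor, percentile) table, one score per pair."""

    table: pd.DataFrame  # columns: gene, receptor, percentile

    def __post_init__(self) -> None:
        t = self.table
        bad = t[(t["percentile"] < 0) | (t["percentile"] > 100)]
        if len(bad):
            raise ValidationError(
                f"percentiles outside [0, 100] at rows {bad.index.tolist()}"
            )

    @property
    def receptors(self) -> list[str]:
        return sorted(self.table["receptor"].unique())

    def scores_for(self, receptor: str) -> pd.Series:
        t = self.table
        sub = t[t["receptor"] == receptor]
        return pd.Series(sub["percentile"].values, index=sub["gene"].values)


@dataclass
class EnrichmentSummary:
    """Target-gene rates among detected / up / down protein sets.

    Percentages follow the reporting convention: base rate to one decimal,
    up/down percentages to the nearest integer.  The hypergeometric
    p-values are a formal supplement to the informal rate comparison.
    """

    n_detected: int
    n_targets_detected: int
    base_rate_pct: float
    n_up: int
    n_up_targets: int
    up_pct: Optional[int]
    n_down: int
    n_down_targets: int
    down_pct: Optional[int]
    p_up: Optional[float] = None
    p_down: Optional[float] = None

    def summary(self) -> str:
        lines = [
            f"{self.n_targets_detected} target genes among {self.n_detected} detected "
            f"proteins (base rate {self.base_rate_pct}%)"
        ]
        if self.up_pct is not None:
            lines.append(
                f"up-regulated: {self.n_up_targets}/{self.n_up} targets ({self.up_pct}%)"
                + (f", hypergeometric p={self.p_up:.3g}" if self.p_up is not None else "")
            )
        if self.down_pct is not None:
            lines.append(
                f"down-regulated: {self.n_down_targets}/{self.n_down} targets ({self.down_pct}%)"
                + (f", hypergeometric p={self.p_down:.3g}" if self.p_down is not None else "")
            )
        return "\n".join(lines)


def load_consensome(path: str) -> ConsensomeTable:
    """Read a consensome TSV in long or wide form.

    Long form: columns gene, receptor, percentile.  Wide form: a gene column
    plus one column per receptor, blank cells meaning "not a candidate".
    Duplicate (receptor, gene) rows keep the maximum percentile with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    lower = [c.lower() for c in df.columns]
    if {"gene", "receptor", "percentile"} <= set(lower):
        df.columns = lower
        long = df[["gene", "receptor", "percentile"]].copy()
    elif "gene" in lower:
        gene_col = df.columns[lower.index("gene")]
        long = df.melt(id_vars=[gene_col], var_name="receptor", value_name="percentile")
        long = long.rename(columns={gene_col: "gene"})
        long = long[long["percentile"].str.strip() != ""]
    else:
        raise FormatError(
            f"consensome {path!r}: need long form (gene/receptor/percentile) "
            "or wide form (gene + receptor columns)"
        )
    try:
        long["percentile"] = long["percentile"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric percentile in {path!r}: {exc}") from exc
    out_of_range = long[(long["percentile"] < 0) | (long["percentile"] > 100)]
    if len(out_of_range):
        raise FormatError(
            f"{path!r}: percentile outside [0, 100] at input rows "
            f"{(out_of_range.index + 2).tolist()}"
        )
    dup = long.duplicated(subset=["gene", "receptor"], keep=False)
    if dup.any():
        log.warning(
            "%d duplicate (receptor, gene) rows; keeping max percentile",
            int(dup.sum()),
        )
        long = (
            long.groupby(["gene", "receptor"], as_index=False, sort=False)["percentile"].max()
        )
    return ConsensomeTable(long.reset_index(drop=True))


def threshold_targets(ct: ConsensomeTable, receptor: str, pct: float = 95.0) -> GeneSet:
    """Genes scoring at or above the percentile cutoff for one receptor."""
    if receptor not in ct.receptors:
        raise ValidationError(
            f"unknown receptor {receptor!r}; available: {ct.receptors}"
        )
    scores = ct.scores_for(receptor)
    genes = frozenset(scores.index[scores >= pct])
    if not genes:
        raise ValidationError(
            f"no {receptor} genes at or above the {pct}th percentile"
        )
    return GeneSet(set_id=f"NR:{receptor}", name=f"{receptor} consensome >= {pct}",
                   species="mouse", genes=genes)


def extract_targets(
    ds: ExpressionDataset,
    gs: GeneSet,
    ct: ConsensomeTable,
    results: list[ContrastResult] | None = None,
    pct: float = 95.0,
) -> MiningResult:
    """Extract target proteins with per-receptor percentile annotation columns.

    Each receptor contributes one column holding the gene's percentile score
    when it meets that receptor's threshold and NaN (blank on export)
    otherwise.
    """
    if ds.stage != "imputed":
        raise ValidationError("mining requires an imputed dataset")
    matched, absent = match_ids(ds.ids, gs.genes)
    if not matched:
        log.warning("no %s targets detected in the dataset", gs.set_id)
        return MiningResult([], ds.matrix.iloc[0:0], absent)
    sub = ds.matrix.loc[matched]
    export = sub.copy()
    if results:
        export = export.join(results_wide_table(results).loc[matched])
    for receptor in ct.receptors:
        scores = ct.scores_for(receptor)
        lut = {str(g).casefold(): v for g, v in scores.items() if v >= pct}
        export[f"pct_{receptor}"] = [
            lut.get(strip_suffix(rid).casefold(), np.nan) for rid in matched
        ]
    return MiningResult(
        matched_ids=matched,
        matched_matrix=sub,
        not_detected=absent,
        zmatrix=zscore_rows(sub),
        export=export,
    )


def _rate(numer: int, denom: int) -> float:
    return 100.0 * numer / denom


def enrichment_summary(
    de_up: set[str],
    de_down: set[str],
    detected: set[str],
    targets: GeneSet,
    exact_test: bool = True,
) -> EnrichmentSummary:
    """Compare target-gene rates in the up/down sets against the base rate.

    All ids are compared case- and suffix-insensitively.  The optional
    hypergeometric p is one-sided: enrichment for the up set, depletion is
    not tested (the comparison of interest is "more targets than chance").
    """
    if not detected:
        raise ValidationError("detected set is empty")
    if not de_up <= detected or not de_down <= detected:
        raise ValidationError("up/down sets must be subsets of the detected set")

    def _norm(ids: set[str]) -> set[str]:
        return {strip_suffix(i).casefold() for i in ids}

    tgt = _norm(set(targets.genes))
    det, up, down = _norm(detected), _norm(de_up), _norm(de_down)
    n_det, n_tgt = len(det), len(det & tgt)
    n_up, n_up_t = len(up), len(up & tgt)
    n_down, n_down_t = len(down), len(down & tgt)
    p_up = p_down = None
    if exact_test:
        if n_up:
            p_up = float(stats.hypergeom.sf(n_up_t - 1, n_det, n_tgt, n_up))
        if n_down:
            p_down = float(stats.hypergeom.sf(n_down_t - 1, n_det, n_tgt, n_down))
    return EnrichmentSummary(
        n_detected=n_det,
        n_targets_detected=n_tgt,
        base_rate_pct=round(_rate(n_tgt, n_det), 1),
        n_up=n_up,
        n_up_targets=n_up_t,
        up_pct=round(_rate(n_up_t, n_up)) if n_up else None,
        n_down=n_down,
        n_down_targets=n_down_t,
        down_pct=round(_rate(n_down_t, n_down)) if n_down else None,
        p_up=p_up,
        p_down=p_down,
    )


def enrichment_from_counts(
    n_detected: int,
    n_targets_detected: int,
    n_up: int = 0,
    n_up_targets: int = 0,
    n_down: int = 0,
    n_down_targets: int = 0,
    exact_test: bool = False,
) -> EnrichmentSummary:
    """Enrichment summary straight from tallies (e.g. counted off an export).

    Same arithmetic and rounding as :func:`enrichment_summary`, for the
    workflow where the user counts rows of the downloaded annotated table
    rather than passing id sets.
    """
    if n_detected <= 0:
        raise ValidationError("detected count must be positive")
    for part, whole, what in (
        (n_targets_detected, n_detected, "detected targets"),
        (n_up_targets, n_up, "up targets") if n_up else (0, 0, ""),
        (n_down_targets, n_down, "down targets") if n_down else (0, 0, ""),
    ):
        if what and part > whole:
            raise ValidationError(f"{what} exceed their superset count")
    p_up = p_down = None
    if exact_test:
        if n_up:
            p_up = float(
                stats.hypergeom.sf(n_up_targets - 1, n_detected, n_targets_detected, n_up)
            )
        if n_down:
            p_down = float(
                stats.hypergeom.sf(n_down_targets - 1, n_detected, n_targets_detected, n_down)
            )
    return EnrichmentSummary(
        n_detected=n_detected,
        n_targets_detected=n_targets_detected,
        base_rate_pct=round(_rate(n_targets_detected, n_detected), 1),
        n_up=n_up,
        n_up_targets=n_up_targets,
        up_pct=round(_rate(n_up_targets, n_up)) if n_up else None,
        n_down=n_down,
        n_down_targets=n_down_targets,
        down_pct=round(_rate(n_down_targets, n_down)) if n_down else None,
        p_up=p_up,
        p_down=p_down,
    )


def consensome_overlap(
    gs_by_receptor: dict[str, GeneSet]
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Pairwise intersection sizes and per-receptor unique targets.

    The Venn-style cross-receptor view: consensomes share genes, so apparent
    activity of one receptor may reflect targets it shares with another;
    the unique sets isolate receptor-specific signal.
    """
    names = list(gs_by_receptor)
    rows = []
    for a, b in itertools.combinations(names, 2):
        rows.append(
            {
                "receptor_a": a,
                "receptor_b": b,
                "n_overlap": len(gs_by_receptor[a].genes & gs_by_receptor[b].genes),
            }
        )
    unique = {}
    for name in names:
        others: set[str] = set()
        for other in names:
            if other != name:
                others |= gs_by_receptor[other].genes
        unique[name] = frozenset(gs_by_receptor[name].genes - others)
    cols = ["receptor_a", "receptor_b", "n_overlap"]
    return pd.DataFrame(rows, columns=cols), unique
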