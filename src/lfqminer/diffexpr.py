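"""All-pairwise differential testing with empirical-Bayes variance moderation.

For each pair of conditions a two-sample t-test is computed per protein on
pooled residual variance s^2 with d = n1 + n2 - 2 degrees of freedom.  With
moderation on, per-protein variances are shrunk toward a common prior:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

where the prior (d0, s0^2) is estimated across proteins by the method of
moments on the log residual variances (Smyth 2004 style): under the model
s^2 ~ s0^2 * F(d, d0), e = log s^2 - digamma(d/2) + log(d/2) has

    E[e]   = log s0^2 - digamma(d0/2) + log(d0/2)
    Var[e] = trigamma(d/2) + trigamma(d0/2)

so d0 solves trigamma(d0/2) = Var[e] - trigamma(d/2) (inverse trigamma by
Newton iteration) and s0^2 follows from the mean.  The moderated statistic
t = log2FC / (s_tilde * sqrt(1/n1 + 1/n2)) is referred to Student t with
d + d0 degrees of freedom.  d0 = 0 recovers the ordinary pooled t.

Multiple testing is corrected per contrast with Benjamini-Hochberg; a
protein is called significant when padj < alpha AND |log2FC| > lfc_cutoff,
both strict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .preprocess import ExpressionDataset

#: d0 value used to represent "no evidence of variance heterogeneity"
#: (the prior dominates completely); kept finite so t dfs stay computable.
D0_INF = 1e12


@dataclass
class ContrastResult:
    """Per-protein statistics for one condition pair.

    ``table`` is indexed by protein id with columns log2fc, p, padj,
    significant; log2fc = mean(numerator) - mean(denominator) on the log2
    scale.  Swapping numerator and denominator negates log2fc and leaves p
    untouched.
    """

    numerator: str
    denominator: str
    table: pd.DataFrame
    alpha: float = 0.05
    lfc_cutoff: float = 0.5
    d0: float = 0.0
    s02: float = float("nan")

    @property
    def contrast_id(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def reversed(self) -> "ContrastResult":
        t = self.table.copy()
        t["log2fc"] = -t["log2fc"]
        return ContrastResult(
            numerator=self.denominator, denominator=self.numerator, table=t,
            alpha=self.alpha, lfc_cutoff=self.lfc_cutoff, d0=self.d0, s02=self.s02,
        )

    def summary(self) -> str:
        n_sig = int(self.table["significant"].sum())
        up = int((self.table["significant"] & (self.table["log2fc"] > 0)).sum())
        return (
            f"Contrast {self.contrast_id}: {len(self.table)} proteins tested, "
            f"{n_sig} significant (padj < {self.alpha}, |log2FC| > {self.lfc_cutoff}); "
            f"{up} up, {n_sig - up} down; prior d0={self.d0:.3g}, s0^2={self.s02:.3g}"
        )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValidationError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-10:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-protein variances.

    Zero variances are excluded from the fit (log undefined); if the spread
    of log variances is no larger than sampling noise alone explains, d0 is
    effectively infinite and s0^2 is the common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValidationError("too few positive residual variances to fit a prior")
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_INF
        s02 = float(np.exp(emean))
    return d0, s02


def _contrast_stats(
    x1: np.ndarray, x2: np.ndarray, moderated: bool
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Vectorized per-protein stats for numerator matrix x1 vs denominator x2."""
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if np.all(s2 == 0):
        raise ValidationError("zero residual variance for every protein")
    if moderated:
        d0, s02 = estimate_prior(s2, d)
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df = d + d0
    else:
        d0, s02 = 0.0, float("nan")
        s2_post = s2
        df = float(d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se == 0, np.where(lfc == 0, 1.0, 0.0), p)
    return lfc, p, d0, s02


def fit_contrast(
    ds: ExpressionDataset,
    numerator: str,
    denominator: str,
    alpha: float = 0.05,
    lfc_cutoff: float = 0.5,
    moderated: bool = True,
) -> ContrastResult:
    """Test one condition pair; see module docstring for the model."""
    if ds.stage != "imputed":
        raise ValidationError("differential testing requires an imputed dataset")
    for cond in (numerator, denominator):
        if cond not in ds.design.conditions:
            raise ValidationError(f"unknown condition {cond!r}")
        if ds.design.replicate_counts()[cond] < 2:
            raise ValidationError(f"condition {cond!r} has < 2 replicates")
    x1 = ds.matrix[ds.design.samples_of(numerator)].to_numpy(float)
    x2 = ds.matrix[ds.design.samples_of(denominator)].to_numpy(float)
    lfc, p, d0, s02 = _contrast_stats(x1, x2, moderated)
    padj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "padj": padj,
            "significant": (padj < alpha) & (np.abs(lfc) > lfc_cutoff),
        },
        index=ds.matrix.index,
    )
    return ContrastResult(numerator, denominator, table, alpha, lfc_cutoff, d0, s02)


def fit_all_contrasts(
    ds: ExpressionDataset,
    alpha: float = 0.05,
    lfc_cutoff: float = 0.5,
    moderated: bool = True,
) -> list[ContrastResult]:
    """One ContrastResult per unordered condition pair (lexicographic direction)."""
    conds = sorted(ds.design.conditions)
    return [
        fit_contrast(ds, num, den, alpha, lfc_cutoff, moderated)
        for num, den in itertools.combinations(conds, 2)
    ]


def changed_in_any(results: list[ContrastResult]) -> set[str]:
    """Proteins significant in at least one contrast (the DEP set)."""
    out: set[str] = set()
    for r in results:
        out |= r.significant_ids
    return out


def volcano_table(result: ContrastResult) -> pd.DataFrame:
    """Volcano-plot data: log2FC vs -log10 padj with the significance flag."""
    t = result.table
    with np.errstate(divide="ignore"):
        mlp = -np.log10(t["padj"].to_numpy())
    return pd.DataFrame(
        {
            "id": t.index,
            "log2fc": t["log2fc"].to_numpy(),
            "minus_log10_padj": mlp,
            "significant": t["significant"].to_numpy(),
        }
    ).set_index("id")


def results_wide_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Combined wide table: one block of (log2fc, p, padj, significant) per contrast."""
    blocks = []
    for r in results:
        blk = r.table.copy()
        blk.columns = [f"{r.contrast_id}.{c}" for c in blk.columns]
        blocks.append(blk)
    return pd.concat(blocks, axis=1)
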