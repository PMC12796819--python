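"""Identification-overlap summaries, PCA on the most variable proteins, and
k-means clustered z-score heatmaps.

PCA operates on the samples x proteins configuration after restricting to
the top-N proteins by row variance (default 500, clamped to the number of
proteins present); rows are centered but not scaled, and each component's
sign is fixed so its largest-magnitude protein loading is positive, making
coordinates reproducible.  Heatmap rows are z-scored (mean 0, SD 1 across
samples), clustered with seeded k-means, renumbered by descending cluster
size and ordered within a cluster by correlation with the centroid; the
display is clamped to +/- z_cap while exports keep unclamped values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ValidationError
from .preprocess import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x PCs
    percent_variance: np.ndarray  # per PC, sums to <= 100
    n_top: int

    def summary(self) -> str:
        parts = ", ".join(
            f"PC{i + 1} {v:.1f}%" for i, v in enumerate(self.percent_variance[:3])
        )
        return f"PCA on top {self.n_top} most variable proteins: {parts}"


@dataclass
class HeatmapResult:
    zmatrix: pd.DataFrame  # proteins x samples, unclamped, rows in display order
    k: int
    clusters: pd.Series  # cluster label per protein (display order)
    z_cap: float

    @property
    def display_matrix(self) -> pd.DataFrame:
        return self.zmatrix.clip(-self.z_cap, self.z_cap)


def overlap_summary(ds: ExpressionDataset) -> tuple[pd.Series, pd.Series]:
    """Detection counts per sample and histogram of per-protein detection breadth.

    Meant for the pre-imputation dataset, where NaN still marks "not
    detected".  Returns (per-sample counts, histogram indexed by the number
    of samples a protein was detected in, covering 0..n_samples).
    """
    detected = ds.matrix.notna()
    per_sample = detected.sum(axis=0)
    per_sample.name = "n_detected"
    breadth = detected.sum(axis=1)
    hist = breadth.value_counts().reindex(
        range(len(ds.matrix.columns) + 1), fill_value=0
    )
    hist.name = "n_proteins"
    hist.index.name = "n_samples_detected_in"
    return per_sample, hist


def pca_top_n(ds: ExpressionDataset, n: int = 500, n_components: int | None = None) -> PcaResult:
    """PCA of samples using the top-n most variable proteins (by row variance)."""
    if ds.stage != "imputed":
        raise ValidationError("PCA requires an imputed (complete) dataset")
    if n < 1:
        raise ValidationError("n must be >= 1")
    n_samples, n_proteins = ds.matrix.shape[1], ds.matrix.shape[0]
    if n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if n > n_proteins:
        log.warning("requested top %d proteins but only %d present; clamping", n, n_proteins)
        n = n_proteins
    variances = ds.matrix.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n]
    # samples x proteins; protein (feature) centering is PCA's own centering
    x = ds.matrix.loc[top].to_numpy(float).T
    k = n_components or min(n_samples, n, 10)
    k = min(k, n_samples - 1, n)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| protein positive on each PC
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1
            pca.components_[j] *= -1
    coords = pd.DataFrame(
        scores,
        index=ds.matrix.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    pct = 100.0 * pca.explained_variance_ratio_
    if not np.all(np.isfinite(scores)):
        raise ValidationError("non-finite PCA coordinates")
    return PcaResult(coordinates=coords, percent_variance=pct, n_top=n)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, SD 1; constant rows become all-zero."""
    values = matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        log.warning("%d constant rows z-scored to all-zero", int(flat.sum()))
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat.nonzero()[0], :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def cluster_heatmap(
    zmatrix: pd.DataFrame, k: int, seed: int, z_cap: float = 2.0
) -> HeatmapResult:
    """Seeded k-means over z-scored rows, >= 10 restarts, best inertia kept.

    Cluster labels are renumbered 1..k by descending cluster size; rows are
    ordered by cluster then by decreasing correlation with the cluster
    centroid.
    """
    n_rows = len(zmatrix)
    if not (1 <= k <= n_rows):
        raise ValidationError(f"k must lie in [1, {n_rows}], got {k}")
    if z_cap <= 0:
        raise ValidationError("z_cap must be positive")
    x = zmatrix.to_numpy(float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(x)
    sizes = pd.Series(raw_labels).value_counts()
    # renumber by descending size (ties by old label for stability)
    order = sorted(sizes.index, key=lambda lbl: (-sizes[lbl], lbl))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[lbl] for lbl in raw_labels])
    centroids = {relabel[i]: c for i, c in enumerate(km.cluster_centers_)}

    def _corr(row: np.ndarray, cen: np.ndarray) -> float:
        if row.std() == 0 or cen.std() == 0:
            return 0.0
        return float(np.corrcoef(row, cen)[0, 1])

    corr = np.array([_corr(x[i], centroids[labels[i]]) for i in range(n_rows)])
    display = np.lexsort((-corr, labels))
    zm = zmatrix.iloc[display]
    return HeatmapResult(
        zmatrix=zm,
        k=k,
        clusters=pd.Series(labels[display], index=zm.index, name="cluster"),
        z_cap=z_cap,
    )


# ---------------------------------------------------------------- plotting

def _save(fig, basepath: str) -> list[str]:
    paths = [f"{basepath}.png", f"{basepath}.svg"]
    for p in paths:
        fig.savefig(p, bbox_inches="tight", dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return paths


def plot_pca(res: PcaResult, basepath: str, conditions: pd.Series | None = None) -> list[str]:
    """Scatter of PC1 vs PC2 colored by condition; data TSV written alongside."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    c = res.coordinates
    if conditions is not None:
        for cond in dict.fromkeys(conditions):
            sel = conditions == cond
            ax.scatter(c.loc[sel.values, "PC1"], c.loc[sel.values, "PC2"], label=cond, s=40)
        ax.legend(fontsize=7)
    else:
        ax.scatter(c["PC1"], c["PC2"], s=40)
    ax.set_xlabel(f"PC1 ({res.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({res.percent_variance[1]:.1f}%)")
    ax.set_title(f"PCA (top {res.n_top} most variable proteins)")
    c.to_csv(f"{basepath}.tsv", sep="\t")
    return _save(fig, basepath)


def plot_volcano(vt: pd.DataFrame, basepath: str, title: str = "") -> list[str]:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = vt["significant"]
    ax.scatter(vt.loc[~sig, "log2fc"], vt.loc[~sig, "minus_log10_padj"], s=6, c="lightgray")
    ax.scatter(vt.loc[sig, "log2fc"], vt.loc[sig, "minus_log10_padj"], s=8, c="black")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(title)
    vt.to_csv(f"{basepath}.tsv", sep="\t")
    return _save(fig, basepath)


def plot_heatmap(res: HeatmapResult, basepath: str, title: str = "") -> list[str]:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, max(3, min(10, 0.02 * len(res.zmatrix) + 2))))
    im = ax.imshow(
        res.display_matrix.to_numpy(),
        aspect="auto",
        cmap="RdBu_r",
        vmin=-res.z_cap,
        vmax=res.z_cap,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(res.zmatrix.columns)))
    ax.set_xticklabels(res.zmatrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(title or f"z-score heatmap, k={res.k}")
    fig.colorbar(im, ax=ax, label="z score")
    out = res.zmatrix.copy()
    out.insert(0, "cluster", res.clusters)
    out.to_csv(f"{basepath}.tsv", sep="\t", float_format="%.6f")
    return _save(fig, basepath)
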