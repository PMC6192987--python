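"""Compound-profiling analytics.

From per-treatment differential-expression tables (gene, log2FC vs control,
BH-adjusted p) this module derives the mechanism-of-action feature space:

* potent-compound filtering — keep compounds with more than ``min_genes``
  (default 50) genes at padj < 0.05 and |log2FC| > 1 at the top dose;
* candidate-gene selection — up to 200 genes per compound (1000 for the
  pairwise analysis), ranked by padj then |log2FC|, to stop very potent
  compounds from dominating the union;
* classic quantile normalization of the log2FC matrix across compounds;
* Euclidean hierarchical clustering and tSNE embedding of the compounds.

A lightweight internal DE routine (median-of-ratios size factors, Welch
test on log1p-normalized counts, Benjamini-Hochberg) is provided for
simulations and smoke tests; externally computed tables (e.g. DESeq2
exports) are read with :func:`read_de_table` and are the intended input for
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .count import CountMatrix

DE_COLUMNS = ["gene", "log2fc", "padj", "base_mean"]


class DesignError(ValueError):
    """Invalid DE design (e.g. fewer than two wells in a group)."""


class DEFormatError(ValueError):
    """A DE table file is missing required columns or has non-numeric values."""


class SelectionError(ValueError):
    """Candidate-gene selection produced an empty union."""


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------


@dataclass
class DETable:
    """Differential expression result for one treatment/dose vs control.

    ``table`` is indexed by gene with columns ``log2fc``, ``padj``,
    ``base_mean``; untested genes (e.g. all-zero) carry NaN padj.
    """

    table: pd.DataFrame
    treatment: str = ""
    dose_um: float | None = None

    def __post_init__(self) -> None:
        missing = {"log2fc", "padj"} - set(self.table.columns)
        if missing:
            raise DEFormatError(f"DE table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise DEFormatError("duplicate gene ids in DE table")
        padj = self.table["padj"].dropna()
        if ((padj < 0) | (padj > 1)).any():
            raise DEFormatError("padj outside [0, 1]")


def read_de_table(path, treatment: str = "", dose_um: float | None = None) -> DETable:
    """Read a DE table (CSV or TSV) with columns gene, log2fc, padj[, base_mean]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower() for c in df.columns]
    missing = {"gene", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise DEFormatError(f"missing columns: {sorted(missing)}")
    for col in ("log2fc", "padj"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if "base_mean" not in df.columns:
        df["base_mean"] = np.nan
    return DETable(df.set_index("gene"), treatment=treatment, dose_um=dose_um)


def write_de_table(det: DETable, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    det.table.reset_index().rename(columns={det.table.index.name or "index": "gene"}).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# internal DE stand-in
# ---------------------------------------------------------------------------


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes with nonzero geometric mean."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.astype(float))
        log_gm = np.mean(np.where(counts > 0, logc, -np.inf), axis=0)
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise DesignError("no gene has nonzero counts in every sample")
    ratios = logc[:, usable] - log_gm[usable]
    sf = np.exp(np.median(ratios, axis=1))
    return sf


def internal_de(
    matrix: CountMatrix,
    treatment_wells: Sequence[str],
    control_wells: Sequence[str],
    pseudocount: float = 1.0,
    treatment: str = "",
    dose_um: float | None = None,
) -> DETable:
    """Simple internal DE: normalized-mean log2FC + Welch test + BH.

    Size factors are median-of-ratios over both groups jointly; log2FC is
    ``log2((mean_t + c) / (mean_c + c))`` on normalized counts with
    pseudocount ``c``; p-values come from a two-sided Welch t-test on
    ``log1p`` of normalized counts; padj is Benjamini-Hochberg over the
    tested (not-all-zero) genes. This is deliberately not a negative
    binomial GLM; import externally computed tables for publication-grade
    inference.
    """
    from statsmodels.stats.multitest import multipletests

    if len(treatment_wells) < 2 or len(control_wells) < 2:
        raise DesignError("each group needs >= 2 wells")
    frame = matrix.to_dense_frame()
    missing = (set(treatment_wells) | set(control_wells)) - set(frame.index)
    if missing:
        raise DesignError(f"wells absent from matrix: {sorted(missing)[:5]}")
    sub = frame.loc[list(treatment_wells) + list(control_wells)]
    counts = sub.to_numpy(dtype=float)
    sf = size_factors(counts)
    norm = counts / sf[:, None]
    nt = len(treatment_wells)
    t_norm, c_norm = norm[:nt], norm[nt:]

    mean_t = t_norm.mean(axis=0)
    mean_c = c_norm.mean(axis=0)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    base_mean = norm.mean(axis=0)

    tested = (counts.sum(axis=0) > 0)
    log_t = np.log1p(t_norm)
    log_c = np.log1p(c_norm)
    pvals = np.full(norm.shape[1], np.nan)
    if tested.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = scipy.stats.ttest_ind(
                log_t[:, tested], log_c[:, tested], equal_var=False, axis=0
            )
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties: no evidence
        pvals[tested] = p
    padj = np.full_like(pvals, np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {"log2fc": log2fc, "padj": padj, "base_mean": base_mean},
        index=pd.Index(sub.columns, name="gene"),
    )
    return DETable(table, treatment=treatment, dose_um=dose_um)


# ---------------------------------------------------------------------------
# significance, potency, candidate selection
# ---------------------------------------------------------------------------


def significant_genes(
    det: DETable, padj_cutoff: float = 0.05, lfc_cutoff: float = 1.0
) -> pd.Index:
    """Genes with padj < padj_cutoff AND |log2FC| > lfc_cutoff (both strict)."""
    t = det.table
    mask = (t["padj"] < padj_cutoff) & (t["log2fc"].abs() > lfc_cutoff)
    return t.index[mask.fillna(False)]


def select_potent(
    tables: Mapping[str, DETable],
    min_genes: int = 50,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> list[str]:
    """Compounds with strictly more than ``min_genes`` significant genes."""
    return [
        name
        for name, det in tables.items()
        if len(significant_genes(det, padj_cutoff, lfc_cutoff)) > min_genes
    ]


def select_candidates(
    det: DETable,
    max_genes: int = 200,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> list[str]:
    """Up to ``max_genes`` significant genes, ranked by padj asc, then |log2FC|
    desc, then gene id."""
    sig = significant_genes(det, padj_cutoff, lfc_cutoff)
    sub = det.table.loc[sig]
    ranked = sorted(
        sub.index, key=lambda g: (sub.at[g, "padj"], -abs(sub.at[g, "log2fc"]), g)
    )
    return ranked[:max_genes]


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns.

    Each column's values are replaced by the cross-column mean of the sorted
    values at their rank; tied values within a column receive the mean over
    their rank range. Requires finite values (impute before normalizing);
    an all-NaN column raises a column error.
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    arr = values.to_numpy(dtype=float)
    all_nan = np.isnan(arr).all(axis=0)
    if all_nan.any():
        raise ValueError(
            f"column(s) with all-missing values: {list(values.columns[all_nan])}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values; impute before quantile normalization")
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(n)
        col[order] = mean_sorted
        # ties: average the assigned values over each tied group
        s = pd.Series(col).groupby(arr[:, j]).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Quantile-normalized log2FC over the candidate-gene union.

    Rows are genes, columns are compounds; ``candidates`` records which
    genes each compound contributed to the union.
    """

    values: pd.DataFrame
    candidates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_union(self) -> list[str]:
        return list(self.values.index)


def build_feature_matrix(
    tables: Mapping[str, DETable],
    max_genes: int = 200,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
    normalize: bool = True,
) -> FeatureMatrix:
    """Union of per-compound candidate genes x compounds, quantile-normalized.

    Genes missing from a compound's table (untested) are imputed as
    log2FC = 0 before normalization.
    """
    if len(tables) < 2:
        raise SelectionError("feature matrix needs >= 2 compounds")
    candidates = {
        name: select_candidates(det, max_genes, padj_cutoff, lfc_cutoff)
        for name, det in tables.items()
    }
    union: list[str] = []
    seen = set()
    for genes in candidates.values():
        for g in genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    if not union:
        raise SelectionError("no compound contributed any candidate genes")
    union = sorted(union)
    lfc = pd.DataFrame(0.0, index=pd.Index(union, name="gene"), columns=list(tables))
    for name, det in tables.items():
        present = det.table.index.intersection(union)
        lfc.loc[present, name] = det.table.loc[present, "log2fc"].to_numpy()
    lfc = lfc.fillna(0.0)
    values = quantile_normalize(lfc) if normalize else lfc
    return FeatureMatrix(values, candidates)


# ---------------------------------------------------------------------------
# clustering and embedding
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative clustering of compounds (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def fmt(node, parent_height):
            blen = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{blen:.6g}"
            children = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{blen:.6g}"

        root = tree
        inner = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = sch.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def hierarchical_cluster(
    features: FeatureMatrix | pd.DataFrame, linkage: str = "complete"
) -> Dendrogram:
    """Cluster compounds (columns) on Euclidean distance of their feature vectors."""
    values = features.values if isinstance(features, FeatureMatrix) else features
    arr = values.to_numpy(dtype=float).T
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 compounds to cluster")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite feature values")
    Z = sch.linkage(arr, method=linkage, metric="euclidean")
    return Dendrogram(Z, list(values.columns))


def embed_tsne(
    features: FeatureMatrix | pd.DataFrame,
    perplexity: float = 10.0,
    max_iterations: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D tSNE embedding of compounds; deterministic for a fixed seed."""
    from sklearn.manifold import TSNE

    values = features.values if isinstance(features, FeatureMatrix) else features
    arr = values.to_numpy(dtype=float).T
    n = arr.shape[0]
    if n <= perplexity:
        raise ValueError(f"perplexity {perplexity} must be < number of compounds {n}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iterations,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(arr)
    return pd.DataFrame(coords, index=values.columns, columns=["tsne1", "tsne2"])
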