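"""Quality-control analyses: barnyard purity, well correlation, saturation,
ROC against a reference truth set, and CRISPR indel frame binning.

The barnyard purity check quantifies cross-well contamination on a
mixed-species plate: each well's purity is the dominant species' share of
its UMIs, and the platform-level summary is the fraction of nonempty wells
whose purity exceeds a threshold (0.96 by default, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .count import CountMatrix


class LabelingError(ValueError):
    """ROC truth labeling produced no positives or no negatives."""


# ---------------------------------------------------------------------------
# species purity
# ---------------------------------------------------------------------------


@dataclass
class PurityReport:
    """Per-well species purity and the global pass fraction.

    ``per_well`` has one UMI-count column per species plus ``total`` and
    ``purity`` (NaN for empty wells, which are excluded from the global
    fraction).
    """

    per_well: pd.DataFrame
    threshold: float
    pass_fraction: float
    n_evaluated: int


def species_purity(
    matrix: CountMatrix, purity_threshold: float = 0.96
) -> PurityReport:
    """Per-well purity = max species UMI count / total (ERCC excluded)."""
    endo = matrix.endogenous()
    species = sorted(endo.genes["species"].unique())
    if len(species) < 2:
        raise ValueError("species purity requires >= 2 species")
    per_species = {}
    for spc in species:
        mask = (endo.genes["species"] == spc).to_numpy()
        per_species[spc] = np.asarray(endo.X[:, mask].sum(axis=1)).ravel()
    table = pd.DataFrame(per_species, index=endo.wells.index)
    total = table.sum(axis=1)
    purity = table.max(axis=1) / total.replace(0, np.nan)
    table["total"] = total
    table["purity"] = purity
    evaluated = purity.dropna()
    passed = (evaluated > purity_threshold).sum()
    return PurityReport(
        per_well=table,
        threshold=purity_threshold,
        pass_fraction=float(passed / len(evaluated)) if len(evaluated) else float("nan"),
        n_evaluated=int(len(evaluated)),
    )


# ---------------------------------------------------------------------------
# well-well correlation
# ---------------------------------------------------------------------------


def _log1p_cpm(X: sp.spmatrix) -> np.ndarray:
    dense = np.asarray(X.todense(), dtype=float)
    lib = dense.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = np.where(lib > 0, dense / lib * 1e6, 0.0)
    return np.log1p(cpm)


def well_correlation(matrix: CountMatrix, transform: str = "log1p-CPM") -> pd.DataFrame:
    """Pearson correlation between wells on transformed endogenous expression.

    Zero-variance wells yield NaN rows/columns (their diagonal stays 1).
    """
    endo = matrix.endogenous()
    if endo.shape[0] < 2:
        raise ValueError("need >= 2 wells")
    if transform == "log1p-CPM":
        data = _log1p_cpm(endo.X)
    elif transform in ("identity", None):
        data = np.asarray(endo.X.todense(), dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    centered = data - data.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = centered / (sd[:, None] * np.sqrt(data.shape[1]))
    corr = normed @ normed.T
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=endo.wells.index, columns=endo.wells.index)


# ---------------------------------------------------------------------------
# downsampling and gene detection
# ---------------------------------------------------------------------------


def downsample(matrix: CountMatrix, fraction: float, seed: int = 0) -> CountMatrix:
    """Binomial thinning of every UMI count by ``fraction`` (deterministic per seed)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    coo = matrix.X.tocoo()
    if fraction == 1.0:
        data = coo.data.copy()
    elif fraction == 0.0:
        data = np.zeros_like(coo.data)
    else:
        data = rng.binomial(coo.data.astype(np.int64), fraction)
    X = sp.csr_matrix(
        (data, (coo.row, coo.col)), shape=matrix.X.shape, dtype=np.int64
    )
    X.eliminate_zeros()
    return CountMatrix(X, matrix.wells.copy(), matrix.genes.copy())


def downsample_records(records: list, fraction: float, seed: int = 0) -> list:
    """Uniform subsampling of tagged reads *before* UMI deduplication."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(records)) < fraction
    return [r for r, k in zip(records, keep) if k]


def genes_detected(matrix: CountMatrix, thresholds: list[float] | None = None) -> pd.DataFrame:
    """Per well, number of genes with count strictly above each threshold.

    Columns are one per threshold (ascending); endogenous genes only.
    """
    thresholds = [0] if thresholds is None else list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    endo = matrix.endogenous()
    dense = np.asarray(endo.X.todense())
    out = {f">{t:g}": (dense > t).sum(axis=1) for t in thresholds}
    return pd.DataFrame(out, index=endo.wells.index)


@dataclass
class SaturationCurve:
    """Genes detected per well across a series of downsampling fractions."""

    table: pd.DataFrame  # columns: fraction, threshold, mean_genes, sd_genes


def saturation_curve(
    matrix: CountMatrix,
    fractions: list[float],
    thresholds: list[float] | None = None,
    seed: int = 0,
) -> SaturationCurve:
    thresholds = [0] if thresholds is None else list(thresholds)
    rows = []
    rng = np.random.default_rng(seed)
    for frac in fractions:
        sub = downsample(matrix, frac, seed=int(rng.integers(2**31)))
        det = genes_detected(sub, thresholds)
        for t in thresholds:
            col = det[f">{t:g}"]
            rows.append(
                {
                    "fraction": frac,
                    "threshold": t,
                    "mean_genes": float(col.mean()),
                    "sd_genes": float(col.std()),
                }
            )
    return SaturationCurve(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ROC against a reference platform
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_vs_reference(
    scores: pd.Series,
    reference_log2fc: pd.Series,
    truth_lfc_cutoff: float = 2.0,
    signed: bool = False,
) -> RocResult:
    """ROC of per-gene scores against truth labels from a reference platform.

    Positives are genes whose reference |log2FC| (or signed log2FC when
    ``signed``) exceeds ``truth_lfc_cutoff``; the curve sweeps the score and
    the AUC is the trapezoid area.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    common = scores.index.intersection(reference_log2fc.index)
    if len(common) == 0:
        raise LabelingError("no shared genes between scores and reference")
    s = scores.loc[common].astype(float)
    ref = reference_log2fc.loc[common].astype(float)
    labels = (ref > truth_lfc_cutoff) if signed else (ref.abs() > truth_lfc_cutoff)
    if labels.all() or not labels.any():
        raise LabelingError("degenerate label set (all positive or all negative)")
    fpr, tpr, _ = roc_curve(labels.to_numpy(), s.to_numpy())
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=float(sk_auc(fpr, tpr)),
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


# ---------------------------------------------------------------------------
# CRISPR indel frame binning
# ---------------------------------------------------------------------------


@dataclass
class IndelSummary:
    """Read-weighted fractions of wild-type, in-frame and frameshift genotypes."""

    wild_type: float
    in_frame: float
    frameshift: float

    def as_dict(self) -> dict[str, float]:
        return {
            "wild_type": self.wild_type,
            "in_frame": self.in_frame,
            "frameshift": self.frameshift,
        }


def bin_indels(genotype_tallies: list[tuple[int, int]]) -> IndelSummary:
    """Bin tallied genotypes by net indel length: 0 -> wild type, %3==0 ->
    in-frame, otherwise frameshift; fractions weighted by read count."""
    counts = {"wild_type": 0, "in_frame": 0, "frameshift": 0}
    for net_len, reads in genotype_tallies:
        if reads < 0:
            raise ValueError("negative read count")
        if net_len == 0:
            counts["wild_type"] += reads
        elif net_len % 3 == 0:
            counts["in_frame"] += reads
        else:
            counts["frameshift"] += reads
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty input: no reads to bin")
    return IndelSummary(
        wild_type=counts["wild_type"] / total,
        in_frame=counts["in_frame"] / total,
        frameshift=counts["frameshift"] / total,
    )


def read_indel_tallies(path) -> list[tuple[int, int]]:
    """Read a ``net_indel_bp<TAB>read_count`` TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["net_indel_bp", "read_count"])
    return list(zip(df["net_indel_bp"].astype(int), df["read_count"].astype(int)))
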