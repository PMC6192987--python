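"""UMI-deduplicated wells x genes counting from tagged transcriptome alignments.

Uniquely mapped, tagged read-2 alignments are collapsed transcript -> gene
and the number of distinct (well, gene, UMI) triples per cell of the matrix
is counted. Uniqueness is decided at gene level after the transcript
collapse: a read hitting several isoforms of one gene is still unique; a
read touching two genes is discarded. The default "exact" UMI collapse
counts distinct UMIs verbatim; the "directional" mode additionally merges
1-mismatch UMI pairs where the larger count dominates (count(a) >= 2*count(b) - 1),
absorbing UMIs created by sequencing errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import BarcodeSet, PlateMap
from .demux import parse_tag


class MalformedTagError(ValueError):
    """Query name does not carry the ``<id>_<barcode>_<umi>`` tag."""


class UnknownWellError(KeyError):
    """Tagged barcode resolves to a well absent from the plate map."""


class MatrixFormatError(ValueError):
    """Matrix directory contents are inconsistent."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def read_annotation(path) -> pd.DataFrame:
    """Read a ``transcript_id<TAB>gene_id<TAB>species`` TSV (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["transcript_id", "gene_id", "species"]
    )
    return df.set_index("transcript_id")


def gene_table(annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse a transcript annotation to unique genes with species / ERCC flags."""
    genes = (
        annotation.reset_index()[["gene_id", "species"]]
        .drop_duplicates("gene_id")
        .set_index("gene_id")
    )
    genes["is_ercc"] = genes["species"].str.upper() == "ERCC"
    return genes


# ---------------------------------------------------------------------------
# alignment records
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class AlignmentRecord:
    """One SAM line after transcript -> gene collapse."""

    qname: str
    gene: str | None
    mapped: bool
    primary: bool
    mapq: int


def parse_tagged_sam(
    sam_path, annotation: pd.DataFrame, lenient: bool = False
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file of tagged reads.

    Reference names are collapsed to gene ids via ``annotation``
    (transcript_id-indexed, ``gene_id`` column). Unmapped records yield
    ``mapped=False``; a query name without the demux tag raises
    :class:`MalformedTagError` (or is skipped under ``lenient``).
    """
    import pysam

    tx_to_gene = annotation["gene_id"].to_dict()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            qname = rec.query_name or ""
            if qname.count("_") < 2:
                if lenient:
                    continue
                raise MalformedTagError(f"untagged query name: {qname!r}")
            if rec.is_unmapped:
                yield AlignmentRecord(qname, None, False, not rec.is_secondary, 0)
                continue
            ref = rec.reference_name
            gene = tx_to_gene.get(ref, ref)
            yield AlignmentRecord(
                qname,
                gene,
                True,
                not (rec.is_secondary or rec.is_supplementary),
                rec.mapping_quality,
            )


def filter_unique(
    records: Iterable[AlignmentRecord], min_mapq: int | None = None
) -> list[AlignmentRecord]:
    """Keep primary records of reads whose alignments touch exactly one gene.

    All records of a query (primary, secondary, supplementary) vote on the
    gene set; reads mapping to multiple genes, or unmapped, are dropped.
    ``min_mapq`` optionally also excludes low-MAPQ primaries (for real
    aligner output where MAPQ marks uniqueness).
    """
    records = list(records)
    genes_of: dict[str, set] = {}
    for rec in records:
        if rec.mapped and rec.gene is not None:
            genes_of.setdefault(rec.qname, set()).add(rec.gene)
    kept = []
    for rec in records:
        if not rec.mapped or not rec.primary:
            continue
        if len(genes_of.get(rec.qname, ())) != 1:
            continue
        if min_mapq is not None and rec.mapq < min_mapq:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse wells x genes UMI count matrix with metadata.

    ``X`` is CSR int64; ``wells`` (row metadata) is indexed by well label;
    ``genes`` (column metadata) is indexed by gene id with ``species`` and
    ``is_ercc`` columns.
    """

    X: sp.csr_matrix
    wells: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.wells), len(self.genes)):
            raise MatrixFormatError(
                f"matrix shape {self.X.shape} != metadata "
                f"({len(self.wells)}, {len(self.genes)})"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise MatrixFormatError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def endogenous(self) -> "CountMatrix":
        """Submatrix excluding ERCC spike-in columns."""
        keep = ~self.genes["is_ercc"].to_numpy()
        return CountMatrix(
            sp.csr_matrix(self.X[:, keep]), self.wells.copy(), self.genes.loc[keep].copy()
        )

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.toarray(), index=self.wells.index, columns=self.genes.index
        )

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.X.astype(np.float32), obs=self.wells.copy(), var=self.genes.copy()
        )


def count_umis(
    records: Iterable[AlignmentRecord],
    plate: PlateMap,
    barcode_set: BarcodeSet,
    genes: pd.DataFrame,
    umi_collapse: str = "exact",
    lenient: bool = False,
) -> CountMatrix:
    """Count distinct UMIs per (well, gene) from unique-filtered tagged records.

    UMIs containing N are discarded. In strict mode a tagged barcode mapping
    to a well absent from the plate raises :class:`UnknownWellError`;
    ``lenient`` skips such reads.
    """
    if umi_collapse not in ("exact", "directional"):
        raise ValueError(f"unknown umi_collapse {umi_collapse!r}")
    bc_to_well = dict(barcode_set.mapping)
    plate_wells = set(plate.wells)

    wells_l, genes_l, umis_l = [], [], []
    for rec in records:
        _, bc, umi = parse_tag(rec.qname)
        if "N" in umi:
            continue
        well = bc_to_well.get(bc)
        if well is None or well not in plate_wells:
            if lenient:
                continue
            raise UnknownWellError(f"barcode {bc!r} -> well {well!r} not in plate map")
        wells_l.append(well)
        genes_l.append(rec.gene)
        umis_l.append(umi)

    gene_index = pd.Index(genes.index, name="gene_id")
    well_index = pd.Index(plate.wells, name="well")
    if wells_l:
        triples = pd.DataFrame({"well": wells_l, "gene": genes_l, "umi": umis_l})
        triples = triples.drop_duplicates()
        if umi_collapse == "directional":
            read_counts = (
                pd.DataFrame({"well": wells_l, "gene": genes_l, "umi": umis_l})
                .value_counts()
                .rename("reads")
                .reset_index()
            )
            cell_counts = (
                read_counts.groupby(["well", "gene"])
                .apply(
                    lambda g: _directional_cluster_count(
                        dict(zip(g["umi"], g["reads"]))
                    ),
                    include_groups=False,
                )
                .rename("n")
                .reset_index()
            )
        else:
            cell_counts = (
                triples.groupby(["well", "gene"]).size().rename("n").reset_index()
            )
        rows = well_index.get_indexer(cell_counts["well"])
        cols = gene_index.get_indexer(cell_counts["gene"])
        if (cols < 0).any():
            bad = cell_counts["gene"][cols < 0].unique()
            raise UnknownWellError(f"genes absent from annotation: {bad[:5]}")
        X = sp.csr_matrix(
            (cell_counts["n"].to_numpy(), (rows, cols)),
            shape=(len(well_index), len(gene_index)),
            dtype=np.int64,
        )
    else:
        X = sp.csr_matrix((len(well_index), len(gene_index)), dtype=np.int64)

    wells_meta = plate.table.copy()
    genes_meta = genes.copy()
    if "is_ercc" not in genes_meta.columns:
        genes_meta["is_ercc"] = genes_meta["species"].str.upper() == "ERCC"
    return CountMatrix(X, wells_meta, genes_meta)


def _directional_cluster_count(umi_reads: dict[str, int]) -> int:
    """Number of UMI clusters after directional 1-mismatch network collapse."""
    umis = sorted(umi_reads, key=lambda u: (-umi_reads[u], u))
    absorbed: set[str] = set()
    for i, a in enumerate(umis):
        if a in absorbed:
            continue
        for b in umis[i + 1 :]:
            if b in absorbed:
                continue
            if umi_reads[a] >= 2 * umi_reads[b] - 1 and _hamming1(a, b):
                absorbed.add(b)
    return len(umis) - len(absorbed)


def _hamming1(a: str, b: str) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return mism == 1


def count_sam(
    sam_path,
    plate: PlateMap,
    barcode_set: BarcodeSet,
    annotation: pd.DataFrame,
    umi_collapse: str = "exact",
    lenient: bool = False,
    min_mapq: int | None = None,
) -> CountMatrix:
    """End-to-end: parse tagged SAM, unique-filter, count UMIs."""
    records = filter_unique(
        parse_tagged_sam(sam_path, annotation, lenient=lenient), min_mapq=min_mapq
    )
    return count_umis(
        records, plate, barcode_set, gene_table(annotation), umi_collapse, lenient
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_matrix(matrix: CountMatrix, outdir, dense_tsv: bool = False) -> Path:
    """Write MatrixMarket ``matrix.mtx`` + ``wells.tsv`` + ``genes.tsv`` (+ ERCC summary)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), matrix.X.tocoo())
    matrix.wells.to_csv(outdir / "wells.tsv", sep="\t")
    matrix.genes.to_csv(outdir / "genes.tsv", sep="\t")
    ercc_mask = matrix.genes["is_ercc"].to_numpy()
    if ercc_mask.any():
        ercc_total = np.asarray(matrix.X[:, ercc_mask].sum(axis=1)).ravel()
        pd.DataFrame(
            {"well": matrix.wells.index, "ercc_umis": ercc_total}
        ).to_csv(outdir / "ercc.tsv", sep="\t", index=False)
    if dense_tsv:
        matrix.to_dense_frame().to_csv(outdir / "matrix_dense.tsv", sep="\t")
    return outdir


def read_matrix(outdir) -> CountMatrix:
    outdir = Path(outdir)
    try:
        X = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx"))).astype(np.int64)
        wells = pd.read_csv(outdir / "wells.tsv", sep="\t", index_col=0)
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t", index_col=0)
    except FileNotFoundError as exc:
        raise MatrixFormatError(str(exc)) from exc
    if X.shape != (len(wells), len(genes)):
        raise MatrixFormatError(
            f"matrix shape {X.shape} inconsistent with metadata ({len(wells)}, {len(genes)})"
        )
    return CountMatrix(X, wells, genes)
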