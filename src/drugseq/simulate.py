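"""Truth-controlled simulator for plate-based 3' counting experiments.

Generates every input the pipeline consumes — paired FASTQ (read 1 =
barcode+UMI, read 2 = 3'-end cDNA fragment), pre-aligned SAM against a
synthetic transcriptome, plate maps — together with a per-read ground-truth
table (:class:`SimTruth` columns) so downstream stages can be checked
exactly.

Statistical model: per-well molecule counts are negative binomial
(gamma-Poisson, mean/dispersion parameterization); each molecule receives a
uniformly random UMI; PCR re-emission is geometric per molecule; sequencing
errors are i.i.d. base substitutions; cross-well contamination re-labels a
molecule with a uniformly random other well's barcode. Compound effects act
on target-gene means through a Hill dose-response on the log2 fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    CONTROL_TREATMENT,
    GEOMETRY_384,
    BarcodeSet,
    PlateGeometry,
    PlateMap,
    ReadStructure,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i

TRUTH_COLUMNS = ["read_id", "well", "gene", "umi", "is_duplicate", "is_contaminant", "barcode_well"]


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


@dataclass
class SimTranscriptome:
    """Synthetic transcriptome: one transcript per gene, tagged by species.

    ``genes`` is indexed by gene id with columns ``species`` and ``length``;
    ``sequences`` maps gene id -> transcript sequence (bytes). ERCC spike-in
    controls carry species label ``"ERCC"``.
    """

    genes: pd.DataFrame
    sequences: dict[str, bytes]

    def __post_init__(self) -> None:
        if self.genes.index.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    def transcript_id(self, gene: str) -> str:
        return f"{gene}.t1"

    def annotation(self) -> pd.DataFrame:
        """transcript_id -> (gene_id, species) table."""
        return pd.DataFrame(
            {
                "transcript_id": [self.transcript_id(g) for g in self.genes.index],
                "gene_id": self.genes.index,
                "species": self.genes["species"].to_numpy(),
            }
        ).set_index("transcript_id")

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequences[g].decode()), id=self.transcript_id(g), description="")
            for g in self.genes.index
        ]
        seqio_write(records, str(path), "fasta")

    def write_annotation(self, path) -> None:
        self.annotation().reset_index().to_csv(path, sep="\t", index=False, header=False)


def build_transcriptome(
    n_genes_per_species: Mapping[str, int],
    mean_length: int = 800,
    seed: int = 0,
    min_length: int = 200,
    fasta: str | Path | None = None,
    annotation: str | Path | None = None,
) -> SimTranscriptome:
    """Random transcriptome with ``n_genes_per_species[species]`` genes each.

    Lengths are uniform in [0.5, 1.5] x ``mean_length`` (clipped at
    ``min_length``); sequences are uniform over ACGT. Deterministic given
    ``seed``. Optionally writes a FASTA and a ``transcript gene species``
    annotation TSV.
    """
    if not any(n >= 1 for n in n_genes_per_species.values()):
        raise ValueError("need at least one gene for at least one species")
    if mean_length < min_length:
        raise ValueError(f"mean_length {mean_length} below minimum fragment length {min_length}")
    rng = np.random.default_rng(seed)
    ids, species = [], []
    for sp, n in n_genes_per_species.items():
        for i in range(n):
            ids.append(f"ERCC-{i:05d}" if sp == "ERCC" else f"{sp}_g{i:04d}")
            species.append(sp)
    lengths = rng.integers(max(min_length, mean_length // 2), mean_length * 3 // 2 + 1, len(ids))
    sequences = {
        g: bytes(_BASES[rng.integers(0, 4, size=int(L))]) for g, L in zip(ids, lengths)
    }
    genes = pd.DataFrame({"species": species, "length": lengths}, index=pd.Index(ids, name="gene_id"))
    tx = SimTranscriptome(genes, sequences)
    if fasta is not None:
        tx.write_fasta(fasta)
    if annotation is not None:
        tx.write_annotation(annotation)
    return tx


# ---------------------------------------------------------------------------
# expression profiles and compound effects
# ---------------------------------------------------------------------------


@dataclass
class ExpressionProfile:
    """Per-gene negative-binomial parameters: mean molecule count and dispersion.

    Variance = mean + dispersion * mean**2 (dispersion -> 0 is Poisson).
    """

    table: pd.DataFrame  # index gene_id; columns mean, dispersion

    def __post_init__(self) -> None:
        if (self.table["mean"] < 0).any():
            raise ValueError("negative means")
        if (self.table["dispersion"] < 0).any():
            raise ValueError("negative dispersion")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


def random_profile(
    gene_ids: Sequence[str],
    total_molecules: float,
    dispersion: float = 0.1,
    seed: int = 0,
    lognormal_sigma: float = 1.0,
) -> ExpressionProfile:
    """Lognormal relative abundances scaled so means sum to ``total_molecules``."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(0.0, lognormal_sigma, len(gene_ids))
    means = raw / raw.sum() * total_molecules
    return ExpressionProfile(
        pd.DataFrame(
            {"mean": means, "dispersion": dispersion},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )


def sample_negative_binomial(
    means: np.ndarray, dispersion: np.ndarray | float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    means = np.asarray(means, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), means.shape)
    out = np.zeros(means.shape, dtype=np.int64)
    pois = disp <= 0
    if pois.any():
        out[pois] = rng.poisson(means[pois])
    nb = ~pois & (means > 0)
    if nb.any():
        shape = 1.0 / disp[nb]
        lam = rng.gamma(shape, means[nb] * disp[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_well_molecules(profile: ExpressionProfile, seed: int = 0) -> pd.Series:
    """True molecule counts for one well, drawn per gene from the NB model."""
    rng = np.random.default_rng(seed)
    counts = sample_negative_binomial(
        profile.table["mean"].to_numpy(), profile.table["dispersion"].to_numpy(), rng
    )
    return pd.Series(counts, index=profile.table.index, name="molecules")


@dataclass(frozen=True)
class CompoundEffect:
    """Transcriptional effect of one compound: Hill dose-response on log2FC.

    ``target_lfc`` maps gene id -> maximal log2 fold change; the applied
    log2FC at dose d is ``lfc_max * d^h / (d^h + ec50^h)``.
    """

    target_lfc: Mapping[str, float]
    ec50_um: float = 1.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("EC50 must be positive")
        if self.hill <= 0:
            raise ValueError("Hill coefficient must be positive")

    def occupancy(self, dose_um: float) -> float:
        if dose_um <= 0:
            return 0.0
        dh = dose_um**self.hill
        return dh / (dh + self.ec50_um**self.hill)

    def applied_log2fc(self, dose_um: float) -> dict[str, float]:
        occ = self.occupancy(dose_um)
        return {g: lfc * occ for g, lfc in self.target_lfc.items()}


def simulate_compound_plate(
    plate: PlateMap,
    base_profile: ExpressionProfile,
    effects: Mapping[str, CompoundEffect],
    seed: int = 0,
    control: str = CONTROL_TREATMENT,
) -> pd.DataFrame:
    """Molecule counts (wells x genes) for a compound-treatment plate.

    Target-gene NB means are scaled by ``2**applied_log2fc(dose)``; control
    wells use the base profile unchanged.
    """
    rng = np.random.default_rng(seed)
    genes = base_profile.table.index
    base_means = base_profile.table["mean"].to_numpy(dtype=float)
    disp = base_profile.table["dispersion"].to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for well, row in plate.table.iterrows():
        means = base_means.copy()
        treatment = row["treatment"]
        if treatment != control:
            if treatment not in effects:
                raise KeyError(f"no CompoundEffect configured for treatment {treatment!r}")
            eff = effects[treatment]
            dose = float(row["dose_um"]) if pd.notna(row["dose_um"]) else 0.0
            for g, lfc in eff.applied_log2fc(dose).items():
                if g in gene_pos:
                    means[gene_pos[g]] *= 2.0**lfc
        rows.append(sample_negative_binomial(means, disp, rng))
    return pd.DataFrame(np.vstack(rows), index=plate.table.index, columns=genes)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _ints_to_base_matrix(values: np.ndarray, length: int) -> np.ndarray:
    """Encode integers in [0, 4^length) as (n, length) uint8 base matrices."""
    digits = np.empty((len(values), length), dtype=np.uint8)
    v = values.copy()
    for pos in range(length - 1, -1, -1):
        digits[:, pos] = v & 3
        v >>= 2
    return _BASES[digits]


def _matrix_to_str_array(mat: np.ndarray) -> np.ndarray:
    n, L = mat.shape
    return np.ascontiguousarray(mat).view(f"S{L}").ravel().astype(str)


def apply_substitution_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place i.i.d. substitution errors at ``rate`` per base (ACGT positions only)."""
    if rate <= 0 or mat.size == 0:
        return
    n_err = rng.binomial(mat.size, rate)
    if n_err == 0:
        return
    flat = mat.reshape(-1)
    idx = rng.integers(0, mat.size, n_err)
    shift = rng.integers(1, 4, n_err).astype(np.uint8)
    flat[idx] = _BASES[(_CODE_LUT[flat[idx]] + shift) % 4]


def _write_fastq(path, ids_prefixed: np.ndarray, seqs: np.ndarray) -> None:
    """Write fixed-width FASTQ records from a uint8 sequence matrix."""
    n, L = seqs.shape
    idw = ids_prefixed.dtype.itemsize  # bytes per id
    rec_len = 1 + idw + 1 + L + 3 + L + 1
    rec = np.empty((n, rec_len), dtype=np.uint8)
    rec[:, 0] = ord("@")
    rec[:, 1 : 1 + idw] = ids_prefixed.view(np.uint8).reshape(n, idw)
    rec[:, 1 + idw] = ord("\n")
    rec[:, 2 + idw : 2 + idw + L] = seqs
    rec[:, 2 + idw + L] = ord("\n")
    rec[:, 3 + idw + L] = ord("+")
    rec[:, 4 + idw + L] = ord("\n")
    rec[:, 5 + idw + L : 5 + idw + 2 * L] = ord("I")
    rec[:, -1] = ord("\n")
    with open(path, "wb") as fh:
        fh.write(rec.tobytes())


def _read_ids(n: int) -> np.ndarray:
    """Fixed-width read ids r000...0, r000...1, ... as an |S array."""
    width = max(len(str(max(n - 1, 0))), 1)
    nums = np.char.zfill(np.arange(n).astype(f"U{width}"), width)
    return np.char.add("r", nums).astype(f"S{width + 1}")


def simulate_reads(
    molecules: pd.DataFrame,
    transcriptome: SimTranscriptome,
    barcode_set: BarcodeSet,
    structure: ReadStructure = ReadStructure(),
    *,
    pcr_duplication_rate: float = 0.0,
    base_error_rate: float = 0.0,
    cross_contamination_rate: float = 0.0,
    seed: int = 0,
    r1_path: str | Path = "r1.fastq",
    r2_path: str | Path = "r2.fastq",
    truth_path: str | Path | None = None,
    read2_length: int = 50,
    polyt_tail: int = 6,
    three_prime_window: int = 400,
) -> pd.DataFrame:
    """Emit paired FASTQ for a wells x genes molecule table, plus per-read truth.

    Every molecule gets a uniform random UMI; with probability
    ``cross_contamination_rate`` it is emitted under a random *other* well's
    barcode (flagged); PCR re-emission is geometric with parameter
    ``1 - pcr_duplication_rate`` (rate 0 = single copy); substitution errors
    are applied per base to both mates. Read 2 is a fragment from the 3'
    terminal window of the transcript; duplicates re-emit the same
    (barcode, UMI, fragment). Returns the truth table (one row per read pair,
    in file order).
    """
    for p in (pcr_duplication_rate, base_error_rate, cross_contamination_rate):
        if not 0 <= p < 1:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    wells = list(molecules.index)
    genes = list(molecules.columns)
    unknown = set(wells) - set(barcode_set.mapping.values())
    if unknown:
        raise ValueError(f"wells missing from barcode set: {sorted(unknown)[:5]}")

    counts = molecules.to_numpy(dtype=np.int64)
    well_idx_mol, gene_idx_mol = np.nonzero(counts)
    reps = counts[well_idx_mol, gene_idx_mol]
    well_idx_mol = np.repeat(well_idx_mol, reps)
    gene_idx_mol = np.repeat(gene_idx_mol, reps)
    n_mol = len(well_idx_mol)

    umi_len = structure.umi_length
    umi_ints = rng.integers(0, 4**umi_len, n_mol, dtype=np.int64)

    # cross-well contamination: molecule emitted under another well's barcode
    contam = (
        rng.random(n_mol) < cross_contamination_rate
        if cross_contamination_rate > 0 and len(wells) > 1
        else np.zeros(n_mol, dtype=bool)
    )
    barcode_well_idx = well_idx_mol.copy()
    if contam.any():
        offset = rng.integers(1, len(wells), contam.sum())
        barcode_well_idx[contam] = (well_idx_mol[contam] + offset) % len(wells)

    # 3' fragment start per molecule (duplicates share the fragment)
    gene_lengths = transcriptome.genes["length"].reindex(genes).to_numpy(dtype=np.int64)
    if (gene_lengths < read2_length).any():
        raise ValueError("transcript shorter than read2_length")
    lo = np.maximum(gene_lengths - three_prime_window, 0)
    hi = gene_lengths - read2_length
    frag_start = lo[gene_idx_mol] + (
        rng.random(n_mol) * (np.minimum(hi, gene_lengths)[gene_idx_mol] - lo[gene_idx_mol] + 1)
    ).astype(np.int64)

    # PCR re-emission
    if pcr_duplication_rate > 0:
        copies = rng.geometric(1.0 - pcr_duplication_rate, n_mol)
    else:
        copies = np.ones(n_mol, dtype=np.int64)
    order = np.repeat(np.arange(n_mol), copies)
    first = np.zeros(len(order), dtype=bool)
    first[np.cumsum(copies) - copies] = True
    is_dup = ~first

    n_reads = len(order)
    src_w = well_idx_mol[order]
    bc_w = barcode_well_idx[order]
    g_idx = gene_idx_mol[order]
    umi_r = umi_ints[order]
    start_r = frag_start[order]
    contam_r = contam[order]

    # read 1: barcode + UMI + poly-T
    well_to_bc = barcode_set.well_to_barcode()
    bc_mat = np.frombuffer(
        "".join(well_to_bc[w] for w in wells).encode(), dtype=np.uint8
    ).reshape(len(wells), structure.barcode_length)
    r1_len = structure.min_read1_length + polyt_tail
    r1 = np.full((n_reads, r1_len), ord("T"), dtype=np.uint8)
    r1[:, structure.barcode_offset : structure.barcode_offset + structure.barcode_length] = (
        bc_mat[bc_w]
    )
    umi_mat = _ints_to_base_matrix(umi_r, umi_len)
    r1[:, structure.umi_offset : structure.umi_offset + umi_len] = umi_mat

    # read 2: fragment from the 3' window, gathered from a concatenated buffer
    seq_buf = np.frombuffer(b"".join(transcriptome.sequences[g] for g in genes), dtype=np.uint8)
    offsets = np.concatenate([[0], np.cumsum(gene_lengths)])[:-1]
    r2 = np.empty((n_reads, read2_length), dtype=np.uint8)
    base_idx = offsets[g_idx] + start_r
    chunk = 200_000
    col = np.arange(read2_length, dtype=np.int64)
    for s in range(0, n_reads, chunk):
        e = min(s + chunk, n_reads)
        r2[s:e] = seq_buf[base_idx[s:e, None] + col[None, :]]

    # truth is recorded *before* sequencing errors
    read_ids = _read_ids(n_reads)
    umi_strings = _matrix_to_str_array(umi_mat)
    well_arr = np.asarray(wells)
    truth = pd.DataFrame(
        {
            "read_id": read_ids.astype(str),
            "well": well_arr[src_w],
            "gene": np.asarray(genes)[g_idx],
            "umi": umi_strings,
            "is_duplicate": is_dup,
            "is_contaminant": contam_r,
            "barcode_well": well_arr[bc_w],
        }
    )

    apply_substitution_errors(r1, base_error_rate, rng)
    apply_substitution_errors(r2, base_error_rate, rng)
    _write_fastq(r1_path, read_ids, r1)
    _write_fastq(r2_path, read_ids, r2)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _iter_fastq_ids(path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, _seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0]


def simulate_alignments(
    truth: pd.DataFrame,
    transcriptome: SimTranscriptome,
    multimap_rate: float = 0.0,
    seed: int = 0,
    sam_path: str | Path = "aligned.sam",
    tagged_fastq: str | Path | None = None,
    barcode_set: BarcodeSet | None = None,
    read2_length: int = 50,
) -> Path:
    """Write a SAM of read-2 alignments implied by the simulation truth.

    Each read maps to its true gene's transcript. With probability
    ``multimap_rate`` a read is multimapped: its primary record gets a low
    MAPQ and a secondary record to a different transcript is emitted.
    Query names carry the demultiplexer tag ``<id>_<barcode>_<umi>``; when
    ``tagged_fastq`` is given, the (possibly error-containing, corrected)
    names produced by the demultiplexer are used verbatim and only reads
    present in that file are emitted. Otherwise tags are reconstructed from
    the truth table (true UMI, and the recorded barcode well's sequence when
    ``barcode_set`` is given, else the well label itself).
    """
    rng = np.random.default_rng(seed)
    gene_of = dict(zip(truth["read_id"], truth["gene"]))
    if tagged_fastq is not None:
        qnames = list(_iter_fastq_ids(tagged_fastq))
        read_ids = [q.rsplit("_", 2)[0] for q in qnames]
    else:
        # reconstruct tags from truth: barcode of the *recorded* barcode well
        read_ids = list(truth["read_id"])
        bc_of = barcode_set.well_to_barcode() if barcode_set is not None else {}
        qnames = [
            f"{r}_{bc_of.get(bw, bw)}_{u}"
            for r, bw, u in zip(truth["read_id"], truth["barcode_well"], truth["umi"])
        ]

    tx_ids = [transcriptome.transcript_id(g) for g in transcriptome.genes.index]
    tx_len = transcriptome.genes["length"].to_numpy()
    tx_index = {g: i for i, g in enumerate(transcriptome.genes.index)}

    n = len(qnames)
    multi = rng.random(n) < multimap_rate if multimap_rate > 0 else np.zeros(n, dtype=bool)
    other = rng.integers(1, max(len(tx_ids), 2), n)

    cigar = f"{read2_length}M"
    sam_path = Path(sam_path)
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for t, L in zip(tx_ids, tx_len):
            fh.write(f"@SQ\tSN:{t}\tLN:{int(L)}\n")
        lines: list[str] = []
        for i, (qname, rid) in enumerate(zip(qnames, read_ids)):
            gi = tx_index[gene_of[rid]]
            if multi[i]:
                gj = (gi + other[i]) % len(tx_ids)
                lines.append(f"{qname}\t0\t{tx_ids[gi]}\t1\t3\t{cigar}\t*\t0\t0\t*\t*\n")
                lines.append(f"{qname}\t256\t{tx_ids[gj]}\t1\t0\t{cigar}\t*\t0\t0\t*\t*\n")
            else:
                lines.append(f"{qname}\t0\t{tx_ids[gi]}\t1\t255\t{cigar}\t*\t0\t0\t*\t*\n")
            if len(lines) >= 100_000:
                fh.write("".join(lines))
                lines = []
        fh.write("".join(lines))
    return sam_path


# ---------------------------------------------------------------------------
# barnyard plates
# ---------------------------------------------------------------------------


def checkerboard_plate_map(
    geometry: PlateGeometry = GEOMETRY_384,
    species: tuple[str, str] = ("human", "mouse"),
    cell_lines: tuple[str, str] = ("293T", "C2C12"),
) -> PlateMap:
    """Interleaved two-species plate map: species alternate by (row+column) parity."""
    rows = []
    replicate = 0
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            sp_i = (r + c) % 2
            replicate += 1
            pad = geometry.column_pad
            rows.append(
                {
                    "well": f"{geometry.row_labels()[r]}{c + 1:0{pad}d}",
                    "treatment": "none",
                    "dose_um": np.nan,
                    "replicate": replicate,
                    "species": species[sp_i],
                    "cell_line": cell_lines[sp_i],
                }
            )
    table = pd.DataFrame(rows).set_index("well")
    return PlateMap(table, geometry)


@dataclass
class BarnyardSim:
    """Bundle of everything a simulated barnyard plate produced."""

    plate_map: PlateMap
    molecules: pd.DataFrame
    truth: pd.DataFrame
    transcriptome: SimTranscriptome
    barcode_set: BarcodeSet
    r1_path: Path
    r2_path: Path
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_barnyard_plate(
    transcriptome: SimTranscriptome,
    barcode_set: BarcodeSet,
    outdir: str | Path,
    geometry: PlateGeometry = GEOMETRY_384,
    molecules_per_well: int = 2000,
    dispersion: float = 0.1,
    ercc_molecules_per_well: float = 0.0,
    structure: ReadStructure = ReadStructure(),
    *,
    pcr_duplication_rate: float = 0.0,
    base_error_rate: float = 0.0,
    cross_contamination_rate: float = 0.0,
    seed: int = 0,
) -> BarnyardSim:
    """Simulate an interleaved human/mouse plate down to paired FASTQ + truth.

    Alternating wells express only their own species' genes (plus an optional
    flat ERCC spike); read/SAM generation then follows :func:`simulate_reads`
    and :func:`simulate_alignments`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_present = set(transcriptome.genes["species"]) - {"ERCC"}
    if len(species_present) < 2:
        raise ValueError("barnyard simulation needs two non-ERCC species")
    plate = checkerboard_plate_map(geometry)
    rng = np.random.default_rng(seed)

    genes = transcriptome.genes
    gene_ids = list(genes.index)
    profiles = {}
    for sp in sorted(species_present):
        sp_genes = list(genes.index[genes["species"] == sp])
        profiles[sp] = random_profile(
            sp_genes,
            molecules_per_well,
            dispersion,
            seed=int(rng.integers(2**31)),
        )
    ercc_genes = list(genes.index[genes["species"] == "ERCC"])

    col_pos = {g: i for i, g in enumerate(gene_ids)}
    counts = np.zeros((len(plate.wells), len(gene_ids)), dtype=np.int64)
    for wi, (well, row) in enumerate(plate.table.iterrows()):
        prof = profiles[row["species"]]
        draws = sample_negative_binomial(
            prof.table["mean"].to_numpy(), prof.table["dispersion"].to_numpy(), rng
        )
        for g, v in zip(prof.table.index, draws):
            counts[wi, col_pos[g]] = v
        if ercc_genes and ercc_molecules_per_well > 0:
            erc = rng.poisson(ercc_molecules_per_well / len(ercc_genes), len(ercc_genes))
            for g, v in zip(ercc_genes, erc):
                counts[wi, col_pos[g]] = v
    molecules = pd.DataFrame(counts, index=plate.wells, columns=gene_ids)

    r1 = outdir / "barnyard_R1.fastq"
    r2 = outdir / "barnyard_R2.fastq"
    truth = simulate_reads(
        molecules,
        transcriptome,
        barcode_set,
        structure,
        pcr_duplication_rate=pcr_duplication_rate,
        base_error_rate=base_error_rate,
        cross_contamination_rate=cross_contamination_rate,
        seed=int(rng.integers(2**31)),
        r1_path=r1,
        r2_path=r2,
        truth_path=outdir / "barnyard_truth.tsv",
    )
    from .core import write_plate_map

    write_plate_map(plate, outdir / "barnyard_platemap.csv")
    barcode_set.write_tsv(outdir / "barnyard_whitelist.tsv")
    return BarnyardSim(
        plate_map=plate,
        molecules=molecules,
        truth=truth,
        transcriptome=transcriptome,
        barcode_set=barcode_set,
        r1_path=r1,
        r2_path=r2,
        paths={
            "truth": outdir / "barnyard_truth.tsv",
            "platemap": outdir / "barnyard_platemap.csv",
            "whitelist": outdir / "barnyard_whitelist.tsv",
        },
    )


# ---------------------------------------------------------------------------
# simulator configuration files
# ---------------------------------------------------------------------------


def load_sim_config(path: str | Path) -> dict:
    """Load a simulator configuration (YAML or JSON) into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_sim_config(config: dict, path: str | Path) -> None:
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(config, indent=2))
    else:
        Path(path).write_text(yaml.safe_dump(config))
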