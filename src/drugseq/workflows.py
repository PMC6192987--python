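"""End-to-end pipeline compositions used by the CLI, examples and tests."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import count as count_mod
from . import demux as demux_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from .core import GEOMETRY_384, PlateGeometry, ReadStructure, generate_barcode_set


@dataclass
class BarnyardRun:
    """Everything the barnyard purity experiment produced."""

    sim: sim_mod.BarnyardSim
    demux_stats: demux_mod.DemuxStats
    matrix: count_mod.CountMatrix
    purity: qc_mod.PurityReport


def barnyard_purity_experiment(
    outdir: str | Path,
    seed: int = 0,
    geometry: PlateGeometry = GEOMETRY_384,
    molecules_per_well: int = 2000,
    n_genes_per_species: int = 400,
    n_ercc: int = 20,
    *,
    cross_contamination_rate: float = 0.005,
    base_error_rate: float = 0.001,
    pcr_duplication_rate: float = 0.3,
    max_mismatch: int = 1,
    purity_threshold: float = 0.96,
) -> BarnyardRun:
    """Simulate a two-species checkerboard plate and push it through the
    pipeline: reads -> demultiplex -> pre-aligned SAM -> exact UMI counting ->
    species purity.

    The returned :class:`qc.PurityReport` carries the per-well purities and
    the fraction of nonempty wells whose dominant-species UMI share exceeds
    ``purity_threshold``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    structure = ReadStructure()

    transcriptome = sim_mod.build_transcriptome(
        {"human": n_genes_per_species, "mouse": n_genes_per_species, "ERCC": n_ercc},
        mean_length=800,
        seed=int(rng.integers(2**31)),
    )
    barcodes = generate_barcode_set(
        geometry.n_wells, length=structure.barcode_length, min_hamming=3,
        seed=int(rng.integers(2**31)), geometry=geometry,
    )
    sim = sim_mod.simulate_barnyard_plate(
        transcriptome,
        barcodes,
        outdir,
        geometry=geometry,
        molecules_per_well=molecules_per_well,
        ercc_molecules_per_well=20.0,
        structure=structure,
        pcr_duplication_rate=pcr_duplication_rate,
        base_error_rate=base_error_rate,
        cross_contamination_rate=cross_contamination_rate,
        seed=int(rng.integers(2**31)),
    )

    tagged = outdir / "tagged_R2.fastq"
    stats = demux_mod.tag_reads(
        sim.r1_path,
        sim.r2_path,
        barcodes,
        structure,
        max_mismatch=max_mismatch,
        out_path=tagged,
        stats_path=outdir / "demux_stats.json",
    )

    sam = sim_mod.simulate_alignments(
        sim.truth,
        transcriptome,
        multimap_rate=0.0,
        seed=int(rng.integers(2**31)),
        sam_path=outdir / "tagged.sam",
        tagged_fastq=tagged,
    )

    matrix = count_mod.count_sam(
        sam, sim.plate_map, barcodes, transcriptome.annotation(), umi_collapse="exact"
    )
    purity = qc_mod.species_purity(matrix, purity_threshold)
    return BarnyardRun(sim=sim, demux_stats=stats, matrix=matrix, purity=purity)
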