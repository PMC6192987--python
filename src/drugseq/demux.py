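"""Well-barcode demultiplexing: extract barcode+UMI from read 1 and tag read 2.

The first pipeline stage moves the well barcode and UMI from read 1 into the
read-2 sequence identifier (``<id>_<barcode>_<umi>``) so that a transcriptome
alignment of read 2 alone still carries the well and molecule identity.
Barcode matching tolerates a configurable number of mismatches; with a
whitelist of minimum pairwise distance >= 2*max_mismatch+1 the correction is
unambiguous for true-barcode sequencing errors.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import BarcodeSet, ReadStructure, hamming_distance

#: sentinel well value for ambiguous neighbor-table entries
_AMBIGUOUS = object()

EXTENDED_ALPHABET = "ACGTN"


class TruncatedReadError(ValueError):
    """Read 1 shorter than the configured barcode/UMI extent."""


class PairingError(ValueError):
    """Read 1 and read 2 files have different record counts."""


def extract_barcode_umi(read1_seq: str, structure: ReadStructure) -> tuple[str, str]:
    """Barcode and UMI substrings of read 1 at the configured offsets (uppercased)."""
    if len(read1_seq) < structure.min_read1_length:
        raise TruncatedReadError(
            f"read1 length {len(read1_seq)} < required {structure.min_read1_length}"
        )
    seq = read1_seq.upper()
    bc = seq[structure.barcode_offset : structure.barcode_offset + structure.barcode_length]
    umi = seq[structure.umi_offset : structure.umi_offset + structure.umi_length]
    return bc, umi


class BarcodeMatcher:
    """Exact + mismatch-tolerant barcode lookup against a whitelist.

    For ``max_mismatch == 1`` all single-mismatch neighbors (over ACGTN — an
    N in the observed barcode mismatches every base) are precomputed into a
    dict; larger tolerances fall back to a linear scan. Exact hits always
    win; a non-exact observation matching >= 2 whitelist entries within
    tolerance is ambiguous.
    """

    def __init__(self, barcode_set: BarcodeSet, max_mismatch: int = 1):
        self.barcode_set = barcode_set
        self.max_mismatch = max_mismatch
        self._exact = dict(barcode_set.mapping)
        self._neighbors: dict[str, object] | None = None
        if max_mismatch == 1:
            neighbors: dict[str, object] = {}
            for barcode, well in barcode_set.mapping.items():
                for pos in range(len(barcode)):
                    for base in EXTENDED_ALPHABET:
                        if base == barcode[pos]:
                            continue
                        variant = barcode[:pos] + base + barcode[pos + 1 :]
                        if variant in self._exact:
                            continue
                        if variant in neighbors and neighbors[variant] != (barcode, well):
                            neighbors[variant] = _AMBIGUOUS
                        else:
                            neighbors[variant] = (barcode, well)
            self._neighbors = neighbors

    def match(self, observed: str) -> tuple[str | None, str | None, str]:
        """Return (well, corrected_barcode, status).

        status is ``"exact"``, ``"corrected"``, ``"ambiguous"`` or
        ``"unassigned"``; well is None unless assigned.
        """
        if len(observed) != self.barcode_set.length:
            raise ValueError("observed barcode length differs from whitelist length")
        well = self._exact.get(observed)
        if well is not None:
            return well, observed, "exact"
        if self.max_mismatch == 0:
            return None, None, "unassigned"
        if self._neighbors is not None:
            hit = self._neighbors.get(observed)
            if hit is None:
                return None, None, "unassigned"
            if hit is _AMBIGUOUS:
                return None, None, "ambiguous"
            barcode, well = hit  # type: ignore[misc]
            return well, barcode, "corrected"
        # general tolerance: linear scan, N mismatches everything
        candidates = []
        for barcode, w in self._exact.items():
            d = sum(1 for a, b in zip(observed, barcode) if a != b or a == "N")
            if d <= self.max_mismatch:
                candidates.append((barcode, w))
        if len(candidates) == 1:
            return candidates[0][1], candidates[0][0], "corrected"
        if len(candidates) > 1:
            return None, None, "ambiguous"
        return None, None, "unassigned"


def match_barcode(
    observed: str, barcode_set: BarcodeSet, max_mismatch: int = 1
) -> str | None:
    """Well for an observed barcode, or None when unassigned/ambiguous."""
    well, _, _ = BarcodeMatcher(barcode_set, max_mismatch).match(observed)
    return well


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------


@dataclass
class DemuxStats:
    """Read accounting for one demultiplexing run.

    Invariant: assigned + unassigned + ambiguous == total; corrected counts
    the subset of assigned reads recovered via mismatch tolerance.
    """

    total: int = 0
    assigned: int = 0
    corrected: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    per_well: Counter = field(default_factory=Counter)
    unassigned_reasons: Counter = field(default_factory=Counter)

    def check(self) -> None:
        if self.assigned + self.unassigned + self.ambiguous != self.total:
            raise AssertionError("demux accounting identity violated")
        if self.corrected > self.assigned:
            raise AssertionError("corrected exceeds assigned")

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "assigned": self.assigned,
            "corrected": self.corrected,
            "ambiguous": self.ambiguous,
            "unassigned": self.unassigned,
            "unassigned_reasons": dict(self.unassigned_reasons),
            "per_well": dict(sorted(self.per_well.items())),
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def per_well_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_well.items()), columns=["well", "assigned_reads"]
        ).set_index("well")


# ---------------------------------------------------------------------------
# tagging
# ---------------------------------------------------------------------------


def make_tag(read_id: str, barcode: str, umi: str) -> str:
    return f"{read_id}_{barcode}_{umi}"


def parse_tag(qname: str) -> tuple[str, str, str]:
    """Invert :func:`make_tag`: (original id, barcode, umi)."""
    original, barcode, umi = qname.rsplit("_", 2)
    return original, barcode, umi


def tag_reads(
    r1_path,
    r2_path,
    barcode_set: BarcodeSet,
    structure: ReadStructure = ReadStructure(),
    max_mismatch: int = 1,
    out_path=None,
    stats_path=None,
    keep_unassigned_path=None,
) -> DemuxStats:
    """Demultiplex a FASTQ pair: write tagged read-2 records and return stats.

    Each retained read-2 record's id becomes ``<id>_<corrected_barcode>_<umi>``;
    unassigned/ambiguous reads are dropped from the tagged output (optionally
    written with a reason code to ``keep_unassigned_path``). Record order is
    preserved. Raises :class:`PairingError` on unequal record counts.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    matcher = BarcodeMatcher(barcode_set, max_mismatch)
    stats = DemuxStats()
    out_chunks: list[str] = []
    reject_chunks: list[str] = []
    sentinel = object()

    out_fh = open(out_path, "w") if out_path is not None else None
    rej_fh = open(keep_unassigned_path, "w") if keep_unassigned_path is not None else None
    try:
        with open(r1_path) as fh1, open(r2_path) as fh2:
            it1 = FastqGeneralIterator(fh1)
            it2 = FastqGeneralIterator(fh2)
            while True:
                rec1 = next(it1, sentinel)
                rec2 = next(it2, sentinel)
                if rec1 is sentinel or rec2 is sentinel:
                    if rec1 is not rec2:
                        raise PairingError("read1/read2 record counts differ")
                    break
                title1, seq1, _ = rec1
                title2, seq2, qual2 = rec2
                stats.total += 1
                rid = title2.split()[0]
                try:
                    bc, umi = extract_barcode_umi(seq1, structure)
                except TruncatedReadError:
                    stats.unassigned += 1
                    stats.unassigned_reasons["truncated_read1"] += 1
                    if rej_fh is not None:
                        reject_chunks.append(f"@{rid} reason=truncated_read1\n{seq2}\n+\n{qual2}\n")
                    continue
                well, corrected_bc, status = matcher.match(bc)
                if status in ("exact", "corrected"):
                    stats.assigned += 1
                    stats.per_well[well] += 1
                    if status == "corrected":
                        stats.corrected += 1
                    if out_fh is not None:
                        out_chunks.append(
                            f"@{make_tag(rid, corrected_bc, umi)}\n{seq2}\n+\n{qual2}\n"
                        )
                elif status == "ambiguous":
                    stats.ambiguous += 1
                    if rej_fh is not None:
                        reject_chunks.append(f"@{rid} reason=ambiguous\n{seq2}\n+\n{qual2}\n")
                else:
                    stats.unassigned += 1
                    stats.unassigned_reasons["no_match"] += 1
                    if rej_fh is not None:
                        reject_chunks.append(f"@{rid} reason=no_match\n{seq2}\n+\n{qual2}\n")
                if out_fh is not None and len(out_chunks) >= 100_000:
                    out_fh.write("".join(out_chunks))
                    out_chunks = []
                if rej_fh is not None and len(reject_chunks) >= 100_000:
                    rej_fh.write("".join(reject_chunks))
                    reject_chunks = []
        if out_fh is not None and out_chunks:
            out_fh.write("".join(out_chunks))
        if rej_fh is not None and reject_chunks:
            rej_fh.write("".join(reject_chunks))
    finally:
        if out_fh is not None:
            out_fh.close()
        if rej_fh is not None:
            rej_fh.close()

    stats.check()
    if stats_path is not None:
        stats.write_json(stats_path)
    return stats
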