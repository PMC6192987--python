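"""Plate, barcode and read-structure domain model.

The pipeline operates on multiwell plates (384-well by default, 1536
supported) in which every well's cDNA carries a well-specific barcode and a
random unique molecular index (UMI) on the reverse-transcription primer.
This module holds the shared vocabulary: the read-1 layout
(:class:`ReadStructure`), plate geometry and well addressing, the barcode
whitelist (:class:`BarcodeSet`) with minimum pairwise Hamming-distance
guarantees, and the plate map linking wells to treatments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"

#: columns required in a plate-map CSV
PLATE_MAP_COLUMNS = ["well", "treatment", "dose_um", "replicate", "species", "cell_line"]


class BarcodeFeasibilityError(RuntimeError):
    """Raised when a barcode set with the requested size/distance cannot be found."""


class PlateMapError(ValueError):
    """Raised for plate maps that violate geometry or replicate constraints."""


# ---------------------------------------------------------------------------
# read structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadStructure:
    """Layout of read 1: where the well barcode and the UMI sit.

    Defaults describe a 10-base well barcode at the start of read 1 followed
    immediately by a 10-base UMI.
    """

    barcode_length: int = 10
    umi_length: int = 10
    barcode_offset: int = 0
    umi_offset: int = 10

    def __post_init__(self) -> None:
        if self.barcode_length <= 0 or self.umi_length <= 0:
            raise ValueError("barcode_length and umi_length must be positive")
        if self.barcode_offset < 0 or self.umi_offset < 0:
            raise ValueError("offsets must be non-negative")
        b = (self.barcode_offset, self.barcode_offset + self.barcode_length)
        u = (self.umi_offset, self.umi_offset + self.umi_length)
        if b[0] < u[1] and u[0] < b[1]:
            raise ValueError("barcode and UMI intervals overlap")

    @property
    def min_read1_length(self) -> int:
        return max(self.barcode_offset + self.barcode_length, self.umi_offset + self.umi_length)


# ---------------------------------------------------------------------------
# wells and geometry
# ---------------------------------------------------------------------------


def _row_label(i: int) -> str:
    # A..Z then AA, AB, ... (1536-well plates have 32 rows)
    if i < 26:
        return chr(ord("A") + i)
    return "A" + chr(ord("A") + i - 26)


_WELL_RE = re.compile(r"^([A-Z]{1,2})(\d{1,3})$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A plate well identified by row letter(s) and 1-based column."""

    row: str
    column: int

    def label(self, pad: int = 2) -> str:
        return f"{self.row}{self.column:0{pad}d}"

    @classmethod
    def from_label(cls, label: str) -> "WellAddress":
        m = _WELL_RE.match(label.strip().upper())
        if not m:
            raise PlateMapError(f"unparseable well label: {label!r}")
        return cls(m.group(1), int(m.group(2)))


@dataclass(frozen=True)
class PlateGeometry:
    """Rectangular plate geometry (rows x columns)."""

    n_rows: int = 16
    n_cols: int = 24

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def column_pad(self) -> int:
        # "A01" on 384-well plates, three digits on 1536
        return 3 if self.n_wells > 384 else 2

    def row_labels(self) -> list[str]:
        return [_row_label(i) for i in range(self.n_rows)]

    def wells(self) -> list[str]:
        """Row-major well labels ("A01", "A02", ...)."""
        pad = self.column_pad
        return [
            f"{_row_label(r)}{c + 1:0{pad}d}"
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def contains(self, address: WellAddress | str) -> bool:
        if isinstance(address, str):
            try:
                address = WellAddress.from_label(address)
            except PlateMapError:
                return False
        rows = self.row_labels()
        return address.row in rows and 1 <= address.column <= self.n_cols

    def normalize(self, label: str) -> str:
        """Canonical zero-padded form of a well label; raises if outside the plate."""
        addr = WellAddress.from_label(label)
        if not self.contains(addr):
            raise PlateMapError(f"well {label!r} outside {self.n_rows}x{self.n_cols} geometry")
        return addr.label(self.column_pad)


GEOMETRY_384 = PlateGeometry(16, 24)
GEOMETRY_1536 = PlateGeometry(32, 48)


# ---------------------------------------------------------------------------
# Hamming distance and barcode sets
# ---------------------------------------------------------------------------


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _pairwise_min_hamming(barcodes: list[str]) -> int:
    if len(barcodes) < 2:
        return len(barcodes[0]) if barcodes else 0
    L = len(barcodes[0])
    mat = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(-1, L)
    # pairwise mismatch counts via broadcasting; fine up to a few thousand codes
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    np.fill_diagonal(diff, L + 1)
    return int(diff.min())


@dataclass
class BarcodeSet:
    """Whitelist mapping barcode sequence -> well label.

    All barcodes share one length and every pair is at Hamming distance of at
    least ``min_pairwise_hamming`` (distance >= 3 permits unambiguous
    single-mismatch correction).
    """

    mapping: dict[str, str]
    min_pairwise_hamming: int = 3

    @property
    def length(self) -> int:
        return len(next(iter(self.mapping)))

    @property
    def barcodes(self) -> list[str]:
        return list(self.mapping)

    def well_to_barcode(self) -> dict[str, str]:
        return {w: b for b, w in self.mapping.items()}

    def validate(self) -> None:
        if not self.mapping:
            raise ValueError("empty barcode set")
        L = self.length
        for b in self.mapping:
            if len(b) != L:
                raise ValueError(f"barcode {b!r} length differs from {L}")
            if set(b) - set(DNA_ALPHABET):
                raise ValueError(f"barcode {b!r} contains non-ACGT characters")
        wells = list(self.mapping.values())
        if len(set(wells)) != len(wells):
            raise ValueError("barcode->well mapping is not bijective")
        observed = _pairwise_min_hamming(self.barcodes)
        if len(self.mapping) > 1 and observed < self.min_pairwise_hamming:
            raise ValueError(
                f"minimum pairwise Hamming distance {observed} < "
                f"required {self.min_pairwise_hamming}"
            )

    # -- serialization ------------------------------------------------------

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for barcode, well in self.mapping.items():
                fh.write(f"{barcode}\t{well}\n")

    @classmethod
    def read_tsv(cls, path, min_pairwise_hamming: int = 1) -> "BarcodeSet":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                barcode, well = line.rstrip("\n").split("\t")
                mapping[barcode] = well
        bset = cls(mapping, min_pairwise_hamming)
        bset.validate()
        return bset


def generate_barcode_set(
    n_wells: int,
    length: int = 10,
    min_hamming: int = 3,
    seed: int = 0,
    geometry: PlateGeometry | None = None,
    max_attempts_per_code: int = 400,
    restarts: int = 20,
) -> BarcodeSet:
    """Generate ``n_wells`` barcodes of ``length`` bases at pairwise distance >= ``min_hamming``.

    Greedy rejection sampling with restarts; deterministic given ``seed``.
    Raises :class:`BarcodeFeasibilityError` when the bounded search cannot
    place the requested number of codes.
    """
    if 4**length < n_wells:
        raise BarcodeFeasibilityError(f"4^{length} < {n_wells} wells")
    if min_hamming > length:
        raise BarcodeFeasibilityError(f"min_hamming {min_hamming} exceeds length {length}")
    if geometry is None:
        geometry = GEOMETRY_384 if n_wells <= 384 else GEOMETRY_1536
    wells = geometry.wells()
    if n_wells > len(wells):
        raise BarcodeFeasibilityError(f"{n_wells} wells exceed geometry {geometry}")

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    for _ in range(restarts):
        accepted = np.empty((0, length), dtype=np.uint8)
        attempts = 0
        budget = max_attempts_per_code * n_wells
        while len(accepted) < n_wells and attempts < budget:
            cand = bases[rng.integers(0, 4, size=length)]
            attempts += 1
            if len(accepted) == 0 or ((accepted != cand).sum(axis=1) >= min_hamming).all():
                accepted = np.vstack([accepted, cand])
        if len(accepted) == n_wells:
            codes = [bytes(row).decode() for row in accepted]
            bset = BarcodeSet(dict(zip(codes, wells[:n_wells])), min_hamming)
            bset.validate()
            return bset
    raise BarcodeFeasibilityError(
        f"could not place {n_wells} codes of length {length} at distance >= {min_hamming}"
    )


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

CONTROL_TREATMENT = "DMSO"


@dataclass
class PlateMap:
    """Well -> (treatment, dose, replicate, species, cell line) assignment.

    ``table`` is indexed by canonical well label. Controls carry
    ``dose_um = NaN``. Partial plates are allowed; ``validate(require_full=True)``
    additionally demands full geometry coverage.
    """

    table: pd.DataFrame
    geometry: PlateGeometry = field(default_factory=lambda: GEOMETRY_384)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def wells(self) -> list[str]:
        return list(self.table.index)

    def validate(self, require_full: bool = False) -> None:
        required = [c for c in PLATE_MAP_COLUMNS if c != "well"]
        missing = set(required) - set(self.table.columns)
        if missing:
            raise PlateMapError(f"plate map missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise PlateMapError(f"duplicate wells: {dups}")
        for well in self.table.index:
            if not self.geometry.contains(well):
                raise PlateMapError(
                    f"well {well!r} outside {self.geometry.n_rows}x{self.geometry.n_cols} plate"
                )
        # replicate indices unique within each (treatment, dose) group
        grouped = self.table.groupby(
            ["treatment", self.table["dose_um"].fillna(-1.0)], dropna=False
        )["replicate"]
        for key, reps in grouped:
            if reps.duplicated().any():
                raise PlateMapError(f"duplicate replicate index in group {key}")
        if require_full and set(self.table.index) != set(self.geometry.wells()):
            raise PlateMapError("plate map does not cover the full geometry")

    def control_wells(self, control: str = CONTROL_TREATMENT) -> list[str]:
        return list(self.table.index[self.table["treatment"] == control])

    def treatment_wells(self, treatment: str, dose_um: float | None = None) -> list[str]:
        mask = self.table["treatment"] == treatment
        if dose_um is not None:
            mask &= np.isclose(self.table["dose_um"].astype(float), dose_um)
        return list(self.table.index[mask])


def read_plate_map(path, geometry: PlateGeometry | None = None) -> PlateMap:
    """Read a plate map CSV (columns well,treatment,dose_um,replicate,species,cell_line)."""
    geometry = geometry or GEOMETRY_384
    df = pd.read_csv(path, dtype={"well": str})
    missing = set(PLATE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise PlateMapError(f"plate map CSV missing columns: {sorted(missing)}")
    df["well"] = [geometry.normalize(w) for w in df["well"]]
    df = df.set_index("well")
    df["dose_um"] = pd.to_numeric(df["dose_um"], errors="coerce")
    df["replicate"] = df["replicate"].astype(int)
    return PlateMap(df, geometry)


def write_plate_map(plate: PlateMap, path) -> None:
    out = plate.table.reset_index().rename(columns={"index": "well"})
    if "well" not in out.columns:
        out = out.rename(columns={out.columns[0]: "well"})
    out[PLATE_MAP_COLUMNS + [c for c in out.columns if c not in PLATE_MAP_COLUMNS]].to_csv(
        path, index=False
    )
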