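"""Antibody-oligonucleotide conjugate (AOC) panel definitions.

A panel describes the DNA layout of one MPX amplicon read: a UMI
identifying the individual AOC molecule, a protein-identity barcode,
and two 25-nt unique pixel identifiers (UPI-A / UPI-B) separated by the
universal binding-site motifs BS1 and BS2 that anchor pixel
hybridisation and, computationally, read parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

ALPHABET = "ACGT"

#: Field order of one synthetic amplicon read, 5'->3'.
DEFAULT_LAYOUT = ("umi", "barcode", "bs1", "upia", "bs2", "upib")

# 20-nt universal binding-site motifs used as read anchors. With 20 nt,
# the 10% mismatch rule admits exactly <=2 mismatches.
DEFAULT_BS1 = "GTAACGTTAGCTGATGCACC"
DEFAULT_BS2 = "CTTAGCAATGCCGTACGAGT"


class PanelCapacityError(ValueError):
    """Raised when the barcode space cannot host the requested panel."""


@dataclass(frozen=True)
class Marker:
    name: str
    barcode: str
    is_control: bool = False


@dataclass
class PanelConfig:
    """Marker panel plus the amplicon read layout.

    Parameters
    ----------
    markers
        Panel entries; barcodes must share one length and be pairwise
        Hamming distance >= 3 so single-mismatch demultiplexing is safe.
    umi_length, upi_length
        Lengths (nt) of the molecular and pixel identifiers.
    bs1, bs2
        Binding-site motif sequences.
    layout
        Ordered field names composing one read.
    """

    markers: list[Marker]
    umi_length: int = 10
    upi_length: int = 25
    bs1: str = DEFAULT_BS1
    bs2: str = DEFAULT_BS2
    layout: tuple[str, ...] = DEFAULT_LAYOUT

    _barcode_index: dict[str, str] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._barcode_index = {m.barcode: m.name for m in self.markers}

    def validate(self) -> None:
        if not self.markers:
            raise ValueError("panel must contain at least one marker")
        if self.umi_length <= 0 or self.upi_length <= 0:
            raise ValueError("umi_length and upi_length must be positive")
        lengths = {len(m.barcode) for m in self.markers}
        if len(lengths) != 1:
            raise ValueError("all marker barcodes must share one length")
        codes = [m.barcode for m in self.markers]
        if len(set(codes)) != len(codes):
            raise ValueError("marker barcodes must be unique")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                if hamming(codes[i], codes[j]) < 3:
                    raise ValueError(
                        f"barcodes {codes[i]!r} and {codes[j]!r} are closer "
                        "than Hamming distance 3"
                    )
        unknown = set(self.layout) - {"umi", "barcode", "bs1", "bs2", "upia", "upib"}
        if unknown:
            raise ValueError(f"unknown layout fields: {sorted(unknown)}")

    # -- geometry of one read ------------------------------------------------

    @property
    def barcode_length(self) -> int:
        return len(self.markers[0].barcode)

    def field_length(self, name: str) -> int:
        return {
            "umi": self.umi_length,
            "barcode": self.barcode_length,
            "bs1": len(self.bs1),
            "bs2": len(self.bs2),
            "upia": self.upi_length,
            "upib": self.upi_length,
        }[name]

    def field_slices(self) -> dict[str, slice]:
        """Positional slice of every layout field within a read."""
        out, offset = {}, 0
        for name in self.layout:
            n = self.field_length(name)
            out[name] = slice(offset, offset + n)
            offset += n
        return out

    @property
    def read_length(self) -> int:
        return sum(self.field_length(f) for f in self.layout)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker_for_barcode(self, barcode: str, max_mismatch: int = 1) -> str | None:
        """Resolve a barcode to a marker name, tolerating mismatches.

        Exact lookup first; otherwise the unique marker within
        ``max_mismatch`` (panel distance >= 3 guarantees uniqueness for
        ``max_mismatch`` = 1).
        """
        hit = self._barcode_index.get(barcode)
        if hit is not None:
            return hit
        if max_mismatch <= 0:
            return None
        best, best_d = None, max_mismatch + 1
        for code, name in self._barcode_index.items():
            d = hamming(code, barcode)
            if d < best_d:
                best, best_d = name, d
        return best if best_d <= max_mismatch else None

    # -- serialisation -------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "umi_length": self.umi_length,
            "upi_length": self.upi_length,
            "bs1": self.bs1,
            "bs2": self.bs2,
            "layout": list(self.layout),
            "markers": [
                {"name": m.name, "barcode": m.barcode, "is_control": m.is_control}
                for m in self.markers
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            markers=[
                Marker(d["name"], d["barcode"], bool(d.get("is_control", False)))
                for d in doc["markers"]
            ],
            umi_length=int(doc["umi_length"]),
            upi_length=int(doc["upi_length"]),
            bs1=doc["bs1"],
            bs2=doc["bs2"],
            layout=tuple(doc["layout"]),
        )


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """``n`` random nucleotide strings of ``length`` nt."""
    idx = rng.integers(0, 4, size=(n, length))
    lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    return [bytes(row).decode() for row in lut[idx]]


def generate_panel(
    n_markers: int,
    seed: int,
    barcode_length: int = 8,
    n_controls: int = 0,
    umi_length: int = 10,
    upi_length: int = 25,
) -> PanelConfig:
    """Draw a random panel with pairwise barcode distance >= 3.

    Rejection sampling over random barcodes; markers are named
    ``M001``..; the last ``n_controls`` markers are flagged as isotype
    controls (named ``CTRL*``). Deterministic for a fixed seed.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    attempts = 0
    max_attempts = 2000 * n_markers
    while len(codes) < n_markers:
        attempts += 1
        if attempts > max_attempts:
            raise PanelCapacityError(
                f"could not place {n_markers} barcodes of length "
                f"{barcode_length} at pairwise distance >= 3"
            )
        cand = random_sequences(rng, 1, barcode_length)[0]
        if all(hamming(cand, c) >= 3 for c in codes):
            codes.append(cand)
    markers = []
    n_targets = n_markers - n_controls
    for i, code in enumerate(codes):
        if i < n_targets:
            markers.append(Marker(f"M{i + 1:03d}", code, False))
        else:
            markers.append(Marker(f"CTRL{i - n_targets + 1}", code, True))
    return PanelConfig(
        markers=markers, umi_length=umi_length, upi_length=upi_length
    )
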