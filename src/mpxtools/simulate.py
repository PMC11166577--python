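"""Synthetic MPX experiment generator.

Each cell is modelled as a unit sphere. DNA pixels (zones) are spherical
caps with centres drawn uniformly on the sphere, in two sets A and B
emulating the two sequential hybridisation rounds. AOC molecules are
placed on the sphere either uniformly or following a von Mises-Fisher
(vMF) distribution around a pole (polarisation / colocalisation), then
assigned to the nearest A-zone centre and nearest B-zone centre within
the cap radius; molecules outside either zone set are dropped, which
models unhybridised AOCs. The resulting (UPI-A, UPI-B, marker, UMI)
records form the edges of the bipartite cell graph.

Defaults calibrate to a lymphocyte-scale experiment: ~1,737 A zones per
cell, ~10,900 placed molecules yielding ~9,580 retained UMIs across an
80-plex panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .panel import ALPHABET, PanelConfig, random_sequences

#: Calibration defaults (zones per cell / molecules per cell).
DEFAULT_N_PIXELS_A = 1737
DEFAULT_N_PIXELS_B = 1737
#: Angular cap radius (radians) at which ~1,700 random caps cover >=95%
#: of the sphere; ~290 nm on a 7-um cell, matching the assay's stated
#: spatial resolution scale.
DEFAULT_PIXEL_RADIUS = 0.083
DEFAULT_TOTAL_MOLECULES = 10_900

MOLECULE_COLUMNS = [
    "cell_id", "entity_id", "marker", "x", "y", "z",
    "zone_a", "zone_b", "umi", "upia", "upib", "bridge",
]
ZONE_COLUMNS = ["zone_id", "zone_set", "cell_id", "x", "y", "z", "upi"]
CELL_COLUMNS = ["cell_id", "entity_id", "cell_type", "is_doublet",
                "n_placed", "n_retained"]


@dataclass(frozen=True)
class SpatialPattern:
    """Spatial placement rule for one marker.

    kind
        ``uniform`` | ``polarized`` | ``colocalized``.
    kappa
        vMF concentration; 0 reduces to uniform.
    pole
        Unit 3-vector; drawn at random per cell when None.
    partner
        For ``colocalized``: marker whose pole is shared.
    """

    kind: str = "uniform"
    kappa: float = 0.0
    pole: tuple[float, float, float] | None = None
    partner: str | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "polarized", "colocalized"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.kind == "colocalized" and self.partner is None:
            raise ValueError("colocalized pattern requires a partner marker")


def uniform() -> SpatialPattern:
    return SpatialPattern("uniform")


def polarized(kappa: float, pole=None) -> SpatialPattern:
    return SpatialPattern("polarized", kappa=kappa,
                          pole=tuple(pole) if pole is not None else None)


def colocalized(partner: str, kappa: float) -> SpatialPattern:
    return SpatialPattern("colocalized", kappa=kappa, partner=partner)


@dataclass
class CellSpec:
    """Ground-truth description of one simulated cell."""

    cell_type: str
    abundance: dict[str, float]
    spatial_pattern: dict[str, SpatialPattern] = field(default_factory=dict)
    n_pixels_a: int = DEFAULT_N_PIXELS_A
    n_pixels_b: int = DEFAULT_N_PIXELS_B
    pixel_radius: float = DEFAULT_PIXEL_RADIUS
    #: "proximity": hybridize to a uniformly chosen zone within
    #: pixel_radius (physical default); "nearest": nearest centre only.
    zone_assignment: str = "proximity"

    def __post_init__(self):
        if self.n_pixels_a < 1 or self.n_pixels_b < 1:
            raise ValueError("n_pixels_a and n_pixels_b must be >= 1")
        if self.pixel_radius <= 0:
            raise ValueError("pixel_radius must be > 0")
        if self.zone_assignment not in ("proximity", "nearest"):
            raise ValueError(f"unknown zone_assignment {self.zone_assignment!r}")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("abundances must be >= 0")
        for m, p in self.spatial_pattern.items():
            if p.kind == "colocalized" and p.partner not in self.abundance:
                raise ValueError(
                    f"colocalization partner {p.partner!r} of {m!r} "
                    "is not in the abundance table")


@dataclass
class ErrorModel:
    """Sequencing-artifact model applied when rendering FASTQ."""

    substitution_rate: float = 0.005
    pcr_duplication: float = 3.0
    dropout_rate: float = 0.0

    def __post_init__(self):
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0,1]")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0,1]")
        if self.pcr_duplication < 1:
            raise ValueError("pcr_duplication must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated MPX experiment.

    molecules
        One row per retained AOC molecule with its true position, zone
        assignments and barcode sequences.
    zones
        One row per DNA pixel (zone), with set identifier A|B.
    cells
        Per emitted entity: spec label and doublet bookkeeping.
    """

    molecules: pd.DataFrame
    zones: pd.DataFrame
    cells: pd.DataFrame

    def edge_list(self) -> pd.DataFrame:
        """Unique-molecule edge list (upia, upib, marker, umi, reads=1)."""
        df = self.molecules[["upia", "upib", "marker", "umi"]].copy()
        df["reads"] = 1
        return df.reset_index(drop=True)

    @property
    def poles(self) -> dict:
        return getattr(self, "_poles", {})

    def save(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.molecules.to_csv(d / "truth_molecules.tsv", sep="\t", index=False)
        self.zones.to_csv(d / "truth_zones.tsv", sep="\t", index=False)
        self.cells.to_csv(d / "truth_cells.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "SimTruth":
        import pathlib

        d = pathlib.Path(directory)
        return cls(
            molecules=pd.read_csv(d / "truth_molecules.tsv", sep="\t"),
            zones=pd.read_csv(d / "truth_zones.tsv", sep="\t"),
            cells=pd.read_csv(d / "truth_cells.tsv", sep="\t"),
        )


def default_cell_spec(
    panel: PanelConfig,
    cell_type: str = "cell",
    total_molecules: int = DEFAULT_TOTAL_MOLECULES,
    spatial_pattern: dict[str, SpatialPattern] | None = None,
    **kwargs,
) -> CellSpec:
    """Even-abundance CellSpec over a panel at calibration defaults."""
    per = total_molecules / len(panel.markers)
    return CellSpec(
        cell_type=cell_type,
        abundance={m: per for m in panel.marker_names},
        spatial_pattern=spatial_pattern or {},
        **kwargs,
    )


# ---------------------------------------------------------------------------
# geometry


def sample_uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_vmf(rng: np.random.Generator, n: int, pole: np.ndarray,
               kappa: float) -> np.ndarray:
    """von Mises-Fisher sample on S^2 around ``pole``."""
    if kappa == 0:
        return sample_uniform_sphere(rng, n)
    u = rng.random(n)
    # inverse-CDF of the cosine w of the colatitude; exp(-2k) underflows
    # harmlessly to 0 for large kappa
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.random(n) * 2 * np.pi
    r = np.sqrt(np.maximum(0.0, 1.0 - w * w))
    xyz = np.column_stack([r * np.cos(phi), r * np.sin(phi), w])
    return xyz @ _rotation_to(pole).T


def _rotation_to(pole: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``pole``."""
    pole = np.asarray(pole, dtype=float)
    pole = pole / np.linalg.norm(pole)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, pole)
    c = float(z @ pole)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _encode_base4(value: int, width: int) -> str:
    out = []
    for _ in range(width):
        out.append(ALPHABET[value & 3])
        value >>= 2
    return "".join(reversed(out))


def _make_upis(rng: np.random.Generator, start_id: int, n: int,
               upi_length: int) -> list[str]:
    """Globally unique UPIs: random prefix + base-4-encoded zone index."""
    enc = 12 if upi_length > 13 else max(1, upi_length - 1)
    prefix = random_sequences(rng, n, upi_length - enc)
    return [p + _encode_base4(start_id + i, enc) for i, p in enumerate(prefix)]


# ---------------------------------------------------------------------------
# single-cell simulation


def _resolve_poles(spec: CellSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    poles: dict[str, np.ndarray] = {}
    for marker, pat in spec.spatial_pattern.items():
        if pat.kind == "polarized":
            poles[marker] = (np.asarray(pat.pole, float)
                             if pat.pole is not None
                             else sample_uniform_sphere(rng, 1)[0])
            poles[marker] = poles[marker] / np.linalg.norm(poles[marker])
    for marker, pat in spec.spatial_pattern.items():
        if pat.kind == "colocalized":
            partner = pat.partner
            if partner not in poles:
                ppat = spec.spatial_pattern.get(partner)
                poles[partner] = (np.asarray(ppat.pole, float)
                                  if ppat is not None and ppat.pole is not None
                                  else sample_uniform_sphere(rng, 1)[0])
                poles[partner] /= np.linalg.norm(poles[partner])
            poles[marker] = poles[partner]
    return poles


def simulate_cell(
    spec: CellSpec,
    seed: int | np.random.SeedSequence,
    umi_length: int = 10,
    upi_length: int = 25,
    cell_id: int = 0,
    entity_id: int | None = None,
    zone_id_offset: int = 0,
) -> SimTruth:
    """Simulate one cell and return its ground truth.

    Molecules are placed per the spec's spatial patterns, assigned to
    the nearest A- and B-zone centre within ``pixel_radius`` (chord
    metric; equidistant centres resolve to the lowest zone id), and
    dropped when either assignment fails.
    """
    rng = np.random.default_rng(seed)
    entity_id = cell_id if entity_id is None else entity_id

    n_total = int(round(sum(spec.abundance.values())))
    if n_total == 0:
        warnings.warn(f"cell {cell_id}: zero total abundance", stacklevel=2)

    # zones
    nA, nB = spec.n_pixels_a, spec.n_pixels_b
    centers = sample_uniform_sphere(rng, nA + nB)
    zone_ids = np.arange(nA + nB) + zone_id_offset
    upis = _make_upis(rng, zone_id_offset, nA + nB, upi_length)
    zones = pd.DataFrame({
        "zone_id": zone_ids,
        "zone_set": ["A"] * nA + ["B"] * nB,
        "cell_id": cell_id,
        "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
        "upi": upis,
    })

    # molecule positions
    poles = _resolve_poles(spec, rng)
    marker_col, pos_list = [], []
    for marker in sorted(spec.abundance):
        n = int(round(spec.abundance[marker]))
        if n == 0:
            continue
        pat = spec.spatial_pattern.get(marker, SpatialPattern())
        if pat.kind == "uniform" or pat.kappa == 0:
            pos = sample_uniform_sphere(rng, n)
        else:
            pos = sample_vmf(rng, n, poles[marker], pat.kappa)
        marker_col.extend([marker] * n)
        pos_list.append(pos)
    if not pos_list:
        molecules = pd.DataFrame(columns=MOLECULE_COLUMNS)
        cells = pd.DataFrame([{
            "cell_id": cell_id, "entity_id": entity_id,
            "cell_type": spec.cell_type, "is_doublet": False,
            "n_placed": 0, "n_retained": 0,
        }])
        return SimTruth(molecules, zones, cells)
    positions = np.vstack(pos_list)
    markers = np.array(marker_col)

    # zone assignment within the cap radius (chord distance); molecules
    # outside either zone set model unhybridised AOCs and are dropped
    max_chord = 2.0 * np.sin(spec.pixel_radius / 2.0)
    if spec.zone_assignment == "nearest":
        dA, iA = cKDTree(centers[:nA]).query(positions, k=1)
        dB, iB = cKDTree(centers[nA:]).query(positions, k=1)
        keep = (dA <= max_chord) & (dB <= max_chord)
    else:
        in_a = cKDTree(centers[:nA]).query_ball_point(positions, r=max_chord)
        in_b = cKDTree(centers[nA:]).query_ball_point(positions, r=max_chord)
        n_mol = len(positions)
        iA = np.zeros(n_mol, dtype=np.int64)
        iB = np.zeros(n_mol, dtype=np.int64)
        keep = np.zeros(n_mol, dtype=bool)
        picks = rng.random((n_mol, 2))
        for k in range(n_mol):
            a, b = in_a[k], in_b[k]
            if a and b:
                keep[k] = True
                iA[k] = a[int(picks[k, 0] * len(a))]
                iB[k] = b[int(picks[k, 1] * len(b))]

    positions, markers = positions[keep], markers[keep]
    iA, iB = iA[keep], iB[keep]
    n_kept = int(keep.sum())

    umis = random_sequences(rng, n_kept, umi_length)
    upi_arr = np.array(upis)
    molecules = pd.DataFrame({
        "cell_id": cell_id,
        "entity_id": entity_id,
        "marker": markers,
        "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2],
        "zone_a": zone_ids[iA],
        "zone_b": zone_ids[nA + iB],
        "umi": umis,
        "upia": upi_arr[iA],
        "upib": upi_arr[nA + iB],
        "bridge": False,
    })
    cells = pd.DataFrame([{
        "cell_id": cell_id, "entity_id": entity_id,
        "cell_type": spec.cell_type, "is_doublet": False,
        "n_placed": n_total, "n_retained": n_kept,
    }])
    truth = SimTruth(molecules, zones, cells)
    truth._poles = {m: p.copy() for m, p in poles.items()}
    return truth


# ---------------------------------------------------------------------------
# sample-level simulation


def simulate_sample(
    specs: list[tuple[CellSpec, int]],
    doublet_fraction: float = 0.0,
    seed: int = 0,
    umi_length: int = 10,
    upi_length: int = 25,
    doublet_bridge_edges: int = 5,
) -> tuple[SimTruth, pd.DataFrame]:
    """Simulate a multi-cell sample; returns (truth, edge list).

    Doublets: ``round(doublet_fraction * n_cells)`` merged entities
    (capped at n_cells // 2), each fusing two cells. The fused cells
    keep their own zone sets; ``doublet_bridge_edges`` contact-interface
    molecules are rewired to take UPI-B from the partner cell, joining
    the two graphs by a handful of edges.

    UPI sequences are globally unique across cells, and each cell draws
    from an independent RNG stream keyed by its index, so results do
    not depend on simulation order.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if not 0 <= doublet_fraction <= 1:
        raise ValueError("doublet_fraction must be in [0,1]")
    cell_specs: list[CellSpec] = []
    for spec, count in specs:
        if count < 0:
            raise ValueError("cell counts must be >= 0")
        cell_specs.extend([spec] * count)
    n_cells = len(cell_specs)
    if n_cells == 0:
        raise ValueError("no cells requested")

    top = np.random.SeedSequence(seed)
    master = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**20,)))

    offsets = np.cumsum([0] + [s.n_pixels_a + s.n_pixels_b for s in cell_specs])
    truths = [
        simulate_cell(
            cell_specs[i],
            np.random.SeedSequence(seed, spawn_key=(i,)),
            umi_length=umi_length, upi_length=upi_length,
            cell_id=i, zone_id_offset=int(offsets[i]),
        )
        for i in range(n_cells)
    ]

    n_doublets = min(int(round(doublet_fraction * n_cells)), n_cells // 2)
    paired = master.permutation(n_cells)[: 2 * n_doublets]
    entity_of = {i: i for i in range(n_cells)}
    for k in range(n_doublets):
        a, b = int(paired[2 * k]), int(paired[2 * k + 1])
        entity_of[b] = entity_of[a] = min(a, b)
        # bridge molecules: rewire a few of cell a's molecules to take
        # their B zone from cell b (the contact interface)
        mol_a = truths[a].molecules
        zb = truths[b].zones
        b_zones = zb[zb.zone_set == "B"]
        if len(mol_a) and len(b_zones):
            n_bridge = min(doublet_bridge_edges, len(mol_a))
            rows = master.choice(len(mol_a), size=n_bridge, replace=False)
            picks = master.integers(0, len(b_zones), size=n_bridge)
            mol_a.iloc[rows, mol_a.columns.get_loc("zone_b")] = \
                b_zones.zone_id.to_numpy()[picks]
            mol_a.iloc[rows, mol_a.columns.get_loc("upib")] = \
                b_zones.upi.to_numpy()[picks]
            mol_a.iloc[rows, mol_a.columns.get_loc("bridge")] = True
        for t, is_first in ((truths[a], True), (truths[b], False)):
            t.cells["is_doublet"] = True

    for i, t in enumerate(truths):
        t.molecules["entity_id"] = entity_of[i]
        t.cells["entity_id"] = entity_of[i]

    truth = SimTruth(
        molecules=pd.concat([t.molecules for t in truths], ignore_index=True),
        zones=pd.concat([t.zones for t in truths], ignore_index=True),
        cells=pd.concat([t.cells for t in truths], ignore_index=True),
    )
    truth._poles = {
        (i, m): p for i, t in enumerate(truths) for m, p in t.poles.items()
    }
    return truth, truth.edge_list()


# ---------------------------------------------------------------------------
# FASTQ rendering

_BASE_LUT = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
_IDX_LUT = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _IDX_LUT[ord(_c)] = _i


def render_fastq(
    truth: SimTruth,
    panel: PanelConfig,
    errors: ErrorModel | None = None,
    seed: int = 0,
    path="reads.fastq",
) -> int:
    """Write amplicon reads for every truth molecule; returns read count.

    Each molecule yields a geometric number of PCR duplicates with mean
    ``pcr_duplication`` (or none, with probability ``dropout_rate``);
    substitution errors are applied independently per read. Quality
    strings are a constant placeholder.
    """
    if len(truth.molecules) == 0:
        raise ValueError("truth contains no molecules")
    errors = errors or ErrorModel(substitution_rate=0.0, pcr_duplication=1.0)
    rng = np.random.default_rng(seed)
    mol = truth.molecules
    barcode_of = {m.name: m.barcode for m in panel.markers}

    parts = []
    for fld in panel.layout:
        if fld == "umi":
            col = mol.umi.to_numpy()
        elif fld == "barcode":
            col = mol.marker.map(barcode_of).to_numpy()
        elif fld == "bs1":
            col = np.full(len(mol), panel.bs1)
        elif fld == "bs2":
            col = np.full(len(mol), panel.bs2)
        elif fld == "upia":
            col = mol.upia.to_numpy()
        else:
            col = mol.upib.to_numpy()
        parts.append(col)
    templates = np.char.add(parts[0].astype(str), "")
    for p in parts[1:]:
        templates = np.char.add(templates, p.astype(str))
    L = panel.read_length

    # per-molecule duplicate counts
    n_mol = len(mol)
    keep = rng.random(n_mol) >= errors.dropout_rate
    dup = np.zeros(n_mol, dtype=int)
    p_geo = 1.0 / errors.pcr_duplication
    dup[keep] = rng.geometric(p_geo, size=int(keep.sum()))

    mat = (np.frombuffer("".join(np.repeat(templates, dup)).encode(),
                         dtype=np.uint8).reshape(-1, L))
    idx = _IDX_LUT[mat]
    if errors.substitution_rate > 0:
        mask = rng.random(idx.shape) < errors.substitution_rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        idx[mask] = (idx[mask] + shift) % 4
    seqs = _BASE_LUT[idx]

    qual = "I" * L
    with open(path, "w") as fh:
        for i in range(seqs.shape[0]):
            fh.write(f"@mpx:{i}\n{bytes(seqs[i]).decode()}\n+\n{qual}\n")
    return int(seqs.shape[0])
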