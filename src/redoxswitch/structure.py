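"""Structural metrics for NMR ensembles and crosslink-validated models.

Provides the quantitative comparisons used for the reduced (zinc-bound) and
oxidized anti-sigma-factor ensembles: inter-atom distances (e.g. the
His37 NE2 – Cys11 SG separation that reports destruction of the metal
site), per-residue and ensemble-averaged solvent-accessible surface area
(Shrake–Rupley point sampling), and satisfaction checks of lysine-specific
crosslink restraints (BS2G/BS3) against candidate complex models.

Coordinates are parsed with gemmi (PDB or mmCIF); a download helper is
provided for deposited entries when a network is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import gemmi

__all__ = [
    "Atom", "Model", "StructureEnsemble", "Crosslink", "CrosslinkReport",
    "VDW_RADII", "LINKER_CUTOFFS",
    "load_ensemble", "fetch_pdb", "atom_distance", "compute_sasa",
    "ensemble_sasa", "check_crosslinks", "sphere_points",
]

# Bondi-type van der Waals radii (Angstrom) for SASA
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "ZN": 1.39, "FE": 1.40, "MG": 1.73,
}

# Calpha-Calpha cutoffs (Angstrom) for lysine-reactive crosslinkers:
# spacer 7.7 A (BS2G) and 11.4 A (BS3) plus side-chain reach and dynamics
LINKER_CUTOFFS = {"BS2G": 26.0, "BS3": 30.0}


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    name: str
    element: str
    pos: tuple[float, float, float]
    het: bool = False


class Model:
    """One model of an ensemble with (chain, residue, atom) addressing."""

    def __init__(self, atoms: list[Atom]):
        self.atoms = atoms
        self._index: dict[tuple[str, int, str], Atom] = {}
        for a in atoms:
            key = (a.chain, a.res_seq, a.name)
            if key not in self._index:  # keep first conformer
                self._index[key] = a

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, chain: str, res_seq: int, name: str) -> Atom:
        try:
            return self._index[(chain, res_seq, name)]
        except KeyError:
            raise KeyError(
                f"atom {name} of residue {res_seq} chain {chain!r} not found"
            ) from None

    def has_atom(self, chain: str, res_seq: int, name: str) -> bool:
        return (chain, res_seq, name) in self._index

    def coords(self, heavy_only: bool = True, include_het: bool = False) -> np.ndarray:
        sel = self.select(heavy_only=heavy_only, include_het=include_het)
        return np.array([a.pos for a in sel], dtype=float)

    def select(self, heavy_only: bool = True, include_het: bool = False,
               residue_range: tuple[int, int] | None = None,
               chain: str | None = None) -> list[Atom]:
        out = []
        for a in self.atoms:
            if heavy_only and a.element == "H":
                continue
            if not include_het and a.het:
                continue
            if chain is not None and a.chain != chain:
                continue
            if residue_range is not None and not (
                    residue_range[0] <= a.res_seq <= residue_range[1]):
                continue
            out.append(a)
        return out


@dataclass
class StructureEnsemble:
    models: list[Model]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError(f"no models parsed from {self.source!r}")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def lowest_energy(self) -> Model:
        """First model of the ensemble (deposition convention)."""
        return self.models[0]


def load_ensemble(path: str | Path) -> StructureEnsemble:
    """Read a PDB or mmCIF file into an ensemble.

    All MODEL records are kept; alternate locations resolve to the first
    conformer; heteroatoms are retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = []
    for gm in st:
        atoms: list[Atom] = []
        for chain in gm:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    if at.has_altloc() and at.altloc != "A":
                        continue
                    atoms.append(Atom(
                        chain=chain.name, res_seq=res.seqid.num,
                        res_name=res.name, name=at.name,
                        element=at.element.name.upper(),
                        pos=(at.pos.x, at.pos.y, at.pos.z), het=het))
        if atoms:
            models.append(Model(atoms))
    ens = StructureEnsemble(models=models, source=str(path))
    for m in ens.models:
        c = m.coords(heavy_only=False, include_het=True)
        if c.size and not np.all(np.isfinite(c)):
            raise ValueError(f"non-finite coordinates in {path}")
    return ens


def fetch_pdb(pdb_id: str, dest: str | Path = ".") -> Path:
    """Download a deposited PDB entry (requires network access)."""
    import urllib.request

    pdb_id = pdb_id.lower()
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    out = dest / f"{pdb_id}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    urllib.request.urlretrieve(url, out)
    return out


def atom_distance(model: Model, sel_a: tuple[str, int, str],
                  sel_b: tuple[str, int, str]) -> float:
    """Euclidean distance (Angstrom) between two addressed atoms."""
    a = model.atom(*sel_a)
    b = model.atom(*sel_b)
    return float(math.dist(a.pos, b.pos))


def sphere_points(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere points (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                   probe: float, n_points: int) -> np.ndarray:
    """Per-atom solvent-accessible area (Angstrom^2) by point sampling."""
    n = coords.shape[0]
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        surface = coords[i] + ri * pts
        neighbours = [j for j in tree.query_ball_point(coords[i], ri + expanded.max())
                      if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        areas[i] = 4.0 * math.pi * ri * ri * exposed_frac
    return areas


def compute_sasa(model: Model, residue_range: tuple[int, int] | None = None,
                 probe_radius: float = 1.4, n_points: int = 960,
                 include_het: bool = False,
                 chain: str | None = None) -> tuple[dict, float]:
    """Shrake–Rupley SASA of a model.

    Occlusion is computed against every heavy atom of the model; the
    returned per-residue dict and total cover ``residue_range`` (inclusive)
    if given.  Radii are looked up per element; unknown elements raise.
    """
    atoms = model.select(heavy_only=True, include_het=include_het, chain=chain)
    if not atoms:
        raise ValueError("model has no atoms after selection")
    coords = np.array([a.pos for a in atoms])
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        try:
            radii[i] = VDW_RADII[a.element]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {a.element!r}")
    areas = _shrake_rupley(coords, radii, probe_radius, n_points)

    per_residue: dict[tuple[str, int], float] = {}
    total = 0.0
    for a, area in zip(atoms, areas):
        if residue_range is not None and not (
                residue_range[0] <= a.res_seq <= residue_range[1]):
            continue
        key = (a.chain, a.res_seq)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
        total += float(area)
    return per_residue, float(total)


def ensemble_sasa(ensemble: StructureEnsemble,
                  residue_range: tuple[int, int] | None = None,
                  probe_radius: float = 1.4, n_points: int = 960,
                  n_models: int | None = None) -> tuple[float, float]:
    """Mean and SD of total SASA over the first ``n_models`` of an ensemble."""
    models = ensemble.models[:n_models] if n_models else ensemble.models
    totals = [compute_sasa(m, residue_range, probe_radius, n_points)[1]
              for m in models]
    return float(np.mean(totals)), float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0


@dataclass(frozen=True)
class Crosslink:
    """A lysine-specific crosslink between two residues."""

    res_a: tuple[str, int]
    res_b: tuple[str, int]
    linker: str = "BS3"
    max_ca_ca: float | None = None

    def cutoff(self) -> float:
        if self.max_ca_ca is not None:
            if self.max_ca_ca <= 0:
                raise ValueError("max_ca_ca must be > 0")
            return self.max_ca_ca
        try:
            return LINKER_CUTOFFS[self.linker]
        except KeyError:
            raise ValueError(f"unknown linker {self.linker!r}") from None


@dataclass
class CrosslinkReport:
    links: list[Crosslink]
    ca_distances: list[float | None]
    nz_distances: list[float | None]
    satisfied: list[bool | None]
    details: list[str] = field(default_factory=list)

    @property
    def fraction_satisfied(self) -> float:
        evaluable = [s for s in self.satisfied if s is not None]
        if not evaluable:
            return float("nan")
        return sum(evaluable) / len(evaluable)

    @property
    def n_unevaluable(self) -> int:
        return sum(1 for s in self.satisfied if s is None)


def check_crosslinks(model: Model, links: list[Crosslink]) -> CrosslinkReport:
    """Evaluate crosslink restraints on a model.

    Reports the Calpha–Calpha distance per link (and lysine NZ–NZ where
    both side chains are present) and whether it satisfies the linker
    cutoff.  Links whose residues or Calpha atoms are missing are marked
    unevaluable rather than dropped.
    """
    ca_d, nz_d, ok, notes = [], [], [], []
    for link in links:
        cutoff = link.cutoff()
        (ch_a, ra), (ch_b, rb) = link.res_a, link.res_b
        if not (model.has_atom(ch_a, ra, "CA") and model.has_atom(ch_b, rb, "CA")):
            ca_d.append(None)
            nz_d.append(None)
            ok.append(None)
            notes.append(f"{ch_a}{ra}-{ch_b}{rb}: unevaluable (missing CA)")
            continue
        d = atom_distance(model, (ch_a, ra, "CA"), (ch_b, rb, "CA"))
        ca_d.append(d)
        if model.has_atom(ch_a, ra, "NZ") and model.has_atom(ch_b, rb, "NZ"):
            nz_d.append(atom_distance(model, (ch_a, ra, "NZ"), (ch_b, rb, "NZ")))
        else:
            nz_d.append(None)
        ok.append(d <= cutoff)
        notes.append(f"{ch_a}{ra}-{ch_b}{rb}: CA-CA {d:.1f} A vs cutoff {cutoff:.1f} A")
    return CrosslinkReport(links=list(links), ca_distances=ca_d,
                           nz_distances=nz_d, satisfied=ok, details=notes)
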