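"""Structural comparison: PDB I/O, Kabsch superposition, regional RMSD and
van der Waals clash scanning.

Workflow mirrors how a mutant crystal structure is compared with wild type:
read both models, pair atoms by (chain, residue number, insertion code,
atom name) over a selection (Cα by default), superpose with the Kabsch
algorithm (proper rotations only), and report RMSD globally and per helix
region — either in the global frame (superpose on everything, measure the
region without refitting; shows how far a region moved relative to the
bundle) or with a local fit (superpose on the region itself; shows internal
distortion). A clash scan between a superposed mutant side chain and a
partner receiver domain flags atom pairs whose van der Waals spheres
overlap by more than a threshold (0.4 Å, the usual severe-clash cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np

#: Bondi-style van der Waals radii in Å (fallback 1.70 for other elements)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70
WATER_RESNAMES = {"HOH", "WAT", "DOD"}

SELECTIONS = ("CA", "backbone", "heavy", "all")
_BACKBONE = {"N", "CA", "C", "O"}


@dataclass
class Atom:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    element: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        if not self.element:
            self.element = _infer_element(self.name)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def key(self) -> tuple:
        return (self.chain, self.resseq, self.icode, self.name)

    @property
    def ident(self) -> str:
        return f"{self.chain}/{self.resname}{self.resseq}{self.icode.strip()}/{self.name}"


def _infer_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    # two-letter elements in proteins are rare; first alpha char suffices
    return stripped[0].upper()


@dataclass
class StructureModel:
    """A flat list of atoms with (chain, resseq, icode, name) lookup."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {}
        for a in self.atoms:
            if a.key in self._index:
                raise ValueError(f"duplicate atom key after altloc resolution: {a.key}")
            self._index[a.key] = a

    def get(self, chain: str, resseq: int, name: str, icode: str = "") -> Optional[Atom]:
        return self._index.get((chain, resseq, icode, name))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)


@dataclass
class RegionSpec:
    """A chain plus inclusive residue ranges and an atom selection."""

    chain: str
    residue_ranges: list[tuple[int, int]]
    selection: str = "CA"

    def __post_init__(self) -> None:
        if self.selection not in SELECTIONS:
            raise ValueError(f"selection must be one of {SELECTIONS}")
        for start, end in self.residue_ranges:
            if start > end:
                raise ValueError(f"invalid residue range ({start}, {end})")

    def contains(self, atom: Atom) -> bool:
        if atom.chain != self.chain:
            return False
        return any(s <= atom.resseq <= e for s, e in self.residue_ranges)


def _atom_in_selection(atom: Atom, selection: str) -> bool:
    if selection == "all":
        return True
    if selection == "heavy":
        return atom.element != "H"
    if selection == "backbone":
        return atom.name in _BACKBONE
    return atom.name == "CA" and atom.element == "C"


def select_atoms(
    model: StructureModel,
    selection: str = "CA",
    region: Optional[RegionSpec] = None,
    include_hetero: bool = False,
) -> list[Atom]:
    out = []
    for a in model.atoms:
        if a.is_water or (a.is_hetero and not include_hetero):
            continue
        if not _atom_in_selection(a, selection):
            continue
        if region is not None and not region.contains(a):
            continue
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)


def read_pdb(path) -> StructureModel:
    """Read the first MODEL of a PDB file.

    Alternate locations resolve to the highest-occupancy conformer (ties
    prefer blank then 'A'). Waters and hetero groups are retained but
    flagged, so comparisons can exclude them.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"cannot parse PDB file {path}: {e}") from e
    if len(st) == 0:
        raise ValueError(f"no models in PDB file {path}")
    model = st[0]

    # group altlocs per (chain, resseq, icode, name) and keep the best one
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H" and res.name not in WATER_RESNAMES
            water = res.name in WATER_RESNAMES
            for at in res:
                atom = Atom(
                    serial=at.serial,
                    name=at.name,
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    resname=res.name,
                    chain=chain.name,
                    resseq=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    element=at.element.name,
                    is_hetero=het or water,
                )
                k = atom.key
                if k not in best:
                    best[k] = atom
                    order.append(k)
                else:
                    cur = best[k]
                    if atom.occupancy > cur.occupancy or (
                        atom.occupancy == cur.occupancy
                        and atom.altloc in ("", "A")
                        and cur.altloc not in ("", "A")
                    ):
                        best[k] = atom
    return StructureModel([best[k] for k in order])


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    # gemmi's add_residue/add_chain copy their argument, so group first
    # and assemble bottom-up
    grouped: dict[str, dict[tuple, list[Atom]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain, {}).setdefault(
            (a.resseq, a.icode, a.resname, a.is_hetero), []
        ).append(a)

    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    for chain_name, residues in grouped.items():
        chain = gemmi.Chain(chain_name)
        for (resseq, icode, resname, het), atoms in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resseq, icode or " ")
            res.het_flag = "H" if het else "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.pos = gemmi.Position(*a.xyz)
                at.occ = a.occupancy
                at.element = gemmi.Element(a.element or _infer_element(a.name))
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# atom matching and superposition


def match_atoms(
    a: StructureModel,
    b: StructureModel,
    selection: str = "CA",
    chain_map: Optional[dict[str, str]] = None,
    region: Optional[RegionSpec] = None,
):
    """Pair atoms of two models by (mapped chain, resseq, icode, name).

    ``chain_map`` renames chains of ``a`` before matching (e.g. {'A': 'B'}).
    ``region`` restricts the pairing (evaluated on the mapped keys).
    Returns (P, Q, keys): two (n, 3) arrays and the shared keys in
    deterministic (chain, residue, name) order.
    """
    cmap = chain_map or {}
    sel_a = {}
    for at in select_atoms(a, selection):
        key = (cmap.get(at.chain, at.chain), at.resseq, at.icode, at.name)
        sel_a[key] = at
    sel_b = {at.key: at for at in select_atoms(b, selection)}
    keys = sorted(set(sel_a) & set(sel_b))
    if region is not None:
        keys = [
            k for k in keys
            if k[0] == region.chain
            and any(s <= k[1] <= e for s, e in region.residue_ranges)
        ]
    if not keys:
        raise ValueError("no common atoms between the two selections")
    P = np.array([sel_a[k].xyz for k in keys])
    Q = np.array([sel_b[k].xyz for k in keys])
    return P, Q, keys


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares optimal proper rigid transform of P onto Q.

    Classic SVD solution; a reflection in the SVD is corrected by flipping
    the smallest singular direction, so det(rotation) = +1 always.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be (n, 3) arrays of equal shape")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs to superpose")
    pbar, qbar = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - pbar, Q - qbar
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:  # rank < 2: points (nearly) collinear
        raise ValueError("degenerate (collinear) configuration; rotation is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qbar - R @ pbar
    resid = Pc @ R.T - Qc
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return Superposition(R, t, rmsd, n)


def region_rmsd(
    a: StructureModel,
    b: StructureModel,
    region: RegionSpec,
    mode: str = "global_frame",
    chain_map: Optional[dict[str, str]] = None,
) -> float:
    """RMSD of a region between two models.

    ``global_frame``: superpose on all matched atoms of the region's
    selection, then measure the region without refitting — the region's
    displacement relative to the rest of the structure. ``local_fit``:
    superpose on the region atoms alone — the region's internal distortion.
    """
    if mode not in ("global_frame", "local_fit"):
        raise ValueError("mode must be 'global_frame' or 'local_fit'")
    Pr, Qr, _ = match_atoms(a, b, region.selection, chain_map, region=region)
    if mode == "local_fit":
        return kabsch_superpose(Pr, Qr).rmsd
    P, Q, _ = match_atoms(a, b, region.selection, chain_map)
    sup = kabsch_superpose(P, Q)
    resid = sup.apply(Pr) - Qr
    return float(np.sqrt((resid**2).sum() / len(Pr)))


# ---------------------------------------------------------------------------
# van der Waals clash scan


@dataclass
class ClashPair:
    atom_a: str
    atom_b: str
    distance: float
    overlap: float


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def clash_scan(
    mobile: StructureModel,
    mobile_sel: RegionSpec,
    target: StructureModel,
    target_sel: RegionSpec,
    overlap_threshold: float = 0.4,
    include_hydrogens: bool = False,
) -> list[ClashPair]:
    """All atom pairs across two selections whose vdW spheres overlap.

    Both models must already sit in a common frame (superpose first).
    Overlap = r_a + r_b − d; pairs with overlap > threshold are returned,
    sorted by overlap descending. Hydrogens are excluded by default.
    """
    sel = mobile_sel.selection
    atoms_a = select_atoms(mobile, sel, mobile_sel, include_hetero=True)
    atoms_b = select_atoms(target, target_sel.selection, target_sel, include_hetero=True)
    if not include_hydrogens:
        atoms_a = [a for a in atoms_a if a.element != "H"]
        atoms_b = [a for a in atoms_b if a.element != "H"]
    if not atoms_a or not atoms_b:
        raise ValueError("empty selection in clash scan")
    xa = np.array([a.xyz for a in atoms_a])
    xb = np.array([b.xyz for b in atoms_b])
    ra = np.array([vdw_radius(a.element) for a in atoms_a])
    rb = np.array([vdw_radius(b.element) for b in atoms_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    overlap = ra[:, None] + rb[None, :] - d
    hits = np.argwhere(overlap > overlap_threshold)
    pairs = [
        ClashPair(
            atoms_a[i].ident, atoms_b[j].ident,
            float(d[i, j]), float(overlap[i, j]),
        )
        for i, j in hits
    ]
    pairs.sort(key=lambda p: -p.overlap)
    return pairs
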