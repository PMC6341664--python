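"""Seeded generators for alignments, titrations, gel tables and structures.

Each generator is a pure function of (design, seed): the same inputs give
byte-identical outputs, and each returns a ground-truth record sufficient
to compute every downstream expected value without re-deriving it.

What they emulate (and what they do not):

* :func:`generate_alignment` — a gapped protein-family alignment with a
  dominant histidine anchor column, a designed residue composition at the
  anchor+k position, near-duplicate rows (to exercise redundancy removal),
  anchor-less rows (to exercise anchor filtering) and rows truncated near
  the anchor (to exercise the too-short tally). Background columns are
  i.i.d. uniform over the 20 residues — no phylogeny, no conservation
  gradients away from the anchor.
* :func:`generate_titration` — a ligand-depletion titration plus a matched
  buffer-only series, with multiplicative Gaussian noise and an optional
  linear drift shared by both series (mimicking dilution/photobleaching).
* :func:`generate_structure_pair` — an idealised Cα helix trace and a copy
  in which designated residue ranges are rigidly displaced, plus isotropic
  coordinate noise and an overall rigid transform. No side chains, no
  realistic protein geometry beyond the trace.
* :func:`generate_gel_lanes` — replicate band intensities scattered around
  designed percent-of-reference levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment_io import AMINO_ACIDS, GAP, AlignedSequence, Alignment
from .binding import BindingParams, Titration, predict_response
from .structure import Atom, StructureModel

# ---------------------------------------------------------------------------
# family alignment


@dataclass
class AlignmentDesign:
    """Design of a synthetic family alignment.

    ``composition`` gives the anchor+k residue counts over the anchored
    template rows; ``n_dropout`` rows lacking the anchor histidine,
    ``n_short`` rows ending within k residues of the anchor, and
    ``n_duplicates`` near-copies per template are generated on top.
    Duplicate mutation load is capped so identity to the template stays
    >= 0.98 by construction.
    """

    n_cols: int = 120
    anchor_col: int = 40
    offset_k: int = 4
    composition: dict[str, int] = field(
        default_factory=lambda: {"G": 87, "S": 10, "A": 3}
    )
    gap_rate: float = 0.1
    n_dropout: int = 0
    n_short: int = 0
    n_duplicates: int = 0
    mutation_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_rate <= 0.3):
            raise ValueError("gap_rate must be in [0, 0.3]")
        if self.anchor_col + self.offset_k >= self.n_cols:
            raise ValueError("anchor_col + offset_k must fit inside n_cols")
        if any(v < 0 for v in self.composition.values()) or not self.composition:
            raise ValueError("composition counts must be non-negative and non-empty")
        if sum(self.composition.values()) < 1:
            raise ValueError("composition must place at least one sequence")


@dataclass
class AlignmentTruth:
    """Ground truth accompanying a generated alignment."""

    expected_counts: dict[str, int]
    expected_removed: int
    expected_short: int
    n_templates: int
    n_rows: int
    anchor_col: int
    duplicate_groups: dict[str, list[str]]


def _random_row(rng: np.random.Generator, design: AlignmentDesign) -> list[str]:
    """Background row: uniform residues, gaps outside the anchor..anchor+k window."""
    aa = np.array(list(AMINO_ACIDS))
    row = list(rng.choice(aa, size=design.n_cols))
    lo, hi = design.anchor_col, design.anchor_col + design.offset_k
    gap_cols = [c for c in range(design.n_cols) if not lo <= c <= hi]
    mask = rng.random(len(gap_cols)) < design.gap_rate
    for c, g in zip(gap_cols, mask):
        if g:
            row[c] = GAP
    return row


def generate_alignment(design: AlignmentDesign) -> tuple[Alignment, AlignmentTruth]:
    rng = np.random.default_rng(design.seed)
    k = design.offset_k
    rows: list[AlignedSequence] = []
    dup_groups: dict[str, list[str]] = {}

    # anchored templates carrying the designed anchor+k composition
    h4_residues = [r for r, n in sorted(design.composition.items()) for _ in range(n)]
    rng.shuffle(h4_residues)
    for i, res in enumerate(h4_residues):
        row = _random_row(rng, design)
        row[design.anchor_col] = "H"
        row[design.anchor_col + k] = res  # no gaps inside the window
        sid = f"tpl{i:05d}"
        rows.append(AlignedSequence(sid, "".join(row)))
        # near-duplicates: copy, then mutate a few non-gap background columns
        for j in range(design.n_duplicates):
            dup = list(row)
            nongap = [
                c for c in range(design.n_cols)
                if dup[c] != GAP
                and not design.anchor_col <= c <= design.anchor_col + k
            ]
            n_nongap = design.n_cols - "".join(row).count(GAP)
            max_mut = int(0.02 * n_nongap)  # keeps identity >= 0.98
            n_mut = min(int(rng.binomial(len(nongap), design.mutation_rate)), max_mut)
            for c in rng.choice(len(nongap), size=n_mut, replace=False):
                col = nongap[int(c)]
                choices = [a for a in AMINO_ACIDS if a != dup[col]]
                dup[col] = choices[int(rng.integers(len(choices)))]
            did = f"{sid}_dup{j}"
            rows.append(AlignedSequence(did, "".join(dup)))
            dup_groups.setdefault(sid, []).append(did)

    # rows lacking the anchor histidine (removed by the anchor filter)
    for i in range(design.n_dropout):
        row = _random_row(rng, design)
        non_h = [a for a in AMINO_ACIDS if a != "H"]
        row[design.anchor_col] = non_h[int(rng.integers(len(non_h)))]
        rows.append(AlignedSequence(f"nohis{i:05d}", "".join(row)))

    # anchored rows ending before anchor+k (tallied as too-short)
    for i in range(design.n_short):
        row = _random_row(rng, design)
        row[design.anchor_col] = "H"
        for c in range(design.anchor_col + 1, design.n_cols):
            row[c] = GAP
        rows.append(AlignedSequence(f"short{i:05d}", "".join(row)))

    truth = AlignmentTruth(
        expected_counts={r: n for r, n in design.composition.items() if n > 0},
        expected_removed=design.n_dropout,
        expected_short=design.n_short,
        n_templates=len(h4_residues),
        n_rows=len(rows),
        anchor_col=design.anchor_col,
        duplicate_groups=dup_groups,
    )
    return Alignment(rows), truth


# ---------------------------------------------------------------------------
# fluorescence titration


@dataclass
class TitrationDesign:
    """Design of a synthetic ligand-depletion titration.

    Defaults follow the assay conditions the analyses assume: ~15.8 nM
    labelled receptor (30 pmol in 1.9 mL) titrated over a log-spaced grid
    from 10 nM to 6 μM, with ~1% multiplicative intensity noise.
    """

    Kd: float = 0.94e-6  # molar
    amplitude: float = 0.4
    receptor_total: float = 15.8e-9  # molar
    l_min: float = 10e-9
    l_max: float = 6e-6
    n_points: int = 20
    baseline_intensity: float = 1.0e6
    noise_sd: float = 0.01
    buffer_drift_slope: float = 0.0  # total fractional drift over the series
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.l_min < self.l_max):
            raise ValueError("ligand grid must satisfy 0 < l_min < l_max")
        if self.n_points < 4:
            raise ValueError("need at least 4 points")


@dataclass
class TitrationTruth:
    params: BindingParams
    receptor_total: float
    model_delta: np.ndarray


def generate_titration(
    design: TitrationDesign,
) -> tuple[Titration, Titration, TitrationTruth]:
    """Ligand and buffer-only series from the quadratic isotherm.

    ligand intensity = F0·(1 + delta_model + drift)·(1 + ε),
    buffer intensity = F0·(1 + drift)·(1 + ε'), with ε, ε' independent
    N(0, noise_sd) draws and drift growing linearly with addition index.
    """
    rng = np.random.default_rng(design.seed)
    L = np.geomspace(design.l_min, design.l_max, design.n_points)
    params = BindingParams(design.Kd, design.amplitude)
    delta = predict_response(params, design.receptor_total, L)
    idx = np.arange(design.n_points)
    drift = design.buffer_drift_slope * idx / max(design.n_points - 1, 1)
    eps_l = rng.normal(0.0, design.noise_sd, design.n_points) if design.noise_sd else 0.0
    eps_b = rng.normal(0.0, design.noise_sd, design.n_points) if design.noise_sd else 0.0
    f0 = design.baseline_intensity
    ligand = Titration(
        design.receptor_total, L, f0 * (1.0 + delta + drift) * (1.0 + eps_l), f0
    )
    buffer = Titration(
        design.receptor_total, L, f0 * (1.0 + drift) * (1.0 + eps_b), f0
    )
    return ligand, buffer, TitrationTruth(params, design.receptor_total, delta)


# ---------------------------------------------------------------------------
# gel lanes


@dataclass
class GelDesign:
    """Replicate band intensities around designed percent-of-reference levels."""

    levels: dict[str, float] = field(
        default_factory=lambda: {"WT": 100.0, "G68Q": 40.0}
    )
    reference_label: str = "WT"
    n_replicates: int = 3
    reference_intensity: float = 10000.0
    noise_sd_percent: float = 5.0  # SD of the percent level across replicates
    level_sds: Optional[dict[str, float]] = None  # per-label override
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_label not in self.levels:
            raise ValueError("levels must include the reference label")

    def sd_for(self, label: str) -> float:
        if self.level_sds and label in self.level_sds:
            return self.level_sds[label]
        return self.noise_sd_percent


def generate_gel_lanes(design: GelDesign) -> "pd.DataFrame":
    """Lane table (label, replicate, intensity); reference lanes are exact."""
    import pandas as pd

    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        ref_int = design.reference_intensity * float(rng.uniform(0.8, 1.2))
        for label, level in design.levels.items():
            if label == design.reference_label:
                inten = ref_int
            else:
                pct = max(0.0, rng.normal(level, design.sd_for(label)))
                inten = ref_int * pct / 100.0
            rows.append((label, rep, inten))
    return pd.DataFrame(rows, columns=["label", "replicate", "intensity"])


# ---------------------------------------------------------------------------
# structure pair


@dataclass
class StructureDesign:
    """Design of a synthetic Cα-trace structure pair.

    The defaults emulate a 167-residue HPt protein in which the N-terminal
    helix and following turn (residues 11-21) shift by ~1.7 Å while the
    rest of the bundle stays put; 0.115 Å per-coordinate noise yields a
    ~0.2 Å Cα RMSD in undisplaced regions.
    """

    n_residues: int = 167
    chain: str = "A"
    displacements: dict[str, tuple[tuple[int, int], float]] = field(
        default_factory=lambda: {"alphaA": ((11, 21), 1.7)}
    )
    noise_sd: float = 0.115  # Å per coordinate
    apply_global_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted(rng for rng, _ in self.displacements.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("displacement regions must not overlap")
        for (s, e), d in self.displacements.values():
            if not (1 <= s <= e <= self.n_residues):
                raise ValueError(f"region ({s}, {e}) outside 1..{self.n_residues}")
            if not np.isfinite(d):
                raise ValueError("displacement magnitudes must be finite")


@dataclass
class StructureTruth:
    displacements: dict[str, tuple[tuple[int, int], float]]
    displacement_vectors: dict[str, np.ndarray]
    noise_sd: float


def _helix_trace(n: int) -> np.ndarray:
    """Compact 4-helix-bundle-like Cα trace.

    Idealised helices (2.3 Å radius, 1.5 Å rise, 100°/residue) of ~40
    residues run antiparallel on a square grid with ~11 Å spacing — the
    trace stays globular at any size, so a superposition cannot absorb a
    local displacement into a thin-rod rotation the way it could with a
    single straight helix.
    """
    per = 40
    n_seg = int(np.ceil(n / per))
    cols = int(np.ceil(np.sqrt(n_seg)))
    offsets = np.array(
        [[11.0 * (i % cols), 11.0 * (i // cols)] for i in range(n_seg)]
    )
    coords = []
    for seg in range(n_seg):
        m = min(per, n - seg * per)
        if m <= 0:
            break
        t = np.arange(m)
        theta = np.deg2rad(100.0) * t
        z = 1.5 * t if seg % 2 == 0 else 1.5 * (per - 1 - t)
        coords.append(
            np.column_stack(
                [
                    offsets[seg, 0] + 2.3 * np.cos(theta),
                    offsets[seg, 1] + 2.3 * np.sin(theta),
                    z,
                ]
            )
        )
    return np.vstack(coords)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _trace_to_model(coords: np.ndarray, chain: str) -> StructureModel:
    atoms = [
        Atom(
            serial=i + 1, name="CA", altloc="", resname="ALA", chain=chain,
            resseq=i + 1, icode="", xyz=coords[i], occupancy=1.0, element="C",
        )
        for i in range(len(coords))
    ]
    return StructureModel(atoms)


def generate_structure_pair(
    design: StructureDesign,
) -> tuple[StructureModel, StructureModel, StructureTruth]:
    """Base Cα trace and a partner with designed per-region rigid offsets.

    The partner gets isotropic N(0, noise_sd) coordinate noise and (by
    default) an overall random rigid transform, so superposition is
    exercised; the displacement direction for each region is a seeded
    random unit vector scaled to the designed magnitude.
    """
    rng = np.random.default_rng(design.seed)
    base = _helix_trace(design.n_residues)
    partner = base.copy()
    vectors: dict[str, np.ndarray] = {}
    for name, ((start, end), mag) in design.displacements.items():
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * mag
        partner[start - 1 : end] += v
        vectors[name] = v
    if design.noise_sd > 0:
        partner = partner + rng.normal(0.0, design.noise_sd, partner.shape)
    if design.apply_global_transform:
        R = _random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        partner = partner @ R.T + t
    truth = StructureTruth(dict(design.displacements), vectors, design.noise_sd)
    return (
        _trace_to_model(base, design.chain),
        _trace_to_model(partner, design.chain),
        truth,
    )
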