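"""Protein structure input, spherical windows, Kabsch superposition, TM-score."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ..exceptions import DomainError, InputError, ValidationError, WolclockError

logger = logging.getLogger(__name__)

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Residue:
    index: int
    aa: str
    coord: np.ndarray  # representative-atom position, angstrom
    confidence: float  # per-residue confidence (B-factor column), 0-100


@dataclass(frozen=True)
class StructureModel:
    """Ordered residues with representative-atom (CA) coordinates."""

    residues: tuple[Residue, ...]

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValidationError("structure needs at least 2 residues")
        indices = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError("residue indices must be strictly increasing")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues], dtype=float)

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]


def read_structure(path, chain: str = "A") -> StructureModel:
    """Read CA coordinates and B-factor confidences for one chain of a PDB file.

    Residues lacking a CA atom are skipped with a warning; for altloc
    duplicates the first altloc is kept.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        model = next(parser.get_structure("s", str(path)).get_models())
    chain_ids = [c.id for c in model.get_chains()]
    if chain not in chain_ids:
        raise InputError(f"{path}: chain {chain!r} not found (have {chain_ids})")
    residues = []
    for res in model[chain].get_residues():
        if res.id[0] != " ":
            continue  # HETATM / water
        if "CA" not in res:
            logger.warning("residue %s%d lacks a CA atom; skipped", res.resname, res.id[1])
            continue
        atom = res["CA"]
        if atom.is_disordered():
            first = sorted(atom.disordered_get_id_list())[0]
            logger.warning(
                "residue %s%d has altloc CA atoms; keeping altloc %r",
                res.resname, res.id[1], first,
            )
            atom = atom.disordered_get(first)
        residues.append(
            Residue(
                index=res.id[1],
                aa=_AA3TO1.get(res.resname, "X"),
                coord=np.asarray(atom.coord, dtype=float),
                confidence=float(atom.bfactor),
            )
        )
    if not residues:
        raise InputError(f"{path}: chain {chain!r} has no usable residues")
    return StructureModel(tuple(residues))


def spherical_windows(structure: StructureModel, radius: float = 10.0) -> dict[int, tuple[int, ...]]:
    """Residue-index membership of the closed ball around each residue.

    window(i) = residues whose representative atom lies within ``radius``
    angstrom of residue i's (i itself always included).
    """
    if radius <= 0:
        raise DomainError("radius must be > 0")
    coords = structure.coords
    idx = structure.indices
    dist = cdist(coords, coords)
    members = {}
    for row, i in enumerate(idx):
        members[i] = tuple(idx[col] for col in np.flatnonzero(dist[row] <= radius))
    return members


# ---------------------------------------------------------------------------
# superposition and TM-score

def kabsch_superpose(ref_xyz: np.ndarray, mob_xyz: np.ndarray):
    """Least-squares rigid transform (R, t) mapping mobile onto reference.

    Returns (rotation 3x3, translation 3) with transformed = mob @ R.T + t.
    """
    ref_xyz = np.asarray(ref_xyz, float)
    mob_xyz = np.asarray(mob_xyz, float)
    if ref_xyz.shape != mob_xyz.shape or ref_xyz.shape[0] < 3:
        raise InputError("need >= 3 corresponding points of equal shape")
    ref_c = ref_xyz.mean(axis=0)
    mob_c = mob_xyz.mean(axis=0)
    p = mob_xyz - mob_c
    q = ref_xyz - ref_c
    if np.linalg.matrix_rank(q, tol=1e-8) < 2 or np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise WolclockError("degenerate (collinear) point set; superposition undefined")
    h = p.T @ q
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mob_c
    return rot, trans


def tm_d0(length: int) -> float:
    """TM-score distance scale d0(L), floored at 0.5 angstrom."""
    if length > 15:
        return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def tm_score_from_transform(
    ref_xyz: np.ndarray,
    mob_xyz: np.ndarray,
    rotation: np.ndarray,
    translation: np.ndarray,
    norm_length: int,
) -> float:
    """Evaluate the TM sum for given corresponding coordinates and transform."""
    moved = mob_xyz @ rotation.T + translation
    d = np.linalg.norm(moved - ref_xyz, axis=1)
    d0 = tm_d0(norm_length)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / norm_length)


@dataclass(frozen=True)
class TmResult:
    score: float
    norm_length: int
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int


def _default_correspondence(ref: StructureModel, target: StructureModel):
    common = sorted(set(ref.indices) & set(target.indices))
    return [(i, i) for i in common]


def kabsch_tm(
    ref: StructureModel,
    target: StructureModel,
    correspondence=None,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> TmResult:
    """TM-score of target against ref under iteratively refined superposition.

    The score is normalized by the length of the *target* structure (so it
    is asymmetric when lengths differ).  Superposition starts from all
    correspondence pairs and is refined on the pairs closer than a
    d0-derived cutoff until the score stabilizes.
    """
    if correspondence is None:
        correspondence = _default_correspondence(ref, target)
    correspondence = list(correspondence)
    if len(correspondence) < 3:
        raise InputError("need at least 3 correspondence pairs")
    ref_pos = {r.index: r.coord for r in ref.residues}
    tgt_pos = {r.index: r.coord for r in target.residues}
    try:
        ref_xyz = np.array([ref_pos[i] for i, _ in correspondence])
        tgt_xyz = np.array([tgt_pos[j] for _, j in correspondence])
    except KeyError as exc:
        raise InputError(f"correspondence names unknown residue index {exc}") from None

    l_norm = len(target)
    d0 = tm_d0(l_norm)
    cutoff = max(d0, 1.0)

    include = np.ones(len(correspondence), dtype=bool)
    best = None
    prev_score = -np.inf
    for _ in range(max_iter):
        rot, trans = kabsch_superpose(ref_xyz[include], tgt_xyz[include])
        score = tm_score_from_transform(ref_xyz, tgt_xyz, rot, trans, l_norm)
        moved = tgt_xyz @ rot.T + trans
        dists = np.linalg.norm(moved - ref_xyz, axis=1)
        if best is None or score > best[0]:
            best = (score, rot, trans, dists)
        if abs(score - prev_score) < tol:
            break
        prev_score = score
        new_include = dists < cutoff
        if new_include.sum() < 3 or np.array_equal(new_include, include):
            break
        include = new_include

    score, rot, trans, dists = best
    rmsd = float(np.sqrt(np.mean(dists**2)))
    return TmResult(
        score=score,
        norm_length=l_norm,
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        n_pairs=len(correspondence),
    )
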