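"""Multi-model peptide ensemble geometry.

A solution-NMR structure of a short peptide is an ensemble of conformers.
This module quantifies what the ensemble overlays show: pairwise backbone
RMSD after optimal (least-squares) superposition, the axis of each helical
segment (principal axis of its CA atoms, oriented N→C), and the inter-helix
angle distribution across models.  Axes are *directed*, so angles live in
[0°, 180°] and an obtuse helix-helix elbow (e.g. ~95°) is distinguishable
from its supplement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .chemshift import HelixSegment
from .sequences import Peptide

BACKBONE = ("N", "CA", "C")

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Model:
    """One conformer: parallel arrays of residue number / atom name / xyz (Å)."""

    res_numbers: np.ndarray  # (n,) int
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        rn = np.asarray(self.res_numbers, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "res_numbers", rn)
        object.__setattr__(self, "coords", xyz)
        if xyz.shape != (rn.size, 3) or len(self.atom_names) != rn.size:
            raise GeometryError("atom arrays must be congruent")
        present: dict[int, set[str]] = {}
        for num, name in zip(rn, self.atom_names):
            present.setdefault(int(num), set()).add(name)
        for num, names in present.items():
            missing = set(BACKBONE) - names
            if missing:
                raise GeometryError(
                    f"residue {num} lacks backbone atoms {sorted(missing)}"
                )

    def atom_key(self) -> tuple[tuple[int, str], ...]:
        return tuple(zip((int(n) for n in self.res_numbers), self.atom_names))

    def select(
        self,
        atom_names: set[str] | None = None,
        segment: HelixSegment | None = None,
    ) -> np.ndarray:
        """Coordinates of the selected atoms, in file order."""
        mask = np.ones(self.res_numbers.size, dtype=bool)
        if atom_names is not None:
            mask &= np.array([a in atom_names for a in self.atom_names])
        if segment is not None:
            mask &= (self.res_numbers >= segment.first) & (
                self.res_numbers <= segment.last
            )
        return self.coords[mask]

    def coord_of(self, number: int, atom: str) -> np.ndarray:
        for i, (num, name) in enumerate(zip(self.res_numbers, self.atom_names)):
            if num == number and name == atom:
                return self.coords[i]
        raise GeometryError(f"atom {atom} of residue {number} not found")


@dataclass(frozen=True)
class ModelEnsemble:
    models: tuple[Model, ...]
    peptide: Peptide

    def __post_init__(self) -> None:
        if not self.models:
            raise GeometryError("ensemble needs at least one model")
        key = self.models[0].atom_key()
        for i, m in enumerate(self.models[1:], start=2):
            if m.atom_key() != key:
                raise GeometryError(
                    f"model {i} atom set differs from model 1"
                )
        nums = set(int(n) for n in self.models[0].res_numbers)
        outside = nums - set(self.peptide.residue_numbers)
        if outside:
            raise GeometryError(
                f"residue numbers {sorted(outside)} not in peptide "
                f"{self.peptide.name} ({self.peptide.start_number}-"
                f"{self.peptide.end_number})"
            )

    def __len__(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class HelixAxis:
    """Directed (N→C) helix axis with fit quality."""

    direction: np.ndarray  # unit 3-vector
    centroid: np.ndarray
    segment: HelixSegment
    rms_to_axis: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise GeometryError("axis direction must be a unit vector")


# ---------------------------------------------------------------- PDB I/O


def read_model_ensemble(path: str | Path, peptide: Peptide) -> ModelEnsemble:
    """Read a (multi-)model PDB file and reconcile it against the peptide.

    Only ATOM records are honored; alternate locations other than blank/'A'
    are rejected; residue numbers must be the peptide's absolute numbers.
    """
    st = gemmi.read_pdb(str(path))
    models: list[Model] = []
    for gm in st:
        nums: list[int] = []
        names: list[str] = []
        elements: list[str] = []
        xyz: list[list[float]] = []
        for chain in gm:
            for res in chain:
                if res.het_flag == "H":
                    continue  # HETATM ignored
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        raise GeometryError(
                            f"unsupported altloc {atom.altloc!r} at "
                            f"{res.seqid.num}/{atom.name}"
                        )
                    nums.append(res.seqid.num)
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                one = _THREE_TO_ONE.get(res.name)
                if one is not None and res.seqid.num in peptide:
                    expected = peptide.residue(res.seqid.num).code
                    if one != expected:
                        raise GeometryError(
                            f"residue {res.seqid.num} is {expected} in the "
                            f"peptide but {one} in {path}"
                        )
        models.append(
            Model(np.array(nums), tuple(names), tuple(elements), np.array(xyz))
        )
    return ModelEnsemble(tuple(models), peptide)


def write_model_ensemble(ensemble: ModelEnsemble, path: str | Path) -> None:
    """Write a standard multi-model PDB (MODEL/ENDMDL delimited)."""
    st = gemmi.Structure()
    st.name = ensemble.peptide.name
    for k, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(k)
        chain = gemmi.Chain("A")
        current: gemmi.Residue | None = None
        for num, name, element, pos in zip(
            model.res_numbers, model.atom_names, model.elements, model.coords
        ):
            if current is None or current.seqid.num != int(num):
                if current is not None:
                    chain.add_residue(current)
                current = gemmi.Residue()
                current.seqid = gemmi.SeqId(int(num), " ")
                current.name = _ONE_TO_THREE[
                    ensemble.peptide.residue(int(num)).code
                ]
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*pos)
            current.add_atom(atom)
        if current is not None:
            chain.add_residue(current)
        gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.write_text(st.make_pdb_string())


# ---------------------------------------------------------------- geometry


def superpose_rmsd(
    reference: Model,
    mobile: Model,
    selection: set[str] = frozenset(BACKBONE),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal least-squares superposition of ``mobile`` onto ``reference``.

    Atoms are paired 1:1 by (residue number, atom name) within the
    selection.  Returns (RMSD in Å, proper rotation matrix, translation),
    such that mobile' = mobile @ R.T + t best fits the reference.
    """
    ref_pairs = {
        (int(n), a): c
        for n, a, c in zip(reference.res_numbers, reference.atom_names, reference.coords)
        if a in selection
    }
    mob_pairs = {
        (int(n), a): c
        for n, a, c in zip(mobile.res_numbers, mobile.atom_names, mobile.coords)
        if a in selection
    }
    keys = sorted(set(ref_pairs) & set(mob_pairs))
    if len(keys) < 3:
        raise GeometryError(
            f"superposition needs >= 3 paired atoms, got {len(keys)}"
        )
    P = np.array([ref_pairs[k] for k in keys])
    Q = np.array([mob_pairs[k] for k in keys])
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - pc, Q - qc
    rot, _ = Rotation.align_vectors(Pc, Qc)
    R = rot.as_matrix()
    # small-angle Gauss-Newton polish: the SVD rotation is only accurate to
    # ~1e-8 rad, which matters when the true RMSD is ~0
    Qr = Qc @ R.T
    for _ in range(3):
        resid = Pc - Qr
        A = (Qr**2).sum() * np.eye(3) - Qr.T @ Qr
        b = np.cross(Qr, resid).sum(axis=0)
        try:
            omega = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(omega)):
            break
        dR = Rotation.from_rotvec(omega).as_matrix()
        Qr = Qr @ dR.T
        R = dR @ R
    t = pc - qc @ R.T
    rmsd = math.sqrt(((Pc - Qr) ** 2).sum() / len(keys))
    return float(rmsd), R, t


def pairwise_rmsd_matrix(
    ensemble: ModelEnsemble, selection: set[str] = frozenset(BACKBONE)
) -> pd.DataFrame:
    """Symmetric matrix of pairwise backbone RMSDs across the ensemble."""
    n = len(ensemble)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, _, _ = superpose_rmsd(ensemble.models[i], ensemble.models[j], selection)
            mat[i, j] = mat[j, i] = r
    labels = [f"model_{k + 1}" for k in range(n)]
    return pd.DataFrame(mat, index=labels, columns=labels)


def fit_helix_axis(model: Model, segment: HelixSegment) -> HelixAxis:
    """Principal axis of the segment's CA atoms, oriented N→C.

    The dominant right singular vector of the centered CA coordinates gives
    the axis; its sign is fixed so the projection of (last CA − first CA)
    onto it is positive.  ``rms_to_axis`` is the RMS perpendicular distance
    of the CA atoms to the fitted line.
    """
    ca_atoms = sorted(
        (int(n), c)
        for n, a, c in zip(model.res_numbers, model.atom_names, model.coords)
        if a == "CA" and n in segment
    )
    ca = np.array([c for _, c in ca_atoms])
    if ca.shape[0] < 4:
        raise GeometryError(
            f"helix-axis fit needs >= 4 CA atoms in {segment}, got {ca.shape[0]}"
        )
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(ca[-1] - ca[0], direction) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    perp = centered - np.outer(centered @ direction, direction)
    rms = float(np.sqrt((perp**2).sum(axis=1).mean()))
    return HelixAxis(direction, centroid, segment, rms)


def interhelix_angle(
    ensemble: ModelEnsemble, seg_a: HelixSegment, seg_b: HelixSegment
) -> tuple[np.ndarray, float, float]:
    """Per-model angle between two directed helix axes, with mean and SD.

    angle = arccos(dir_A · dir_B) in degrees, range [0, 180]; the SD is the
    population standard deviation over models.
    """
    angles = []
    for model in ensemble.models:
        a = fit_helix_axis(model, seg_a).direction
        b = fit_helix_axis(model, seg_b).direction
        angles.append(math.degrees(math.acos(float(np.clip(a @ b, -1.0, 1.0)))))
    arr = np.array(angles)
    return arr, float(arr.mean()), float(arr.std())


def angle_table(
    ensemble: ModelEnsemble, seg_a: HelixSegment, seg_b: HelixSegment
) -> pd.DataFrame:
    angles, _, _ = interhelix_angle(ensemble, seg_a, seg_b)
    return pd.DataFrame(
        {
            "model": [f"model_{k + 1}" for k in range(len(ensemble))],
            "angle_deg": angles,
        }
    )


# ---------------------------------------------------------------- dihedrals


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(model: Model) -> dict[int, tuple[float | None, float | None]]:
    """(phi, psi) per residue; None at chain termini or across breaks."""
    nums = sorted(set(int(n) for n in model.res_numbers))
    out: dict[int, tuple[float | None, float | None]] = {}
    for num in nums:
        phi = psi = None
        try:
            n, ca, c = (model.coord_of(num, a) for a in BACKBONE)
            if num - 1 in nums:
                phi = _dihedral(model.coord_of(num - 1, "C"), n, ca, c)
            if num + 1 in nums:
                psi = _dihedral(n, ca, c, model.coord_of(num + 1, "N"))
        except GeometryError:
            pass
        out[num] = (phi, psi)
    return out


# Coarse rectangular phi/psi regions: (phi_min, phi_max, psi_min, psi_max).
_FAVORED = [
    (-100.0, -30.0, -80.0, -5.0),   # alpha
    (-180.0, -45.0, 90.0, 180.0),   # beta
    (-180.0, -45.0, -180.0, -150.0),  # beta (wrapped psi)
    (40.0, 90.0, -10.0, 80.0),      # left-handed alpha
]
_ALLOWED_MARGIN = 20.0


def _in_region(phi: float, psi: float, regions, margin: float = 0.0) -> bool:
    return any(
        (lo_f - margin) <= phi <= (hi_f + margin)
        and (lo_s - margin) <= psi <= (hi_s + margin)
        for lo_f, hi_f, lo_s, hi_s in regions
    )


def ramachandran_summary(ensemble: ModelEnsemble) -> dict[str, float]:
    """Fractions of evaluable (phi, psi) pairs in favored/allowed/outlier.

    Regions are coarse rectangles (alpha, beta, left-handed alpha) with a
    20° margin defining "allowed"; fractions sum to 1 over residues whose
    phi and psi are both computable.
    """
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    total = 0
    for model in ensemble.models:
        for phi, psi in backbone_dihedrals(model).values():
            if phi is None or psi is None:
                continue
            total += 1
            if _in_region(phi, psi, _FAVORED):
                counts["favored"] += 1
            elif _in_region(phi, psi, _FAVORED, _ALLOWED_MARGIN):
                counts["allowed"] += 1
            else:
                counts["outlier"] += 1
    if total == 0:
        raise GeometryError("no residue with both phi and psi evaluable")
    return {k: v / total for k, v in counts.items()}
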