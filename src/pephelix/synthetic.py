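"""Synthetic data with known ground truth.

Emulates the four kinds of raw data the analysis consumes, each with the
true parameter recorded so estimators can be tested for recovery:

* two-state helix-coil shift tables — δ_obs = δ_RC + f·Δδ_100% + noise,
  with Gaussian measurement noise of 0.01 ppm (¹H) and 0.1 ppm (¹³C);
* "mixture" tables — a free table plus localized perturbations at chosen
  residues (the ground truth for CSP interface mapping);
* two-basis CD spectra — f·B_helix + (1−f)·B_coil, with the bases anchored
  at 222 nm to the −36000 / +3000 deg cm² dmol⁻¹ limits of the CD helix
  estimator so the round-trip is exact at zero noise;
* hinged two-helix coordinate ensembles — ideal α-helices (φ=−57°, ψ=−47°)
  with the second helix rotated about the hinge to a prescribed inter-axis
  angle, plus optional coordinate jitter.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cd import THETA222_COIL, THETA222_HELIX, CDSpectrum, MOLAR_ELLIPTICITY
from .chemshift import FULL_HELIX_LIMIT, HelixSegment, ShiftTable
from .geometry import Model, ModelEnsemble, fit_helix_axis
from .random_coil import RandomCoilTable
from .sequences import Peptide


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class HelixProfile:
    """Per-residue true helix probability f_i ∈ [0, 1]."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise SyntheticError("helix fractions must lie in [0, 1]")

    @classmethod
    def flat(cls, f: float, n: int) -> "HelixProfile":
        return cls((float(f),) * n)

    @classmethod
    def from_segments(
        cls, peptide: Peptide, segments: Mapping[HelixSegment, float], baseline: float = 0.0
    ) -> "HelixProfile":
        """Piecewise profile: ``baseline`` outside the given segments."""
        fr = [baseline] * len(peptide)
        for seg, f in segments.items():
            for num in range(seg.first, seg.last + 1):
                fr[num - peptide.start_number] = f
        return cls(tuple(fr))


@dataclass(frozen=True)
class SimulationSpec:
    """Noise levels and seed shared by the generators.

    Defaults are the per-measurement experimental errors of the shift data
    (0.01 ppm ¹H, 0.1 ppm ¹³C); CD noise defaults to zero.
    """

    seed: int = 0
    noise_h_ppm: float = 0.01
    noise_c_ppm: float = 0.1
    cd_noise_mdeg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.noise_h_ppm, self.noise_c_ppm, self.cd_noise_mdeg) < 0:
            raise SyntheticError("noise levels must be >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def noise(self, nucleus: str) -> float:
        return self.noise_c_ppm if nucleus == "CA" else self.noise_h_ppm


# two-state limiting secondary shifts by nucleus; HN carries no helix
# signature in this model (it only contributes measurement noise)
_LIMITS = {"HA": FULL_HELIX_LIMIT["HA"], "CA": FULL_HELIX_LIMIT["CA"], "HN": 0.0}


def simulate_shift_table(
    peptide: Peptide,
    profile: HelixProfile,
    rc: RandomCoilTable,
    spec: SimulationSpec,
    condition: str = "synthetic",
) -> ShiftTable:
    """Two-state shift table: δ_obs(i, ν) = δ_RC(aa_i, ν) + f_i·Δδ_100%(ν) + ε."""
    if len(profile.fractions) != len(peptide):
        raise SyntheticError(
            f"profile length {len(profile.fractions)} != peptide length {len(peptide)}"
        )
    rng = spec.rng(salt=1)
    shifts: dict[tuple[int, str], float] = {}
    for i, num in enumerate(peptide.residue_numbers):
        aa = peptide.sequence[i]
        for nuc in ("HA", "HN", "CA"):
            if nuc == "HN" and aa == "P":
                continue
            if not rc.has(aa, nuc):
                continue
            value = rc.shift(aa, nuc) + profile.fractions[i] * _LIMITS[nuc]
            sigma = spec.noise(nuc)
            if sigma > 0:
                value += rng.normal(0.0, sigma)
            shifts[(num, nuc)] = value
    return ShiftTable(
        peptide,
        condition,
        shifts,
        meta={"true_profile": profile.fractions, "rc_set": rc.name, "seed": spec.seed},
    )


def simulate_mixture_perturbation(
    free: ShiftTable,
    perturbed: Mapping[int, tuple[float, float, float]],
    spec: SimulationSpec,
) -> ShiftTable:
    """Mixture table = free + (ΔHA, ΔHN, ΔCA) offsets + fresh noise.

    Offsets on nuclei absent from the free table are skipped with a
    warning; the ground-truth offsets are recorded in the table metadata.
    """
    rng = spec.rng(salt=2)
    applied: dict[int, tuple[float, float, float]] = {}
    shifts: dict[tuple[int, str], float] = {}
    for num in perturbed:
        if num not in free.peptide:
            raise SyntheticError(f"perturbed residue {num} not in peptide")
    for (num, nuc), value in free.shifts.items():
        offset = 0.0
        if num in perturbed:
            d_ha, d_hn, d_ca = perturbed[num]
            offset = {"HA": d_ha, "HN": d_hn, "CA": d_ca}[nuc]
            applied[num] = perturbed[num]
        sigma = spec.noise(nuc)
        noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        shifts[(num, nuc)] = value + offset + noise
    skipped = {
        num: nucs
        for num in perturbed
        if (
            nucs := [
                nuc
                for nuc, d in zip(("HA", "HN", "CA"), perturbed[num])
                if d != 0.0 and (num, nuc) not in free.shifts
            ]
        )
    }
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "perturbation offsets skipped on missing nuclei: %s", skipped
        )
    return ShiftTable(
        free.peptide,
        free.condition,
        shifts,
        temperature_C=free.temperature_C,
        pH=free.pH,
        label=f"{free.id}+partner",
        meta={"true_offsets": dict(perturbed), "seed": spec.seed},
    )


# ---------------------------------------------------------------- CD bases


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _helix_basis(lam: np.ndarray) -> np.ndarray:
    """Smooth helix-like shape: +band <195 nm, minima at 208 and 222 nm.

    A parametric stand-in anchored so B_helix(222) is exactly the full-helix
    limit of the 222 nm estimator.
    """
    shape = (
        1.5 * _gauss(lam, 190.0, 4.5)
        - 1.0 * _gauss(lam, 208.0, 4.5)
        - 0.95 * _gauss(lam, 222.0, 4.5)
    )
    at222 = (
        1.5 * math.exp(-0.5 * (32.0 / 4.5) ** 2)
        - math.exp(-0.5 * (14.0 / 4.5) ** 2)
        - 0.95
    )
    return shape * (THETA222_HELIX / at222)


def _coil_basis(lam: np.ndarray) -> np.ndarray:
    """Coil-like shape: single deep minimum near 197 nm, anchored at 222 nm."""
    g222 = math.exp(-0.5 * (25.0 / 7.0) ** 2)
    offset = THETA222_COIL + 20000.0 * g222
    return -20000.0 * _gauss(lam, 197.0, 7.0) + offset


def simulate_cd_spectrum(
    f_helix: float,
    n_res: int,
    spec: SimulationSpec,
    wavelengths: Sequence[float] | None = None,
) -> CDSpectrum:
    """Two-basis mean-residue CD spectrum for helix fraction ``f_helix``.

    [θ](λ) = f·B_helix(λ) + (1−f)·B_coil(λ) + noise; at 222 nm the
    noise-free value is exactly f·(−36000) + (1−f)·3000, so the 222 nm
    estimator inverts it.
    """
    if not 0.0 <= f_helix <= 1.0:
        raise SyntheticError("helix fraction must lie in [0, 1]")
    lam = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(190.0, 260.0 + 1e-9, 0.5)
    )
    theta = f_helix * _helix_basis(lam) + (1.0 - f_helix) * _coil_basis(lam)
    if spec.cd_noise_mdeg > 0:
        theta = theta + spec.rng(salt=3).normal(0.0, spec.cd_noise_mdeg, lam.shape)
    return CDSpectrum(
        lam,
        theta,
        units=MOLAR_ELLIPTICITY,
        meta={"true_f_helix": f_helix, "n_residues": n_res},
    )


# ---------------------------------------------------------------- helices

# ideal backbone internal coordinates (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
PHI_ALPHA, PSI_ALPHA, OMEGA = -57.0, -47.0, 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement of atom d given chain a-b-c and internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    peptide: Peptide, phi: float = PHI_ALPHA, psi: float = PSI_ALPHA
) -> Model:
    """N/CA/C backbone of an ideal helix over the whole peptide."""
    coords: list[np.ndarray] = []
    # seed triad for residue 1
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords += [n0, ca0, c0]
    for _ in range(len(peptide) - 1):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_new = _place_atom(ca_prev, c_prev, n_new, _B_N_CA, _A_C_N_CA, OMEGA)
        c_new = _place_atom(c_prev, n_new, ca_new, _B_CA_C, _A_N_CA_C, phi)
        coords += [n_new, ca_new, c_new]
    res_numbers = np.repeat(list(peptide.residue_numbers), 3)
    atom_names = tuple(["N", "CA", "C"] * len(peptide))
    elements = tuple(["N", "C", "C"] * len(peptide))
    return Model(res_numbers, atom_names, elements, np.vstack(coords))


def build_hinged_helix_ensemble(
    peptide: Peptide,
    seg_a: HelixSegment,
    seg_b: HelixSegment,
    angle_deg: float,
    n_models: int = 20,
    jitter: float = 0.0,
    seed: int = 0,
) -> ModelEnsemble:
    """Ensemble of helix-hinge-helix models at a prescribed inter-axis angle.

    Starting from one ideal straight helix, all atoms from ``seg_b.first``
    onward are rotated about the hinge (the first CA of ``seg_b``) so that
    the angle between the two segments' fitted N→C axes equals
    ``angle_deg`` exactly before jitter.  Gaussian coordinate jitter of the
    given Å scale (independent per model) is added afterwards.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise SyntheticError("angle must lie in [0°, 180°]")
    if seg_a.last >= seg_b.first:
        raise SyntheticError(f"segments {seg_a} and {seg_b} must be disjoint and ordered")
    for seg in (seg_a, seg_b):
        if seg.first not in peptide or seg.last not in peptide:
            raise SyntheticError(f"segment {seg} outside peptide")

    base = build_ideal_helix(peptide)
    a0 = fit_helix_axis(base, seg_a).direction
    b0 = fit_helix_axis(base, seg_b).direction
    alpha0 = math.degrees(math.acos(float(np.clip(a0 @ b0, -1.0, 1.0))))
    # rotation axis normal to both fitted axes keeps b in the (a, b) plane
    n = np.cross(a0, b0)
    if np.linalg.norm(n) < 1e-8:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a0 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(a0, helper)
    n /= np.linalg.norm(n)

    hinge = base.coord_of(seg_b.first, "CA").copy()
    mask = base.res_numbers >= seg_b.first

    def rotated(delta_deg: float) -> np.ndarray:
        rot = Rotation.from_rotvec(np.radians(delta_deg) * n)
        xyz = base.coords.copy()
        xyz[mask] = rot.apply(xyz[mask] - hinge) + hinge
        return xyz

    # the sign of the in-plane rotation that opens the angle
    best_xyz, best_err = None, float("inf")
    for delta in (angle_deg - alpha0, alpha0 - angle_deg):
        xyz = rotated(delta)
        trial = Model(base.res_numbers, base.atom_names, base.elements, xyz)
        ang = math.degrees(
            math.acos(
                float(
                    np.clip(
                        fit_helix_axis(trial, seg_a).direction
                        @ fit_helix_axis(trial, seg_b).direction,
                        -1.0,
                        1.0,
                    )
                )
            )
        )
        err = abs(ang - angle_deg)
        if err < best_err:
            best_xyz, best_err = xyz, err

    rng = np.random.default_rng((seed, 4))
    models = []
    for _ in range(n_models):
        xyz = best_xyz.copy()
        if jitter > 0:
            xyz = xyz + rng.normal(0.0, jitter, xyz.shape)
        models.append(Model(base.res_numbers, base.atom_names, base.elements, xyz))
    return ModelEnsemble(tuple(models), peptide)
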