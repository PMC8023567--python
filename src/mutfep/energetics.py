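"""Reference-state construction and nonbonded energetics.

The unphysical reference side chains are short linear chains grown from the
C-alpha: RDR carries one non-interacting dummy atom plus one soft-core sphere
(bond lengths 0.153 nm), R2R two soft-core spheres (0.252 and 0.351 nm).  The
soft atoms use (C6)^1/2 = 0.27322 (kJ mol^-1 nm^6)^1/2 and
(C12)^1/2 = 0.056143 (kJ mol^-1 nm^12)^1/2 with soft-core parameter 1.51,
giving an effective van der Waals radius of about 0.662 nm.  Electrostatics
follow the Barker-Watts reaction-field scheme (eps_RF = 61, cutoff 1.4 nm).
All energies are direct pair sums over explicit selections; coordinates are
in nm, energies in kJ/mol, charges in elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_PREFACTOR = 138.9354

#: Square-root LJ parameters of the soft reference atoms.
REFERENCE_C6_SQRT = 0.27322  # (kJ mol^-1 nm^6)^1/2
REFERENCE_C12_SQRT = 0.056143  # (kJ mol^-1 nm^12)^1/2

#: Soft-core softness parameter of the reference atoms.
SOFTCORE_ALPHA = 1.51


@dataclass
class AtomRecord:
    """One interaction site: position (nm), charge (e), square-root LJ params."""

    name: str
    position: np.ndarray
    charge: float = 0.0
    c6_sqrt: float = 0.0
    c12_sqrt: float = 0.0
    soft: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.c6_sqrt < 0 or self.c12_sqrt < 0:
            raise ValueError("square-root LJ parameters must be non-negative")


@dataclass
class NonbondedParams:
    """Cutoff and reaction-field parameters."""

    cutoff: float = 1.4  # nm
    eps_rf: float = 61.0
    coulomb_prefactor: float = COULOMB_PREFACTOR

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.eps_rf < 1:
            raise ValueError("eps_rf must be >= 1")


@dataclass
class ReferenceStateSpec:
    """Geometry and nonbonded parameters of an RDR or R2R reference side chain."""

    variant: str = "RDR"
    softcore_alpha: float = SOFTCORE_ALPHA
    c6_sqrt: float = REFERENCE_C6_SQRT
    c12_sqrt: float = REFERENCE_C12_SQRT
    # RDR: Ca-D and D-A bonds; R2R: Ca-A and A-A bonds.
    bond_lengths: tuple = None

    def __post_init__(self) -> None:
        if self.variant not in ("RDR", "R2R"):
            raise ValueError("variant must be 'RDR' or 'R2R'")
        if self.bond_lengths is None:
            self.bond_lengths = (0.153, 0.153) if self.variant == "RDR" else (0.252, 0.351)
        if any(b <= 0 for b in self.bond_lengths):
            raise ValueError("bond lengths must be positive")


@dataclass
class Frame:
    """A single configuration: atoms plus named index selections."""

    atoms: list
    selections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for name, idx in self.selections.items():
            idx = list(idx)
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"selection {name!r} holds invalid atom indices")
            self.selections[name] = idx

    def select(self, name: str) -> list:
        return [self.atoms[i] for i in self.selections[name]]


@dataclass
class RotamerConformer:
    """A library side-chain conformation with its C-alpha and occurrence P."""

    atoms: list
    side_chain_indices: list
    occurrence: float = 1.0
    ca_index: int = None

    def __post_init__(self) -> None:
        if self.ca_index is None:
            ca = [i for i, a in enumerate(self.atoms) if a.name.strip() == "CA"]
            if len(ca) != 1:
                raise ValueError("conformer must contain exactly one CA atom")
            self.ca_index = ca[0]

    @property
    def ca_position(self) -> np.ndarray:
        return self.atoms[self.ca_index].position

    def side_chain_cog(self) -> np.ndarray:
        if not self.side_chain_indices:
            raise ValueError("conformer has no side-chain atoms")
        return np.mean([self.atoms[i].position for i in self.side_chain_indices], axis=0)


def crf_constant(eps_rf: float) -> float:
    """Reaction-field constant C_RF = 2(eps-1)/(2 eps + 1)."""
    if eps_rf < 1:
        raise ValueError("eps_rf must be >= 1")
    return 2.0 * (eps_rf - 1.0) / (2.0 * eps_rf + 1.0)


def rf_coulomb_energy(q1: float, q2: float, r: float, params: NonbondedParams) -> float:
    """Barker-Watts reaction-field Coulomb energy of a charge pair (kJ/mol).

    E = f q1 q2 [1/r + C_RF r^2 / (2 Rc^3) - (1 + C_RF/2)/Rc]; the shift makes
    the energy exactly zero at the cutoff; beyond it, pairs contribute zero.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    rc = params.cutoff
    if r > rc:
        return 0.0
    c = crf_constant(params.eps_rf)
    return (
        params.coulomb_prefactor
        * q1
        * q2
        * (1.0 / r + c * r * r / (2.0 * rc**3) - (1.0 + c / 2.0) / rc)
    )


def combine_lj(a: AtomRecord, b: AtomRecord) -> tuple[float, float]:
    """Geometric GROMOS combination: C6 = c6a^1/2 c6b^1/2, C12 likewise."""
    return a.c6_sqrt * b.c6_sqrt, a.c12_sqrt * b.c12_sqrt


def lj_energy(c6: float, c12: float, r: float) -> float:
    """Plain 12-6 Lennard-Jones energy C12/r^12 - C6/r^6 (kJ/mol)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    r6 = r**6
    return c12 / (r6 * r6) - c6 / r6


def softcore_lj_energy(
    c6: float,
    c12: float,
    r: float,
    alpha_sc: float = SOFTCORE_ALPHA,
    lambda_sc: float = 1.0,
) -> float:
    """Soft-core Lennard-Jones energy, finite at r = 0 for lambda_sc > 0.

    With s = alpha_sc (C12/C6) lambda_sc^2 the energy is
    C12/(s + r^6)^2 - C6/(s + r^6); s = 0 recovers the plain 12-6 form.
    """
    if r < 0:
        raise ValueError("distance must be non-negative")
    shift = alpha_sc * lambda_sc**2
    if shift == 0.0:
        return lj_energy(c6, c12, r)
    if c6 == 0.0:
        if c12 == 0.0:
            return 0.0
        raise ValueError("soft-core undefined without C6")
    s = shift * (c12 / c6)
    denom = s + r**6
    return c12 / (denom * denom) - c6 / denom


def effective_vdw_radius(c6_sqrt: float = REFERENCE_C6_SQRT, c12_sqrt: float = REFERENCE_C12_SQRT) -> float:
    """Self-pair LJ minimum distance (2 C12/C6)^(1/6); informational only."""
    c6 = c6_sqrt * c6_sqrt
    c12 = c12_sqrt * c12_sqrt
    return (2.0 * c12 / c6) ** (1.0 / 6.0)


def build_reference_state(
    spec: ReferenceStateSpec, ca_position: Sequence[float], direction: Sequence[float]
) -> list:
    """Place the reference-chain atoms collinearly from the C-alpha.

    Atoms sit along ``direction`` at cumulative bond lengths: RDR puts the
    dummy D at 0.153 nm and the soft sphere A at 0.306 nm; R2R puts soft
    spheres at 0.252 and 0.603 nm.
    """
    ca = np.asarray(ca_position, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("zero direction vector")
    d = d / norm
    soft_kwargs = dict(c6_sqrt=spec.c6_sqrt, c12_sqrt=spec.c12_sqrt, soft=True)
    dist1 = spec.bond_lengths[0]
    dist2 = spec.bond_lengths[0] + spec.bond_lengths[1]
    if spec.variant == "RDR":
        return [
            AtomRecord("D", ca + dist1 * d),  # non-interacting dummy
            AtomRecord("A", ca + dist2 * d, **soft_kwargs),
        ]
    return [
        AtomRecord("A1", ca + dist1 * d, **soft_kwargs),
        AtomRecord("A2", ca + dist2 * d, **soft_kwargs),
    ]


def fit_rotamer(
    frame_ca_position: Sequence[float],
    refstate_atoms: Iterable[AtomRecord],
    rotamer: RotamerConformer,
) -> list:
    """Rigidly place a library conformer onto a reference-state frame.

    The conformer is translated so its C-alpha coincides with the frame's,
    then rotated about the C-alpha by the minimal rotation that carries the
    Ca -> side-chain-centre-of-geometry direction onto the Ca -> soft-site
    centroid direction.  The residual torsion about that axis keeps its
    library value.  Returns the transformed atom positions in conformer order.
    """
    soft_positions = [a.position for a in refstate_atoms if a.soft]
    if not soft_positions:
        raise ValueError("reference state has no soft atoms")
    ca_target = np.asarray(frame_ca_position, dtype=float)
    centroid = np.mean(soft_positions, axis=0)
    v = centroid - ca_target
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("undefined orientation: soft centroid coincides with CA")
    v = v / nv

    ca_rot = rotamer.ca_position
    cog = rotamer.side_chain_cog()
    u = cog - ca_rot
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ValueError("undefined orientation")
    u = u / nu

    rot, _ = Rotation.align_vectors([v], [u])
    return [
        ca_target + rot.apply(a.position - ca_rot) for a in rotamer.atoms
    ]


def pair_energy(a: AtomRecord, b: AtomRecord, nb: NonbondedParams, alpha_sc: float = SOFTCORE_ALPHA) -> float:
    """Nonbonded energy of one atom pair: (soft-core) LJ + reaction-field Coulomb."""
    r = float(np.linalg.norm(a.position - b.position))
    if r > nb.cutoff:
        return 0.0
    c6, c12 = combine_lj(a, b)
    soft = a.soft or b.soft
    if soft:
        e = softcore_lj_energy(c6, c12, r, alpha_sc=alpha_sc, lambda_sc=1.0)
    else:
        if r < 1e-4:
            raise ValueError(f"overlapping physical atoms {a.name}-{b.name} at r={r:g} nm")
        e = lj_energy(c6, c12, r)
    if a.charge != 0.0 and b.charge != 0.0:
        e += rf_coulomb_energy(a.charge, b.charge, r, nb)
    return e


def group_energy(
    group_a: Iterable[AtomRecord],
    group_b: Iterable[AtomRecord],
    nb: NonbondedParams,
    alpha_sc: float = SOFTCORE_ALPHA,
) -> float:
    """Direct double sum of pair energies between two disjoint atom groups."""
    return sum(pair_energy(a, b, nb, alpha_sc) for a in group_a for b in group_b)


def perturbation_energy(
    frame: Frame,
    placed_side_chain: Iterable[AtomRecord],
    refstate_atoms: Iterable[AtomRecord],
    nb: NonbondedParams,
    environment: str = "environment",
    alpha_sc: float = SOFTCORE_ALPHA,
) -> float:
    """Per-frame perturbation energy dH = H_target - H_reference (kJ/mol).

    The target term sums plain-LJ + reaction-field interactions of the placed
    physical side-chain atoms with the frame's environment selection; the
    reference term sums soft-core interactions of the reference atoms with the
    same environment.  An empty environment yields zero.
    """
    env = frame.select(environment)
    e_target = group_energy(placed_side_chain, env, nb, alpha_sc)
    e_ref = group_energy(refstate_atoms, env, nb, alpha_sc)
    return e_target - e_ref


def system_energy(atoms: Sequence[AtomRecord], nb: NonbondedParams, alpha_sc: float = SOFTCORE_ALPHA) -> float:
    """Total energy over unique pairs of a toy system (direct O(N^2) sum)."""
    total = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            total += pair_energy(atoms[i], atoms[j], nb, alpha_sc)
    return total
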