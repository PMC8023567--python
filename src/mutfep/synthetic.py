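"""Seeded synthetic ensembles with analytically known free energies.

These generators stand in for molecular-dynamics sampling: every one returns
its own exact ground truth (a Gaussian closed form, a brute-force partition
sum, or an analytic polynomial integral), so the estimators can be validated
end-to-end without trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .energetics import NonbondedParams, system_energy
from .osp import ConformerEnsembleSet, PerturbationSeries
from .tpf import EndStateStats, LambdaProfile


@dataclass
class GaussianEnsembleSpec:
    """Gaussian perturbation-energy ensemble: dH ~ N(mu, sigma^2)."""

    mu: float
    sigma: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.n_frames < 1:
            raise ValueError("sigma must be >= 0 and n_frames >= 1")


def gen_gaussian_series(
    spec: GaussianEnsembleSpec,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    leg: str = "bound",
    dimer: str = "A",
    conformer_id: int = 1,
) -> tuple[PerturbationSeries, float]:
    """Seeded Gaussian dH draws and the exact free energy mu - beta sigma^2 / 2."""
    rng = np.random.default_rng(spec.seed)
    values = rng.normal(spec.mu, spec.sigma, spec.n_frames)
    exact = spec.mu - constants.beta * spec.sigma**2 / 2.0
    series = PerturbationSeries(values, leg=leg, dimer=dimer, conformer_id=conformer_id)
    return series, exact


@dataclass
class DiscreteSystemSpec:
    """Fully enumerable two-Hamiltonian system over shared microstates."""

    microstate_energies_R: list
    microstate_energies_N: list
    temperature: float = DEFAULT_CONSTANTS.temperature

    def __post_init__(self) -> None:
        if len(self.microstate_energies_R) != len(self.microstate_energies_N):
            raise ValueError("energy lists must be parallel")
        if len(self.microstate_energies_R) < 2:
            raise ValueError("need >= 2 microstates")


def discrete_exact_dG(spec: DiscreteSystemSpec, constants: ThermoConstants | None = None) -> float:
    """Brute-force partition sums: dG = -kT ln(Z_N / Z_R)."""
    if constants is None:
        constants = ThermoConstants(temperature=spec.temperature)
    beta = constants.beta
    e_r = np.asarray(spec.microstate_energies_R, dtype=float)
    e_n = np.asarray(spec.microstate_energies_N, dtype=float)
    # log-sum-exp partition sums
    def _logz(e):
        m = np.min(beta * e)
        return -m + math.log(np.sum(np.exp(-(beta * e - m))))

    return -(_logz(e_n) - _logz(e_r)) / beta


def gen_discrete_system(
    spec: DiscreteSystemSpec,
    n_frames: int = 1000,
    seed: int = 0,
    leg: str = "bound",
    dimer: str = "A",
) -> tuple[PerturbationSeries, float]:
    """Sample microstates from the R-state Boltzmann distribution.

    Each sampled frame carries dH = E_N - E_R of its microstate; the exact
    free energy comes from full partition-sum enumeration.
    """
    constants = ThermoConstants(temperature=spec.temperature)
    beta = constants.beta
    e_r = np.asarray(spec.microstate_energies_R, dtype=float)
    e_n = np.asarray(spec.microstate_energies_N, dtype=float)
    w = np.exp(-beta * (e_r - e_r.min()))
    w /= w.sum()
    rng = np.random.default_rng(seed)
    states = rng.choice(e_r.size, size=n_frames, p=w)
    series = PerturbationSeries(e_n[states] - e_r[states], leg=leg, dimer=dimer)
    return series, discrete_exact_dG(spec, constants)


@dataclass
class PolynomialProfileSpec:
    """True dG/dlambda cubic a + b l + c l^2 + d l^3 with optional endpoint noise."""

    a: float
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    noise: float = 0.0
    seed: int = 0
    n_grid: int = 101


def gen_polynomial_profile(
    spec: PolynomialProfileSpec,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    leg: str = "bound",
    dimer: str = "A",
) -> tuple[LambdaProfile, EndStateStats, float]:
    """Exact lambda profile, matching end-state statistics, and the true integral.

    Endpoint curvatures are encoded into fluctuations via the cumulant
    relation rmsd = sqrt(-G''/beta); positive curvature has no Gaussian
    counterpart and is rejected.
    """
    a, b, c, d = spec.a, spec.b, spec.c, spec.d
    g0p, g0pp = a, b
    g1p = a + b + c + d
    g1pp = b + 2 * c + 3 * d
    if g0pp > 0 or g1pp > 0:
        raise ValueError("cumulant curvature must be non-positive")
    beta = constants.beta
    rng = np.random.default_rng(spec.seed)
    jitter = (lambda: rng.normal(0.0, spec.noise)) if spec.noise > 0 else (lambda: 0.0)
    stats = EndStateStats(
        mean_N=g0p + jitter(),
        rmsd_N=math.sqrt(-g0pp / beta),
        mean_C=g1p + jitter(),
        rmsd_C=math.sqrt(-g1pp / beta),
        leg=leg,
        dimer=dimer,
    )
    lambdas = np.linspace(0.0, 1.0, spec.n_grid)
    means = a + b * lambdas + c * lambdas**2 + d * lambdas**3
    exact = a + b / 2.0 + c / 3.0 + d / 4.0
    return LambdaProfile(lambdas, means), stats, exact


def gen_gaussian_ensemble_set(
    mus: dict,
    sigma: float,
    occurrences: dict,
    n_frames: int,
    seed: int = 0,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    dimers: tuple = ("A", "B"),
) -> tuple[ConformerEnsembleSet, float]:
    """Full bound/unbound conformer set with an analytic binding free energy.

    ``mus`` maps (conformer_id, leg) -> Gaussian mean; all series share one
    sigma.  The exact binding value is the occurrence-weighted exponential
    combination of the per-conformer Gaussian free energies, differenced over
    legs (identical across dimers by construction).
    """
    beta = constants.beta
    rng = np.random.default_rng(seed)
    series = {}
    legs = sorted({leg for (_, leg) in mus})
    conformers = sorted({c for (c, _) in mus})
    for leg in legs:
        for dimer in dimers:
            for conf in conformers:
                values = rng.normal(mus[(conf, leg)], sigma, n_frames)
                series[(conf, leg, dimer)] = PerturbationSeries(
                    values, leg=leg, dimer=dimer, conformer_id=conf
                )
    exact_leg = {}
    for leg in legs:
        weighted = [
            (mus[(c, leg)] - beta * sigma**2 / 2.0) - math.log(occurrences[c]) / beta
            for c in conformers
        ]
        arr = np.asarray(weighted)
        m = arr.min()
        exact_leg[leg] = m - math.log(np.sum(np.exp(-beta * (arr - m)))) / beta
    exact_binding = exact_leg.get("bound", 0.0) - exact_leg.get("unbound", 0.0)
    ensemble = ConformerEnsembleSet(series=series, occurrences=dict(occurrences))
    return ensemble, exact_binding


@dataclass
class ToyComplexSpec:
    """Small interacting-particle system sampled by Metropolis Monte Carlo."""

    atoms: list = field(default_factory=list)
    temperature: float = DEFAULT_CONSTANTS.temperature
    steps: int = 1000
    step_size: float = 0.02  # nm
    seed: int = 0
    restraint_k: float = 0.0  # kJ mol^-1 nm^-2 harmonic tether to start positions

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("need at least one particle")
        if len(self.atoms) > 20:
            raise ValueError("toy systems are capped at 20 particles")


def gen_toy_complex(
    spec: ToyComplexSpec,
    nb: NonbondedParams | None = None,
    sample_every: int = 1,
) -> tuple[list, float]:
    """Metropolis sampling of a toy complex; returns (frames, acceptance rate).

    Each frame is the list of particle positions (copies).  Energies are
    direct pair sums plus an optional harmonic tether; a zero-step run returns
    only the initial frame.
    """
    if nb is None:
        nb = NonbondedParams()
    constants = ThermoConstants(temperature=spec.temperature)
    beta = constants.beta
    rng = np.random.default_rng(spec.seed)
    atoms = [a for a in spec.atoms]
    anchors = [a.position.copy() for a in atoms]

    def energy() -> float:
        e = system_energy(atoms, nb)
        if spec.restraint_k > 0:
            for a, ref in zip(atoms, anchors):
                e += 0.5 * spec.restraint_k * float(np.sum((a.position - ref) ** 2))
        return e

    current = energy()
    frames = [[a.position.copy() for a in atoms]]
    accepted = 0
    for step in range(spec.steps):
        i = int(rng.integers(len(atoms)))
        old = atoms[i].position.copy()
        atoms[i].position = old + rng.normal(0.0, spec.step_size, 3)
        try:
            proposed = energy()
        except ValueError:  # overlapping physical atoms
            proposed = math.inf
        if proposed <= current or rng.random() < math.exp(-beta * (proposed - current)):
            current = proposed
            accepted += 1
        else:
            atoms[i].position = old
        if (step + 1) % sample_every == 0:
            frames.append([a.position.copy() for a in atoms])
    rate = accepted / spec.steps if spec.steps else 0.0
    return frames, rate
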