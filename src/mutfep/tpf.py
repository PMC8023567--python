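"""Third-power fitting (TPF) of charging free energies, TI oracle, charging
corrections and linear-interaction-energy (LIE) estimates.

The charging of a side chain couples the electrostatic Hamiltonian linearly in
lambda, so the derivative V = dH/dlambda is the charging coupling energy and
the free-energy curve G(lambda) has endpoint derivatives

    G'(0)  = <V>_N          G''(0) = -beta Var_N(V)
    G'(1)  = <V>_C          G''(1) = -beta Var_C(V)

(second cumulant / Gaussian approximation).  TPF fits the cubic
dG/dlambda = a + b*lambda + c*lambda^2 + d*lambda^3 to these four values and
integrates it analytically; with end-state means and fluctuations only, two
simulations replace a full thermodynamic-integration ladder.  Raw charging
free energies of net-charge-changing mutations are corrected a posteriori for
reaction-field/cutoff/periodicity artifacts whose components (pol+dir, dsm)
are supplied per leg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ThermoConstants


@dataclass
class EndStateStats:
    """Mean and fluctuation (standard deviation) of the charging coupling
    energy V = dH/dlambda in the neutral (N) and charged (C) end-state
    ensembles, in kJ/mol."""

    mean_N: float
    rmsd_N: float
    mean_C: float
    rmsd_C: float
    leg: str = "bound"
    dimer: str = "A"

    def __post_init__(self) -> None:
        if self.rmsd_N < 0 or self.rmsd_C < 0:
            raise ValueError("rmsd must be non-negative")
        for v in (self.mean_N, self.rmsd_N, self.mean_C, self.rmsd_C):
            if not math.isfinite(v):
                raise ValueError("end-state statistics must be finite")


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the fitted dG/dlambda = a + b l + c l^2 + d l^3 (kJ/mol)."""

    a: float
    b: float
    c: float
    d: float

    def __call__(self, lam: float | np.ndarray) -> float | np.ndarray:
        lam = np.asarray(lam, dtype=float)
        out = self.a + lam * (self.b + lam * (self.c + lam * self.d))
        return float(out) if out.ndim == 0 else out


@dataclass
class ChargingCorrections:
    """Per-leg correction components: pol_dir = dG_pol + dG_dir, dsm = dG_dsm (kJ/mol)."""

    pol_dir: float
    dsm: float
    leg: str = "bound"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pol_dir) and math.isfinite(self.dsm)):
            raise ValueError("corrections must be finite")


@dataclass
class TPFResults:
    """Corrected charging free energy: corrected = raw + correction_total (kJ/mol).

    ``raw`` is the dimer-averaged bound-minus-unbound TPF free energy (or a
    single-leg value when only one leg is supplied), ``correction_total`` the
    bound-minus-unbound artifact correction.
    """

    raw: float
    correction_total: float = 0.0
    per_leg: dict = field(default_factory=dict)
    coefficients: dict = field(default_factory=dict)

    @property
    def corrected(self) -> float:
        return self.raw + self.correction_total

    def summary(self) -> str:
        lines = ["Third-power-fitting results", "-" * 31]
        for key, value in sorted(self.per_leg.items()):
            lines.append(f"dG_N>C[{key}] = {value:10.3f} kJ/mol")
        lines.append(f"raw        = {self.raw:10.3f} kJ/mol")
        lines.append(f"correction = {self.correction_total:10.3f} kJ/mol")
        lines.append(f"corrected  = {self.corrected:10.3f} kJ/mol")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Plot the fitted dG/dlambda cubic(s); requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lam = np.linspace(0.0, 1.0, 101)
        for key, coeffs in sorted(self.coefficients.items()):
            ax.plot(lam, coeffs(lam), label=str(key))
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel(r"d$G$/d$\lambda$ (kJ/mol)")
        if self.coefficients:
            ax.legend()
        return ax


@dataclass
class LambdaProfile:
    """<dH/dlambda> means on a lambda grid for the TI quadrature oracle."""

    lambdas: np.ndarray
    means: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.lambdas.shape != self.means.shape or self.lambdas.size < 2:
            raise ValueError("profile needs >= 2 matching lambda points")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambdas must be strictly increasing")
        if self.lambdas[0] != 0.0 or self.lambdas[-1] != 1.0:
            raise ValueError("lambda grid must span [0, 1] including endpoints")


def endpoint_derivatives(
    stats: EndStateStats, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> tuple[float, float, float, float]:
    """First and second free-energy derivatives at lambda = 0 and 1.

    Returns (G'(0), G''(0), G'(1), G''(1)); curvatures follow the cumulant
    relation G'' = -beta * rmsd^2 for linear coupling.
    """
    beta = constants.beta
    return (
        stats.mean_N,
        -beta * stats.rmsd_N**2,
        stats.mean_C,
        -beta * stats.rmsd_C**2,
    )


def fit_third_power(derivs: Sequence[float]) -> CubicCoefficients:
    """Cubic dG/dlambda through endpoint first/second derivatives.

    Solves a = G'(0), b = G''(0), a+b+c+d = G'(1), b+2c+3d = G''(1) exactly.
    """
    g0p, g0pp, g1p, g1pp = (float(v) for v in derivs)
    for v in (g0p, g0pp, g1p, g1pp):
        if not math.isfinite(v):
            raise ValueError("derivatives must be finite")
    a = g0p
    b = g0pp
    # c + d = g1p - a - b ; 2c + 3d = g1pp - b
    s1 = g1p - a - b
    s2 = g1pp - b
    d = s2 - 2.0 * s1
    c = s1 - d
    return CubicCoefficients(a, b, c, d)


def integrate_cubic(coeffs: CubicCoefficients) -> float:
    """Analytic integral of the fitted cubic over lambda in [0, 1]."""
    return coeffs.a + coeffs.b / 2.0 + coeffs.c / 3.0 + coeffs.d / 4.0


def tpf_free_energy(
    stats: EndStateStats | Iterable[EndStateStats],
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """TPF charging free energy dG_N>C, arithmetically averaged over dimers."""
    if isinstance(stats, EndStateStats):
        stats = [stats]
    values = [
        integrate_cubic(fit_third_power(endpoint_derivatives(s, constants)))
        for s in stats
    ]
    if not values:
        raise ValueError("no end-state statistics supplied")
    return float(np.mean(values))


def ti_oracle(profile: LambdaProfile) -> float:
    """Thermodynamic-integration reference: trapezoidal quadrature of <dH/dl>."""
    return float(np.trapezoid(profile.means, profile.lambdas))


def ti_oracle_gauss(coeffs: CubicCoefficients, order: int = 8) -> float:
    """Gauss-Legendre quadrature of a smooth dG/dlambda on [0, 1] (test aid)."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    lam = 0.5 * (nodes + 1.0)
    return float(0.5 * np.sum(weights * coeffs(lam)))


def sum_leg_corrections(c: ChargingCorrections) -> float:
    """Total per-leg correction: (dG_pol + dG_dir) + dG_dsm."""
    return c.pol_dir + c.dsm


def total_correction(bound_sum: float, unbound_sum: float) -> float:
    """Net correction entering the binding difference: bound - unbound."""
    return bound_sum - unbound_sum


def apply_correction(raw: float, cor: float) -> float:
    """Corrected charging free energy dG_N>C = raw + correction."""
    return raw + cor


class ThirdPowerFit:
    """TPF model over end-state statistics of both thermodynamic legs.

    Parameters
    ----------
    stats : iterable of EndStateStats
        One entry per (leg, dimer).  When both legs are present, ``fit``
        returns the bound-minus-unbound raw charging free energy (each leg
        dimer-averaged); with a single leg it returns that leg's value.
    corrections : iterable of ChargingCorrections, optional
        Per-leg artifact corrections for net-charge-changing mutations.
    """

    def __init__(
        self,
        stats: Iterable[EndStateStats],
        corrections: Iterable[ChargingCorrections] = (),
        constants: ThermoConstants = DEFAULT_CONSTANTS,
    ) -> None:
        self.stats = list(stats)
        if not self.stats:
            raise ValueError("no end-state statistics supplied")
        self.corrections = list(corrections)
        self.constants = constants

    @classmethod
    def from_dataframe(
        cls,
        stats: pd.DataFrame,
        corrections: pd.DataFrame | None = None,
        constants: ThermoConstants = DEFAULT_CONSTANTS,
    ) -> "ThirdPowerFit":
        """Build from frames with columns (leg, dimer, mean_N, rmsd_N, mean_C,
        rmsd_C) and optionally (leg, pol_dir, dsm)."""
        stat_objs = [
            EndStateStats(
                mean_N=row.mean_N,
                rmsd_N=row.rmsd_N,
                mean_C=row.mean_C,
                rmsd_C=row.rmsd_C,
                leg=row.leg,
                dimer=getattr(row, "dimer", "A"),
            )
            for row in stats.itertuples(index=False)
        ]
        cor_objs = []
        if corrections is not None:
            cor_objs = [
                ChargingCorrections(pol_dir=row.pol_dir, dsm=row.dsm, leg=row.leg)
                for row in corrections.itertuples(index=False)
            ]
        return cls(stat_objs, cor_objs, constants=constants)

    def fit(self) -> TPFResults:
        per_leg: dict = {}
        coefficients: dict = {}
        legs = sorted({s.leg for s in self.stats})
        for leg in legs:
            leg_stats = [s for s in self.stats if s.leg == leg]
            per_dimer = []
            for s in leg_stats:
                coeffs = fit_third_power(endpoint_derivatives(s, self.constants))
                coefficients[(leg, s.dimer)] = coeffs
                per_dimer.append(integrate_cubic(coeffs))
            per_leg[leg] = float(np.mean(per_dimer))
        if set(legs) >= {"bound", "unbound"}:
            raw = per_leg["bound"] - per_leg["unbound"]
        else:
            raw = per_leg[legs[0]]
        cor = 0.0
        if self.corrections:
            sums = {c.leg: sum_leg_corrections(c) for c in self.corrections}
            if set(sums) >= {"bound", "unbound"}:
                cor = total_correction(sums["bound"], sums["unbound"])
            else:
                cor = next(iter(sums.values()))
        return TPFResults(
            raw=raw, correction_total=cor, per_leg=per_leg, coefficients=coefficients
        )


def lie_binding(
    dV_vdw: float,
    dV_coul: float,
    alpha: float = 0.161,
    beta_el: float = 0.5,
) -> float:
    """Linear-interaction-energy binding estimate alpha*dV_vdw + beta_el*dV_coul.

    ``dV_vdw`` and ``dV_coul`` are bound-minus-unbound ensemble-average
    interaction-energy differences in kJ/mol (dimer-averaged upstream).  The
    empirical van der Waals coefficient defaults to 0.161 and the standard
    electrostatic coefficient to 1/2.
    """
    for v in (dV_vdw, dV_coul, alpha, beta_el):
        if not math.isfinite(v):
            raise ValueError("LIE inputs must be finite")
    return alpha * dV_vdw + beta_el * dV_coul
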