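"""One-step perturbation (OSP) free energies.

A single simulation of an unphysical reference side chain (soft-core atoms)
yields per-frame perturbation energies dH = H_target - H_reference for many
physical end states at once.  The free-energy difference to each end state
follows from Zwanzig exponential reweighting,

    dG = -kT ln < exp(-beta dH) >_R ,

conformer-library occurrences enter as -kT ln P_i shifts, and the per-conformer
estimates are combined by a second exponential average.  The fraction of
reference frames with dH below the final dG diagnoses how well the reference
ensemble overlaps a given end state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DEFAULT_CONSTANTS, ThermoConstants

LEGS = ("bound", "unbound")
DIMERS = ("A", "B")


@dataclass
class PerturbationSeries:
    """Per-frame perturbation energies for one conformer in one ensemble leg.

    Parameters
    ----------
    values : array-like
        dH = H_target - H_reference per frame, in kJ/mol.
    leg : {"bound", "unbound"}
    dimer : {"A", "B"}
    conformer_id : int
        1-based conformer index in the rotamer library.
    kind : {"insertion", "removal"}
        "removal" marks side-chain-removal series (the Gly convention), so
        downstream cycle assembly can recognise them.
    """

    values: np.ndarray
    leg: str = "bound"
    dimer: str = "A"
    conformer_id: int = 1
    kind: str = "insertion"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("empty ensemble")
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(f"non-finite perturbation energy at frame {bad[0]}")
        if self.leg not in LEGS:
            raise ValueError(f"leg must be one of {LEGS}, got {self.leg!r}")
        if self.dimer not in DIMERS:
            raise ValueError(f"dimer must be one of {DIMERS}, got {self.dimer!r}")
        if self.conformer_id < 1:
            raise ValueError("conformer_id must be >= 1")

    @property
    def frame_count(self) -> int:
        return int(self.values.size)


@dataclass
class ConformerEnsembleSet:
    """All perturbation series of one end state keyed by (conformer, leg, dimer).

    ``occurrences`` holds the relative occurrence P_i of each library conformer;
    they must sum to one over the conformers of the set.
    """

    series: dict
    occurrences: dict

    def __post_init__(self) -> None:
        conformers = sorted({key[0] for key in self.series})
        if not conformers:
            raise ValueError("empty ensemble set")
        total = sum(self.occurrences.get(c, 0.0) for c in conformers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occurrences must sum to 1, got {total}")
        for c in conformers:
            if self.occurrences.get(c, 0.0) <= 0:
                raise ValueError("non-positive occurrence")
        legs = {key[1] for key in self.series}
        dimers = {key[2] for key in self.series}
        for c in conformers:
            for leg in legs:
                for dimer in dimers:
                    if (c, leg, dimer) not in self.series:
                        raise ValueError(
                            f"conformer {c} missing from leg={leg!r} dimer={dimer!r}"
                        )
        self.conformer_ids = conformers
        self.legs = sorted(legs)
        self.dimers = sorted(dimers)


def zwanzig_free_energy(
    series: PerturbationSeries, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Zwanzig free-energy difference -kT ln <exp(-beta dH)>_R in kJ/mol.

    Uses a log-sum-exp reformulation, so arbitrarily large |dH| cannot
    overflow the exponential.
    """
    beta = constants.beta
    values = series.values
    return -(logsumexp(-beta * values) - math.log(values.size)) / beta


def weight_conformer(dG: float, occurrence: float, constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Fold a conformer occurrence P into its free energy: dG - kT ln(P)."""
    if occurrence <= 0:
        raise ValueError("non-positive occurrence")
    return dG - constants.kT * math.log(occurrence)


def combine_conformers(
    weighted_dGs: Sequence[float], constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Exponential combination -kT ln sum_i exp(-beta dG_i) of weighted values.

    With occurrence-weighted inputs this evaluates
    -kT ln sum_i P_i <exp(-beta dH_i)>_R, the occurrence-weighted OSP estimate
    over the conformer library.  The result never exceeds min(dG_i).
    """
    dGs = np.asarray(weighted_dGs, dtype=float)
    if dGs.size == 0:
        raise ValueError("empty ensemble")
    beta = constants.beta
    return -logsumexp(-beta * dGs) / beta


def contributing_fraction(series: PerturbationSeries, dG: float) -> float:
    """Percentage of frames with dH strictly below the free-energy estimate."""
    if not math.isfinite(dG):
        raise ValueError("dG must be finite")
    return 100.0 * float(np.count_nonzero(series.values < dG)) / series.frame_count


def glycine_removal_dG(
    series: PerturbationSeries, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Free energy of removing the reference side chain (the Gly end state).

    Identical estimator to :func:`zwanzig_free_energy`; the series should carry
    ``kind="removal"`` so cycle assembly can apply the Gly convention.
    """
    if series.kind != "removal":
        series.kind = "removal"
    return zwanzig_free_energy(series, constants)


def average_tautomers(dG_A: float, dG_B: float) -> float:
    """Arithmetic mean of the two histidine-tautomer free energies."""
    if not (math.isfinite(dG_A) and math.isfinite(dG_B)):
        raise ValueError("tautomer free energies must be finite")
    return 0.5 * (dG_A + dG_B)


@dataclass
class OSPResults:
    """Results of an occurrence-weighted OSP evaluation.

    Attributes
    ----------
    per_conformer_dG : dict
        Unweighted Zwanzig dG per (conformer_id, leg, dimer), kJ/mol.
    combined_dG : dict
        Occurrence-weighted, exponentially combined dG per (leg, dimer), kJ/mol.
    binding_dG : float
        Dimer-averaged bound-minus-unbound free energy, kJ/mol.
    p_contr : float
        Contributing-frame percentage averaged over conformers, legs, dimers.
    """

    per_conformer_dG: dict
    combined_dG: dict
    binding_dG: float
    p_contr: float
    constants: ThermoConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    def summary(self) -> str:
        lines = ["One-step perturbation results", "-" * 33]
        for (leg, dimer), value in sorted(self.combined_dG.items()):
            lines.append(f"dG[{leg:>7s}, dimer {dimer}] = {value:10.3f} kJ/mol")
        lines.append(f"binding dG (bound - unbound, dimer mean) = {self.binding_dG:.3f} kJ/mol")
        lines.append(f"contributing frames = {self.p_contr:.2f} %")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"conformer": c, "leg": leg, "dimer": dimer, "dG_kJ_mol": v}
            for (c, leg, dimer), v in sorted(self.per_conformer_dG.items())
        ]
        return pd.DataFrame(rows)


class OneStepPerturbation:
    """OSP model over a conformer ensemble set.

    Build from a :class:`ConformerEnsembleSet` (or a tidy DataFrame via
    :meth:`from_dataframe`), then :meth:`fit` evaluates the Zwanzig estimator
    per conformer, folds in occurrences, combines conformers per (leg, dimer),
    and forms the dimer-averaged binding free energy.
    """

    def __init__(
        self,
        ensemble: ConformerEnsembleSet,
        constants: ThermoConstants = DEFAULT_CONSTANTS,
    ) -> None:
        self.ensemble = ensemble
        self.constants = constants

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        occurrences: Mapping[int, float] | None = None,
        constants: ThermoConstants = DEFAULT_CONSTANTS,
    ) -> "OneStepPerturbation":
        """Build from a tidy frame with columns leg, dimer, conformer, delta_H_kJ_mol.

        If ``occurrences`` is omitted, conformers are taken as equally likely.
        """
        required = {"leg", "dimer", "conformer", "delta_H_kJ_mol"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        series: dict = {}
        for (conf, leg, dimer), group in data.groupby(["conformer", "leg", "dimer"]):
            conf = int(conf)
            series[(conf, leg, dimer)] = PerturbationSeries(
                group["delta_H_kJ_mol"].to_numpy(), leg=leg, dimer=dimer, conformer_id=conf
            )
        conformers = sorted({k[0] for k in series})
        if occurrences is None:
            occurrences = {c: 1.0 / len(conformers) for c in conformers}
        ensemble = ConformerEnsembleSet(series=series, occurrences=dict(occurrences))
        return cls(ensemble, constants=constants)

    def fit(self) -> OSPResults:
        ens = self.ensemble
        if not {"bound", "unbound"}.issubset(ens.legs):
            raise ValueError("both bound and unbound legs required")
        per_conformer: dict = {}
        combined: dict = {}
        fractions = []
        for leg in ens.legs:
            for dimer in ens.dimers:
                weighted = []
                for conf in ens.conformer_ids:
                    s = ens.series[(conf, leg, dimer)]
                    dG = zwanzig_free_energy(s, self.constants)
                    per_conformer[(conf, leg, dimer)] = dG
                    weighted.append(weight_conformer(dG, ens.occurrences[conf], self.constants))
                    fractions.append(contributing_fraction(s, dG))
                combined[(leg, dimer)] = combine_conformers(weighted, self.constants)
        diffs = [
            combined[("bound", d)] - combined[("unbound", d)] for d in ens.dimers
        ]
        return OSPResults(
            per_conformer_dG=per_conformer,
            combined_dG=combined,
            binding_dG=float(np.mean(diffs)),
            p_contr=float(np.mean(fractions)),
            constants=self.constants,
        )


def osp_pipeline(
    ensemble: ConformerEnsembleSet, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> OSPResults:
    """Functional wrapper: weight, combine and difference an ensemble set."""
    return OneStepPerturbation(ensemble, constants=constants).fit()
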