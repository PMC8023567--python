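"""Thermodynamic-cycle assembly of relative binding free energies.

Per mutation and reference-state variant, the binding free energy relative to
the unphysical reference state is the OSP (nonpolar) term plus the corrected
TPF (charging) term.  The reference-state contribution cancels only between
legs that share a variant, so a relative mutation free energy against the
wild type is formed strictly within one variant; the variant is chosen per
mutation as the one whose reference ensemble contributed the larger fraction
of frames.  Histidine tautomers are averaged after cycle closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .osp import average_tautomers

VARIANTS = ("RDR", "R2R")

HIS_TAUTOMERS = ("HisA", "HisB")


@dataclass
class RefStateEntry:
    """One mutation's result for one reference-state variant."""

    osp_dG: float
    p_contr: float = float("nan")
    tpf_corrected: float | None = None
    binding_override: float | None = None

    @property
    def binding_dG(self) -> float:
        if self.binding_override is not None:
            return self.binding_override
        return combine_osp_tpf(self.osp_dG, self.tpf_corrected)


@dataclass
class MutantRecord:
    """Per-reference-state OSP/TPF results for one mutation at one site."""

    site: str
    mutation: str
    p1prime: str
    per_refstate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.per_refstate:
            raise ValueError("at least one reference-state variant required")
        for variant in self.per_refstate:
            if variant not in VARIANTS:
                raise ValueError(f"unknown reference-state variant {variant!r}")

    def binding_dG(self, variant: str) -> float:
        return self.per_refstate[variant].binding_dG


@dataclass
class SiteScanResult:
    """Relative binding free energies of one saturation scan."""

    site: str
    p1prime: str
    wildtype: str
    relative_dG: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site": self.site, "mutation": m, "p1prime": self.p1prime, "relative_dG": v}
            for m, v in sorted(self.relative_dG.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Saturation scan at site {self.site} (wild type {self.wildtype}, "
            f"P1' = {self.p1prime})",
            "-" * 52,
        ]
        for m, v in sorted(self.relative_dG.items()):
            lines.append(f"{m:>6s}  {v:8.1f} kJ/mol")
        return "\n".join(lines)


def combine_osp_tpf(osp_dG: float, tpf_corrected: float | None = None) -> float:
    """Binding free energy relative to the reference state: OSP + corrected TPF.

    Apolar side chains have no charging step; a missing TPF term counts as 0.
    """
    if not math.isfinite(osp_dG):
        raise ValueError("OSP free energy must be finite")
    if tpf_corrected is None or (isinstance(tpf_corrected, float) and math.isnan(tpf_corrected)):
        return osp_dG
    return osp_dG + tpf_corrected


def select_reference_state(p_contr_rdr: float, p_contr_r2r: float) -> str:
    """Pick the variant with the larger contributing-frame percentage (tie: RDR)."""
    for p in (p_contr_rdr, p_contr_r2r):
        if not 0.0 <= p <= 100.0:
            raise ValueError("contributing percentages must lie in [0, 100]")
    return "R2R" if p_contr_r2r > p_contr_rdr else "RDR"


def _choose_variant(record: MutantRecord) -> str:
    if len(record.per_refstate) == 1:
        return next(iter(record.per_refstate))
    rdr = record.per_refstate["RDR"].p_contr
    r2r = record.per_refstate["R2R"].p_contr
    return select_reference_state(rdr, r2r)


def relative_mutation_energy(mutant: MutantRecord, wildtype: MutantRecord) -> float:
    """Cycle-closed relative binding free energy of a mutation (kJ/mol).

    Selects the mutant's reporting variant by contributing-frame percentage and
    subtracts the wild type's binding free energy in the *same* variant; only
    then does the shared reference-state free energy cancel.
    """
    variant = _choose_variant(mutant)
    if variant not in wildtype.per_refstate:
        raise ValueError(
            f"cycle cannot close: wild type lacks reference-state variant {variant}"
        )
    return mutant.binding_dG(variant) - wildtype.binding_dG(variant)


def assemble_site_scan(
    records: list[MutantRecord],
    wildtype: MutantRecord,
    average_his_tautomers: bool = True,
) -> SiteScanResult:
    """Close the cycle for every mutation of one site against the wild type.

    Returns one row per canonical amino acid; His tautomers are averaged after
    cycle closure.  The wild type itself appears at exactly 0.
    """
    sites = {r.site for r in records} | {wildtype.site}
    p1s = {r.p1prime for r in records} | {wildtype.p1prime}
    if len(sites) != 1 or len(p1s) != 1:
        raise ValueError("records must share one site and one P1' residue")
    seen = set()
    relative: dict = {}
    for rec in records:
        if rec.mutation in seen:
            raise ValueError(f"duplicate mutation entry {rec.mutation!r}")
        seen.add(rec.mutation)
        if rec.mutation == wildtype.mutation:
            relative[rec.mutation] = 0.0
        else:
            relative[rec.mutation] = relative_mutation_energy(rec, wildtype)
    relative.setdefault(wildtype.mutation, 0.0)
    if average_his_tautomers and all(t in relative for t in HIS_TAUTOMERS):
        relative["His"] = average_tautomers(*(relative.pop(t) for t in HIS_TAUTOMERS))
    return SiteScanResult(
        site=wildtype.site,
        p1prime=wildtype.p1prime,
        wildtype=wildtype.mutation,
        relative_dG=relative,
    )


def records_from_table(table: pd.DataFrame) -> list[MutantRecord]:
    """Build mutant records from a long-format binding table.

    Expected columns: site, mutation, p1prime, variant, osp_dG, p_contr,
    tpf_corrected (blank for apolar side chains) and optionally binding_dG
    (an explicit override used verbatim where given).
    """
    required = {"site", "mutation", "p1prime", "variant", "osp_dG"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records: dict = {}
    for row in table.itertuples(index=False):
        key = (str(row.site), row.mutation, row.p1prime)
        tpf = getattr(row, "tpf_corrected", None)
        if tpf is not None and isinstance(tpf, float) and math.isnan(tpf):
            tpf = None
        override = getattr(row, "binding_dG", None)
        if override is not None and isinstance(override, float) and math.isnan(override):
            override = None
        entry = RefStateEntry(
            osp_dG=float(row.osp_dG),
            p_contr=float(getattr(row, "p_contr", float("nan"))),
            tpf_corrected=tpf,
            binding_override=override,
        )
        if key not in records:
            records[key] = MutantRecord(
                site=str(row.site),
                mutation=row.mutation,
                p1prime=row.p1prime,
                per_refstate={row.variant: entry},
            )
        else:
            if row.variant in records[key].per_refstate:
                raise ValueError(f"duplicate mutation entry {key}")
            records[key].per_refstate[row.variant] = entry
    return list(records.values())
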