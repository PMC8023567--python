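"""Packaged caspase-2 saturation-mutagenesis reference dataset.

The package ships the published free-energy tables of the E105/G171 scans of
human caspase-2 (OSP free energies per reference state, charging corrections,
raw TPF charging free energies, per-variant binding free energies, relative
free energies with the experimental screen outcome, and the LIE comparison)
as machine-readable TSV fixtures.  ``site_scans`` and ``study_metrics`` rerun
the whole post-simulation pipeline — correction bookkeeping, cycle closure,
classification — from those inputs.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import cycle as _cycle
from . import validation as _validation
from .tpf import (
    ChargingCorrections,
    apply_correction,
    sum_leg_corrections,
    total_correction,
)

WILDTYPE = {"105": "Glu", "171": "Gly"}

#: The four mutations whose side chain changes the net charge.
CHARGED = ("Arg", "Asp", "Glu", "Lys")


def _read(name: str) -> pd.DataFrame:
    path = resources.files("mutfep.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"site": str})


def load_osp_table() -> pd.DataFrame:
    """OSP free energies and contributing-frame percentages, both variants."""
    return _read("osp_free_energies.tsv")


def load_corrections() -> pd.DataFrame:
    """Charging-correction components (pol_dir, dsm) per leg."""
    return _read("charging_corrections.tsv")


def load_tpf_table() -> pd.DataFrame:
    """Raw TPF charging free energies with published correction/corrected."""
    return _read("tpf_charging.tsv")


def load_binding_table() -> pd.DataFrame:
    """Per-variant OSP + TPF binding free energies relative to the reference state."""
    return _read("binding_free_energies.tsv")


def load_relative_outcomes() -> pd.DataFrame:
    """Published relative free energies with experimental screen outcomes."""
    return _read("relative_energies_exp.tsv")


def load_lie_table() -> pd.DataFrame:
    """LIE vs OSP+TPF relative free energies for the 14 polar mutations."""
    return _read("lie_vs_osp_tpf.tsv")


def load_cross_table_proportions() -> pd.DataFrame:
    """Published pooled cross-table proportions per P1' subset."""
    return _read("cross_table_proportions.tsv")


def corrected_charging() -> pd.DataFrame:
    """Recompute the charging bookkeeping from its components.

    Per (site, p1prime, mutation): per-leg sums of (pol_dir, dsm), the total
    correction bound − unbound, and the corrected charging free energy
    raw + total.  Columns: bound_sum, unbound_sum, cor, raw, corrected.
    """
    comp = load_corrections()
    raw = load_tpf_table()
    rows = []
    for (site, p1, mut), group in comp.groupby(["site", "p1prime", "mutation"]):
        sums = {}
        for leg_row in group.itertuples(index=False):
            sums[leg_row.leg] = sum_leg_corrections(
                ChargingCorrections(pol_dir=leg_row.pol_dir, dsm=leg_row.dsm, leg=leg_row.leg)
            )
        cor = total_correction(sums["bound"], sums["unbound"])
        raw_val = float(
            raw.query("site == @site and p1prime == @p1 and mutation == @mut")["raw"].iloc[0]
        )
        rows.append(
            {
                "site": site,
                "p1prime": p1,
                "mutation": mut,
                "bound_sum": sums["bound"],
                "unbound_sum": sums["unbound"],
                "cor": cor,
                "raw": raw_val,
                "corrected": apply_correction(raw_val, cor),
            }
        )
    return pd.DataFrame(rows)


def reference_records(recompute_charging: bool = True) -> pd.DataFrame:
    """Binding table with p_contr joined in and, optionally, the charged
    mutations' TPF term replaced by the value recomputed from components."""
    binding = load_binding_table().copy()
    osp = load_osp_table()[["site", "p1prime", "mutation", "variant", "p_contr"]]
    binding = binding.merge(osp, on=["site", "p1prime", "mutation", "variant"], how="left")
    if recompute_charging:
        charged = corrected_charging()
        lookup = {
            (r.site, r.p1prime, r.mutation): r.corrected for r in charged.itertuples(index=False)
        }
        binding["tpf_corrected"] = [
            lookup.get((r.site, r.p1prime, r.mutation), r.tpf_corrected)
            for r in binding.itertuples(index=False)
        ]
    return binding


def site_scans(recompute_charging: bool = True) -> dict:
    """Cycle-closed saturation scans keyed by (site, p1prime).

    His tautomers are averaged after closure; the wild type sits at exactly 0.
    """
    table = reference_records(recompute_charging=recompute_charging)
    scans = {}
    for (site, p1), group in table.groupby(["site", "p1prime"]):
        records = _cycle.records_from_table(group)
        wt_name = WILDTYPE[str(site)]
        wildtype = next(r for r in records if r.mutation == wt_name)
        scans[(str(site), p1)] = _cycle.assemble_site_scan(records, wildtype)
    return scans


def predictions_from_scans(scans: dict) -> pd.DataFrame:
    """Join recomputed relative free energies with the experimental outcomes."""
    outcomes = load_relative_outcomes().copy()
    outcomes["mutation"] = outcomes["mutation"].replace({"HisA": "His", "HisB": "His"})
    found = outcomes.groupby(["site", "p1prime", "mutation"])["found"].max()
    rows = []
    for (site, p1), scan in scans.items():
        for mut, value in scan.relative_dG.items():
            rows.append(
                {
                    "site": site,
                    "p1prime": p1,
                    "mutation": mut,
                    "predicted_dG": value,
                    "found": int(found.loc[(site, p1, mut)]),
                }
            )
    return pd.DataFrame(rows)


def study_metrics(recompute_charging: bool = True) -> dict:
    """Rerun the full validation pipeline and return its headline numbers.

    MCC and concordance per P1' subset and pooled (wild-type rows excluded),
    plus the per-(site, P1') MCCs of the OSP+TPF and LIE routes over the 14
    polar mutations and the MAD/Pearson agreement between the two methods.
    """
    scans = site_scans(recompute_charging=recompute_charging)
    preds = predictions_from_scans(scans)

    def _table(frame: pd.DataFrame) -> _validation.CrossTable:
        return _validation.build_cross_table(
            _validation.records_from_frame(frame), exclude_wildtype=True, wildtype=WILDTYPE
        )

    out: dict = {"n_predictions": int(len(preds))}
    for p1 in ("Ile", "Pro"):
        table = _table(preds[preds["p1prime"] == p1])
        out[f"mcc_{p1.lower()}"] = _validation.mcc(table)
        out[f"concordance_{p1.lower()}_pct"] = _validation.concordance(table)
    pooled = _table(preds)
    out["mcc_combined"] = _validation.mcc(pooled)
    out["concordance_combined_pct"] = _validation.concordance(pooled)
    out["cross_table_combined"] = pooled

    lie = load_lie_table()
    polar = preds[preds["mutation"].isin(lie["mutation"].unique())]
    for (site, p1), group in lie.groupby(["site", "p1prime"]):
        key = f"{'e105' if str(site) == '105' else 'g171'}_{p1.lower()}"
        sim = polar.drop(columns=["found"]).merge(
            group[["site", "p1prime", "mutation", "found"]],
            on=["site", "p1prime", "mutation"],
        )
        osp_table = _validation.build_cross_table(
            _validation.records_from_frame(
                sim[["site", "mutation", "p1prime", "predicted_dG", "found"]]
            ),
            exclude_wildtype=True,
            wildtype=WILDTYPE,
        )
        lie_frame = group.rename(columns={"lie": "predicted_dG"})
        lie_table = _validation.build_cross_table(
            _validation.records_from_frame(
                lie_frame[["site", "mutation", "p1prime", "predicted_dG", "found"]]
            ),
            exclude_wildtype=True,
            wildtype=WILDTYPE,
        )
        out[f"mcc_osp_tpf_{key}"] = _validation.mcc(osp_table)
        out[f"mcc_lie_{key}"] = _validation.mcc(lie_table)
        out[f"mad_{key}"] = _validation.mad(group["lie"], group["osp_tpf"])
        out[f"pearson_{key}"] = _validation.pearson(group["lie"], group["osp_tpf"])
    return out
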