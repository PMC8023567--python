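"""Readers and writers for the tabular dialects and PDB conformer libraries.

All tabular formats are UTF-8 tab-separated files with ``#`` comment lines
and strict numeric parsing; readers validate and report line numbers on
malformed rows.  Rotamer conformer libraries are multi-MODEL PDB files read
through Bio.PDB; the occupancy column carries the conformer occurrence P_i
when present.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Atom import Atom as _BioAtom
from Bio.PDB.Chain import Chain as _BioChain
from Bio.PDB.Model import Model as _BioModel
from Bio.PDB.Residue import Residue as _BioResidue
from Bio.PDB.Structure import Structure as _BioStructure

from .constants import DEFAULT_CONSTANTS, ThermoConstants
from .energetics import AtomRecord, RotamerConformer
from .osp import ConformerEnsembleSet, PerturbationSeries

BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT"}

ENERGY_COLUMNS = ["frame", "leg", "dimer", "conformer", "delta_H_kJ_mol"]


def _provenance_header(command: str, inputs: dict | None = None, seed: int | None = None) -> str:
    lines = [f"# mutfep provenance: {command}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for name, path in (inputs or {}).items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        lines.append(f"# input {name}: {path} sha256:{digest}")
    return "\n".join(lines) + "\n"


def _read_tsv(path, required: set, dtypes: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", dtype=dtypes, float_precision="round_trip"
        )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_energy_series(path, occurrences_path=None) -> ConformerEnsembleSet:
    """Read a per-frame perturbation-energy table into a conformer ensemble set.

    Dialect: ``frame  leg  dimer  conformer  delta_H_kJ_mol`` with legs
    bound|unbound and dimers A|B.  A sidecar occurrence table (``conformer``,
    ``occurrence``) may be supplied; otherwise occurrences are uniform.
    """
    frame = _read_tsv(path, set(ENERGY_COLUMNS))
    values = pd.to_numeric(frame["delta_H_kJ_mol"], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric delta_H on data row {bad[0] + 1}")
    series = {}
    for (conf, leg, dimer), group in frame.groupby(["conformer", "leg", "dimer"]):
        series[(int(conf), leg, dimer)] = PerturbationSeries(
            group["delta_H_kJ_mol"].to_numpy(dtype=float),
            leg=leg,
            dimer=dimer,
            conformer_id=int(conf),
        )
    conformers = sorted({k[0] for k in series})
    if occurrences_path is not None:
        occ_frame = _read_tsv(occurrences_path, {"conformer", "occurrence"})
        occurrences = {
            int(r.conformer): float(r.occurrence) for r in occ_frame.itertuples(index=False)
        }
    else:
        occurrences = {c: 1.0 / len(conformers) for c in conformers}
    return ConformerEnsembleSet(series=series, occurrences=occurrences)


def write_energy_series(
    ensemble: ConformerEnsembleSet, path, command: str = "write_energy_series", seed=None
) -> None:
    """Write an ensemble set in the energy-series dialect with a provenance header."""
    rows = []
    for (conf, leg, dimer), s in sorted(ensemble.series.items()):
        for i, v in enumerate(s.values):
            rows.append((i, leg, dimer, conf, repr(float(v))))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(command, seed=seed))
        fh.write("\t".join(ENERGY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_occurrences(occurrences: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("conformer\toccurrence\n")
        for conf, p in sorted(occurrences.items()):
            fh.write(f"{conf}\t{repr(float(p))}\n")


def read_endpoint_stats(path) -> pd.DataFrame:
    """Read end-state statistics: site mutation p1prime leg dimer mean_N rmsd_N mean_C rmsd_C."""
    return _read_tsv(
        path,
        {"site", "mutation", "p1prime", "leg", "dimer", "mean_N", "rmsd_N", "mean_C", "rmsd_C"},
        dtypes={"site": str},
    )


def read_corrections(path) -> pd.DataFrame:
    """Read correction components: site mutation p1prime leg pol_dir dsm."""
    return _read_tsv(path, {"site", "mutation", "p1prime", "leg", "pol_dir", "dsm"}, dtypes={"site": str})


def read_lie_averages(path) -> pd.DataFrame:
    """Read LIE interaction-energy differences: site mutation p1prime dV_vdw dV_coul."""
    return _read_tsv(path, {"site", "mutation", "p1prime", "dV_vdw", "dV_coul"}, dtypes={"site": str})


def read_binding_table(path) -> pd.DataFrame:
    """Read a per-variant binding table: site mutation p1prime variant osp_dG [p_contr tpf_corrected binding_dG]."""
    return _read_tsv(path, {"site", "mutation", "p1prime", "variant", "osp_dG"}, dtypes={"site": str})


def read_predictions(path) -> pd.DataFrame:
    """Read predictions: site mutation p1prime predicted_dG found(0|1)."""
    return _read_tsv(
        path, {"site", "mutation", "p1prime", "predicted_dG", "found"}, dtypes={"site": str}
    )


def read_config(path) -> dict:
    """Read a YAML/JSON run configuration (cutoff_nm, eps_rf, softcore_alpha, ...)."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def read_pdb_conformers(path, occurrences: dict | None = None) -> list[RotamerConformer]:
    """Read a multi-MODEL PDB rotamer library, one conformer per MODEL.

    The C-alpha is the atom named CA; side-chain atoms are all non-backbone
    atoms.  Occupancies < 1 are taken as conformer occurrences unless an
    explicit mapping is given.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("rotamers", str(path))
    conformers = []
    for model in structure:
        atoms = []
        side_chain = []
        occ = None
        for atom in model.get_atoms():
            name = atom.get_name().strip()
            atoms.append(
                AtomRecord(name=name, position=np.asarray(atom.coord, dtype=float) / 10.0)
            )
            if name not in BACKBONE_NAMES:
                side_chain.append(len(atoms) - 1)
            if atom.get_occupancy() is not None:
                occ = float(atom.get_occupancy())
        if not any(a.name == "CA" for a in atoms):
            raise ValueError(f"model {model.id}: no CA atom")
        occurrence = 1.0
        if occurrences is not None:
            occurrence = occurrences.get(model.id + 1, occurrences.get(model.id, 1.0))
        elif occ is not None:
            occurrence = occ
        conformers.append(
            RotamerConformer(atoms=atoms, side_chain_indices=side_chain, occurrence=occurrence)
        )
    if not conformers:
        raise ValueError(f"{path}: no MODEL records")
    return conformers


def write_pdb_conformers(conformers: list[RotamerConformer], path, resname: str = "UNK") -> None:
    """Write conformers as a multi-MODEL PDB (coordinates nm -> Angstrom)."""
    structure = _BioStructure("rotamers")
    for m, conformer in enumerate(conformers):
        model = _BioModel(m)
        chain = _BioChain("A")
        residue = _BioResidue((" ", 1, " "), resname, "")
        for i, atom in enumerate(conformer.atoms):
            residue.add(
                _BioAtom(
                    name=atom.name,
                    coord=np.asarray(atom.position, dtype=float) * 10.0,
                    bfactor=0.0,
                    occupancy=conformer.occurrence,
                    altloc=" ",
                    fullname=f" {atom.name:<3s}"[:4],
                    serial_number=i + 1,
                    element=atom.name[0],
                )
            )
        chain.add(residue)
        model.add(chain)
        structure.add(model)
    writer = PDBIO()
    writer.set_structure(structure)
    writer.save(str(path))
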