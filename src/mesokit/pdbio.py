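"""Multi-model PDB I/O for conformer pools (CA-only traces).

Pools are written as one MODEL per conformer with a single CA atom per
residue, via biotite's PDB reader/writer.  Refined ensembles are
written alongside a weights CSV and a JSON diagnostics file.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .conformers import Conformer, ConformerPool, SecondaryStructureDirective

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


def write_pool(path, pool: ConformerPool) -> None:
    """Write a pool as a multi-model CA-only PDB file."""
    n_res = len(pool.sequence)
    template = struc.AtomArray(n_res)
    template.chain_id = np.full(n_res, "A")
    template.res_id = np.arange(1, n_res + 1)
    template.res_name = np.array([THREE_LETTER[a] for a in pool.sequence])
    template.atom_name = np.full(n_res, "CA")
    template.element = np.full(n_res, "C")
    coords = np.stack([c.ca_coords for c in pool.conformers])
    stack = struc.from_template(template, coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_pool(path) -> ConformerPool:
    """Read a multi-model CA PDB back into a pool.

    Dihedral angles are not stored in the CA-only format; the returned
    conformers carry NaN dihedrals and are suitable for geometry-only
    operations (Rg, nu, assembly, scattering).
    """
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"]
    seq = "".join(ONE_LETTER.get(rn, "A") for rn in ca.res_name[ca.res_id > 0])
    n_res = ca.array_length()
    seq = seq[:n_res]
    conformers = []
    nan = np.full(n_res, np.nan)
    for coords in ca.coord:
        conformers.append(Conformer(seq, nan.copy(), nan.copy(), np.array(coords)))
    directive = SecondaryStructureDirective.all_coil(n_res)
    return ConformerPool(conformers, seq, directive, mode="cooperative", mode_param=0.0, seed=-1)


def write_ensemble(prefix, ensemble) -> None:
    """Write a refined ensemble: PDB + weights CSV + JSON diagnostics."""
    write_pool(f"{prefix}.pdb", ensemble.pool)
    pd.DataFrame(
        {"conformer": np.arange(len(ensemble.weights)), "weight": ensemble.weights}
    ).to_csv(f"{prefix}_weights.csv", index=False)
    with open(f"{prefix}_diagnostics.json", "w") as fh:
        json.dump(
            {
                "mean_nu": ensemble.mean_nu,
                "loglik": ensemble.loglik,
                "converged": bool(ensemble.converged),
                "status": ensemble.status,
                "nu_trajectory": [float(v) for v in ensemble.nu_trajectory],
            },
            fh,
            indent=2,
        )
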