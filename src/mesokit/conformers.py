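"""Statistical-coil conformer pools and per-conformer observables.

A :class:`ConformerPool` emulates the construction used to model a
disordered protein inside a condensate: a large pool (default 10,000)
of backbone conformers in which secondary-structure-predicted regions
(confidence > 5) are always built with canonical helix/strand dihedrals
while the remaining residues are sampled either

* **cooperatively** - a stated fraction (0, 12.5, 25 or 37.5 %) of the
  conformers carry fully formed beta-strand dihedrals in the
  unstructured regions, the rest statistical coil - or
* **non-cooperatively** - unstructured dihedrals drawn from a Gaussian
  centered at (phi, psi) = (-112.6, 123) deg with dispersion sigma in
  115-140 deg.

Per conformer the pool stores the radius of gyration Rg, the polymer
scaling factor v solving Rg = rho0 * N**v, and (on demand) surrogate
chemical-shift predictions.  rho0 defaults to 1.927 A, the standard
empirical denatured-state prefactor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chain as _chain
from .chain import ChainBuildError  # re-exported  # noqa: F401

RHO0_DEFAULT = 1.927  # A, empirical denatured-state prefactor

COOPERATIVE_FRACTIONS = (0.0, 12.5, 25.0, 37.5)  # percent
NONCOOP_DISPERSION_RANGE = (115.0, 140.0)  # degrees

# Random-coil chemical shifts (ppm), one row per residue type, for the
# surrogate predictor.  Approximate literature random-coil values; the
# plugin seam in predict_shifts accepts externally computed tables so a
# published predictor can be swapped in without code change.
RANDOM_COIL_SHIFTS = {
    #        CA     CB      C      N     HN
    "A": (52.5, 19.1, 177.8, 123.8, 8.24),
    "C": (58.2, 28.0, 174.6, 118.8, 8.32),
    "D": (54.2, 41.1, 176.3, 120.4, 8.34),
    "E": (56.6, 29.9, 176.6, 120.2, 8.42),
    "F": (57.7, 39.6, 175.8, 120.3, 8.30),
    "G": (45.1, np.nan, 174.9, 108.8, 8.33),
    "H": (55.0, 29.0, 174.1, 118.2, 8.42),
    "I": (61.1, 38.8, 176.4, 119.9, 8.00),
    "K": (56.2, 33.1, 176.6, 120.4, 8.29),
    "L": (55.1, 42.4, 177.6, 121.8, 8.16),
    "M": (55.4, 32.9, 176.3, 119.6, 8.28),
    "N": (53.1, 38.9, 175.2, 118.7, 8.40),
    "P": (63.3, 32.1, 177.3, np.nan, np.nan),
    "Q": (55.7, 29.4, 176.0, 119.8, 8.32),
    "R": (56.0, 30.9, 176.3, 120.5, 8.23),
    "S": (58.3, 63.8, 174.6, 115.7, 8.31),
    "T": (61.8, 69.8, 174.7, 113.6, 8.15),
    "V": (62.2, 32.9, 176.3, 119.2, 8.03),
    "W": (57.5, 29.6, 176.1, 121.3, 8.25),
    "Y": (57.9, 38.8, 175.9, 120.3, 8.12),
}

ATOMS = ("CA", "CB", "C", "N", "HN")

# secondary-structure offsets added to the random-coil value (ppm):
# positive CA / negative CB for helix, the reverse for strand
SECONDARY_OFFSETS = {
    "helix": {"CA": 2.6, "CB": -0.4, "C": 1.7, "N": -1.5, "HN": -0.25},
    "strand": {"CA": -1.5, "CB": 2.2, "C": -1.5, "N": 1.5, "HN": 0.35},
    "coil": {a: 0.0 for a in ATOMS},
}


@dataclass
class SecondaryStructureDirective:
    """Per-residue secondary-structure states with 0-9 confidences.

    Residues with state 'helix' or 'strand' and confidence > 5 are
    treated as structured and always built with canonical dihedrals.
    """

    states: list
    confidences: np.ndarray

    def __post_init__(self) -> None:
        self.confidences = np.asarray(self.confidences, dtype=int)
        if len(self.states) != self.confidences.size:
            raise ValueError("states and confidences lengths differ")
        ok = {"coil", "helix", "strand"}
        bad = set(self.states) - ok
        if bad:
            raise ValueError(f"unknown states {bad}")
        if np.any((self.confidences < 0) | (self.confidences > 9)):
            raise ValueError("confidences must be integers in 0-9")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def structured(self) -> np.ndarray:
        """Boolean mask of residues built with canonical dihedrals."""
        return np.array(
            [s != "coil" and c > 5 for s, c in zip(self.states, self.confidences)]
        )

    @classmethod
    def all_coil(cls, n: int) -> "SecondaryStructureDirective":
        return cls(["coil"] * n, np.zeros(n, dtype=int))

    @classmethod
    def from_psipred(cls, path) -> "SecondaryStructureDirective":
        """Read a PSI-PRED vertical-format (.ss2-style) table.

        Expects columns: index, residue, state (C/H/E), then scores; the
        confidence is the max score scaled to 0-9.
        """
        states, confs = [], []
        code = {"C": "coil", "H": "helix", "E": "strand"}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 3 or parts[0].startswith("#"):
                    continue
                try:
                    int(parts[0])
                except ValueError:
                    continue
                states.append(code.get(parts[2], "coil"))
                if len(parts) >= 6:
                    confs.append(int(round(9 * max(float(x) for x in parts[3:6]))))
                else:
                    confs.append(9)
        return cls(states, np.array(confs))


@dataclass
class Conformer:
    """One backbone conformer: sequence, dihedrals and the CA trace."""

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    ca_coords: np.ndarray
    mode: str = "cooperative"
    mode_param: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.phi) == len(self.psi) == self.ca_coords.shape[0] == n):
            raise ValueError("sequence/dihedral/coordinate lengths differ")


@dataclass
class ConformerPool:
    """A set of conformers with per-conformer derived observables."""

    conformers: list
    sequence: str
    directive: SecondaryStructureDirective
    mode: str
    mode_param: float
    seed: int
    rho0: float = RHO0_DEFAULT

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def rg(self) -> np.ndarray:
        return np.array([radius_of_gyration(c) for c in self.conformers])

    @property
    def nu(self) -> np.ndarray:
        n = len(self.sequence)
        return np.array([rg_to_nu(r, n, self.rho0) for r in self.rg])

    def subset(self, indices) -> "ConformerPool":
        return ConformerPool(
            [self.conformers[i] for i in indices],
            self.sequence,
            self.directive,
            self.mode,
            self.mode_param,
            self.seed,
            self.rho0,
        )


def build_pool(
    sequence: str,
    directive: SecondaryStructureDirective | None = None,
    mode: str = "cooperative",
    mode_param: float = 0.0,
    n: int = 10_000,
    seed: int = 0,
    clash_radius: float = 4.0,
) -> ConformerPool:
    """Build ``n`` clash-free conformers for ``sequence``.

    ``mode_param`` is the beta-strand percentage for cooperative mode
    (one of 0, 12.5, 25, 37.5) or the Gaussian dispersion in degrees
    (115-140) for non-cooperative mode.  The build is deterministic for
    a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_res = len(sequence)
    if directive is None:
        directive = SecondaryStructureDirective.all_coil(n_res)
    if len(directive) != n_res:
        raise ValueError("directive length differs from sequence length")
    if mode == "cooperative":
        if not any(np.isclose(mode_param, f) for f in COOPERATIVE_FRACTIONS):
            raise ValueError(
                f"cooperative mode_param must be one of {COOPERATIVE_FRACTIONS} percent"
            )
    elif mode == "noncooperative":
        lo, hi = NONCOOP_DISPERSION_RANGE
        if not (lo <= mode_param <= hi):
            raise ValueError(f"non-cooperative dispersion must be in [{lo}, {hi}] degrees")
    else:
        raise ValueError("mode must be 'cooperative' or 'noncooperative'")

    rng = np.random.default_rng(seed)
    structured = directive.structured
    base_phi = np.zeros(n_res)
    base_psi = np.zeros(n_res)
    for i in range(n_res):
        if structured[i]:
            ref = _chain.HELIX_PHI_PSI if directive.states[i] == "helix" else _chain.STRAND_PHI_PSI
            base_phi[i], base_psi[i] = ref

    n_strand_conf = int(round(n * mode_param / 100.0)) if mode == "cooperative" else 0
    conformers = []
    for k in range(n):
        strand_conformer = k < n_strand_conf
        phi, psi = base_phi.copy(), base_psi.copy()
        free = ~structured
        n_free = int(free.sum())
        if strand_conformer:
            phi[free], psi[free] = _chain.STRAND_PHI_PSI
            resample = lambda r: _chain.STRAND_PHI_PSI  # noqa: E731
        elif mode == "noncooperative":
            draws = _chain.sample_noncoop(rng, n_free, mode_param)
            phi[free], psi[free] = draws[:, 0], draws[:, 1]
            resample = lambda r: tuple(_chain.sample_noncoop(r, 1, mode_param)[0])  # noqa: E731
        else:
            draws = _chain.sample_coil(rng, n_free)
            phi[free], psi[free] = draws[:, 0], draws[:, 1]
            resample = lambda r: tuple(_chain.sample_coil(r, 1)[0])  # noqa: E731
        phi, psi, ca = _chain.build_ca_trace(
            phi, psi, free, resample, rng, clash_radius=clash_radius
        )
        conformers.append(
            Conformer(sequence, phi, psi, ca, mode=mode, mode_param=mode_param)
        )
    return ConformerPool(conformers, sequence, directive, mode, mode_param, seed)


def radius_of_gyration(conformer) -> float:
    """Mass-uniform radius of gyration over the CA positions (A)."""
    coords = conformer.ca_coords if hasattr(conformer, "ca_coords") else np.asarray(conformer)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 1:
        raise ValueError("need at least one coordinate")
    center = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))


def rg_to_nu(rg: float, n_res: int, rho0: float = RHO0_DEFAULT) -> float:
    """Polymer scaling factor v solving Rg = rho0 * N**v."""
    if rg <= 0 or rho0 <= 0:
        raise ValueError("Rg and rho0 must be > 0")
    if n_res < 2:
        raise ValueError("N must be >= 2")
    return float(np.log(rg / rho0) / np.log(n_res))


def classify_dihedrals(phi: float, psi: float) -> str:
    """Coarse secondary-structure class of one (phi, psi) pair."""
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "helix"
    if -180.0 <= phi <= -90.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -160.0):
        return "strand"
    return "coil"


def predict_shifts(
    conformer: Conformer,
    uncertainty: float = 0.3,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Surrogate chemical-shift prediction for one conformer.

    Each shift is the residue-type random-coil value plus a fixed
    secondary-structure offset determined from the local dihedrals;
    deterministic.  If ``external`` is given (a table computed by a
    published predictor), it is passed through unchanged - the plugin
    seam for swapping in real predictors.
    """
    if external is not None:
        required = {"residue_index", "residue_type", "atom", "shift"}
        if not required.issubset(external.columns):
            raise ValueError(f"external shift table must have columns {sorted(required)}")
        return external
    rows = []
    for i, aa in enumerate(conformer.sequence):
        if aa not in RANDOM_COIL_SHIFTS:
            raise ValueError(f"unknown residue type {aa!r}")
        ss = classify_dihedrals(conformer.phi[i], conformer.psi[i])
        coil = RANDOM_COIL_SHIFTS[aa]
        for atom, base in zip(ATOMS, coil):
            if np.isnan(base):
                continue
            rows.append(
                {
                    "residue_index": i + 1,
                    "residue_type": aa,
                    "atom": atom,
                    "shift": base + SECONDARY_OFFSETS[ss][atom],
                    "uncertainty": uncertainty,
                }
            )
    return pd.DataFrame(rows)


def coil_reference_table(sequence: str, uncertainty: float = 0.3) -> pd.DataFrame:
    """Random-coil reference shifts for ``sequence`` (no offsets)."""
    rows = []
    for i, aa in enumerate(sequence):
        if aa not in RANDOM_COIL_SHIFTS:
            raise ValueError(f"unknown residue type {aa!r}")
        for atom, base in zip(ATOMS, RANDOM_COIL_SHIFTS[aa]):
            if np.isnan(base):
                continue
            rows.append(
                {
                    "residue_index": i + 1,
                    "residue_type": aa,
                    "atom": atom,
                    "shift": base,
                    "uncertainty": uncertainty,
                }
            )
    return pd.DataFrame(rows)


def secondary_shifts(observed: pd.DataFrame, coil_reference: pd.DataFrame) -> pd.DataFrame:
    """Secondary shifts delta-delta = observed - random-coil reference.

    Tables are joined on (residue_index, atom); unmatched observed rows
    are dropped.  Positive CA / negative CB indicates helix; the
    reverse indicates strand.
    """
    merged = observed.merge(
        coil_reference[["residue_index", "atom", "shift"]],
        on=["residue_index", "atom"],
        suffixes=("", "_coil"),
    )
    merged["delta_shift"] = merged["shift"] - merged["shift_coil"]
    cols = ["residue_index", "atom", "delta_shift"]
    if "residue_type" in merged.columns:
        cols.insert(1, "residue_type")
    return merged[cols]
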