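"""Backbone chain construction from (phi, psi) dihedral angles.

Builds N/CA/C backbone traces with ideal bond geometry (omega fixed at
180 deg) using the natural extension reference frame (NeRF) step, and
provides the dihedral libraries used by the pool generator:

* canonical helix / strand dihedrals for directive-structured regions,
* a statistical-coil library sampling broad basins around PPII/beta and
  alpha-R (a documented approximation to database coil sampling),
* a non-cooperative mode drawing both angles from a Gaussian centered
  at (phi, psi) = (-112.6, 123) deg with a tunable dispersion.

Only the C-alpha trace is retained downstream: every derived observable
(Rg, pair distances, bead scattering, surrogate shifts) needs backbone
geometry only.
"""

from __future__ import annotations

import numpy as np

# ideal backbone geometry (lengths in A, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-140.0, 135.0)
NONCOOP_CENTER = (-112.6, 123.0)

# coil basin mixture: (weight, phi0, psi0, sigma_phi, sigma_psi)
COIL_BASINS = (
    (0.35, -75.0, 145.0, 15.0, 20.0),   # PPII
    (0.35, -120.0, 130.0, 25.0, 20.0),  # beta / extended
    (0.20, -65.0, -40.0, 15.0, 15.0),   # alpha-R
    (0.05, 55.0, 45.0, 15.0, 15.0),     # alpha-L
    (0.05, -100.0, 0.0, 40.0, 40.0),    # bridge/other
)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c, given frame atoms a-b-c.

    ``length`` is |c-d|, ``angle_deg`` the b-c-d angle, ``torsion_deg``
    the a-b-c-d dihedral.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def sample_coil(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n (phi, psi) pairs from the coil basin mixture (degrees)."""
    weights = np.array([b[0] for b in COIL_BASINS])
    idx = rng.choice(len(COIL_BASINS), size=n, p=weights / weights.sum())
    out = np.empty((n, 2))
    for i, k in enumerate(idx):
        _, p0, s0, sp, ss = COIL_BASINS[k]
        out[i, 0] = rng.normal(p0, sp)
        out[i, 1] = rng.normal(s0, ss)
    return _wrap(out)


def sample_noncoop(rng: np.random.Generator, n: int, dispersion: float) -> np.ndarray:
    """Draw n (phi, psi) pairs from a Gaussian about (-112.6, 123) deg.

    ``dispersion`` is the Gaussian sigma in degrees applied to both
    angles (the interpretation of the 115-140 dispersion range).
    """
    out = np.empty((n, 2))
    out[:, 0] = rng.normal(NONCOOP_CENTER[0], dispersion, size=n)
    out[:, 1] = rng.normal(NONCOOP_CENTER[1], dispersion, size=n)
    return _wrap(out)


def _wrap(angles: np.ndarray) -> np.ndarray:
    return (angles + 180.0) % 360.0 - 180.0


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Build an (n_res, 3, 3) array of N/CA/C coordinates from dihedrals.

    phi[0] and psi[-1] are not used by the geometry (chain termini).
    """
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi lengths differ")
    coords = np.zeros((n_res, 3, 3))
    # residue 0 in a canonical local frame
    coords[0, 0] = [0.0, 0.0, 0.0]                     # N
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]               # CA
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        _extend_residue(coords, i, psi[i - 1], phi[i])
    return coords


def _extend_residue(coords: np.ndarray, i: int, psi_prev: float, phi_i: float) -> None:
    """Place N/CA/C of residue i given residue i-1 and (psi_{i-1}, phi_i)."""
    n_prev, ca_prev, c_prev = coords[i - 1]
    coords[i, 0] = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
    coords[i, 1] = place_atom(ca_prev, c_prev, coords[i, 0], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
    coords[i, 2] = place_atom(c_prev, coords[i, 0], coords[i, 1], BOND_CA_C, ANGLE_N_CA_C, phi_i)


class ChainBuildError(RuntimeError):
    """Raised when a clash-free chain cannot be built within the retry budget."""


def build_ca_trace(
    phi: np.ndarray,
    psi: np.ndarray,
    resample_mask: np.ndarray,
    resample_fn,
    rng: np.random.Generator,
    clash_radius: float = 4.0,
    clash_sep: int = 3,
    per_residue_retries: int = 50,
    restarts: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a clash-free CA trace, backtracking on steric clashes.

    A clash is two CA atoms >= ``clash_sep`` residues apart closer than
    ``clash_radius`` A.  When placing residue i produces a clash, the
    dihedrals of preceding movable residues (``resample_mask`` True)
    are redrawn via ``resample_fn(rng)`` and the chain rebuilt from the
    earliest redrawn residue; repeated clashes at the same residue
    deepen the backtrack window so the builder can escape compact
    dead ends.  Exhausting ``per_residue_retries`` at one residue
    restarts the conformer; exhausting ``restarts`` raises
    :class:`ChainBuildError`.

    Returns (phi, psi, ca_coords) actually built.
    """
    n_res = len(phi)
    for _ in range(restarts):
        cur_phi = np.array(phi, dtype=float)
        cur_psi = np.array(psi, dtype=float)
        coords = np.zeros((n_res, 3, 3))
        coords[0, 0] = [0.0, 0.0, 0.0]
        coords[0, 1] = [BOND_N_CA, 0.0, 0.0]
        ang = np.deg2rad(ANGLE_N_CA_C)
        coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        retries = np.zeros(n_res, dtype=int)
        i = 1
        failed = False
        while i < n_res:
            _extend_residue(coords, i, cur_psi[i - 1], cur_phi[i])
            ca = coords[i, 1]
            if i >= clash_sep:
                d2 = np.sum((coords[: i - clash_sep + 1, 1] - ca) ** 2, axis=1)
                if np.any(d2 < clash_radius**2):
                    retries[i] += 1
                    if retries[i] > per_residue_retries:
                        failed = True
                        break
                    # redraw a window of movable residues before the clash;
                    # the window deepens with repeated failures here
                    depth = 1 + retries[i] // 8
                    movable = [j for j in range(max(1, i - depth - 2), i) if resample_mask[j]]
                    if not movable:
                        failed = True  # nothing movable before the clash
                        break
                    for j in movable:
                        cur_phi[j], cur_psi[j] = resample_fn(rng)
                    i = movable[0]  # rebuild from the earliest redrawn residue
                    continue
            i += 1
        if not failed:
            return cur_phi, cur_psi, coords[:, 1].copy()
    raise ChainBuildError(
        f"could not build a clash-free {n_res}-residue chain after {restarts} restarts "
        f"({per_residue_retries} per-residue retries each)"
    )
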