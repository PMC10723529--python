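"""Synthetic data generators for every input class of the pipeline.

Each generator is bit-reproducible from a :class:`SimulationSpec`
(kind, parameters, seed) and can emit that spec as a JSON sidecar so
any artifact can be regenerated exactly.

Reference conditions
--------------------
``P14ARF_DETECTED_PARAMS`` holds the broad-peak-with-correlation-length
parameters of the NPM1-matched (p14ARF-detected) condensate curve:
exponents m0 = 1/0.66 and m1 = 1/0.35 (scaling exponents 0.66 and
0.35), peak at q0 = 2*pi/180 1/A (d-spacing 180 A), correlation lengths
xi0 = 85 A and Xi1 = 160 A.  The amplitudes C0 = 1, C1 = 10 and
background B = 0.01 are not constrained by published values; they are
fixed here once so the low-q correlation term dominates the decade
below the pseudo-Bragg peak, as in the measured condensate curves.
``NPM1_DETECTED_PARAMS`` is the correlation-length model for the
p14ARF-matched (NPM1-detected) curve with a ~60 A correlation length.

The default q-range, 0.004-0.45 1/A, is the instrument range of the
extended-q small-angle neutron spectrometer the curves emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .curves import ScatteringCurve
from .sans import (
    BroadPeakParams,
    CorrLengthParams,
    eval_broad_peak,
    eval_broad_peak_corrlen,
    eval_corrlen,
)
from .bayes import ScalingObservation, ShiftObservation, ObservationSet, pool_shift_matrix
from .lattice import LatticeConfig, ensemble_average_curve
from .nmr import (
    DispersionProfile,
    RelaxationSeries,
    eval_fast_exchange,
    eval_flat,
    eval_slow_exchange,
)

__all__ = [
    "SimulationSpec",
    "P14ARF_DETECTED_PARAMS",
    "NPM1_DETECTED_PARAMS",
    "SANS_Q_RANGE",
    "gen_sans",
    "gen_spanning_pool",
    "gen_lattice_curve",
    "gen_observations",
    "gen_frap_movie",
    "gen_cell_image",
    "gen_cpmg",
    "gen_relaxation",
]

SANS_Q_RANGE = (0.004, 0.45)  # 1/A

P14ARF_DETECTED_PARAMS = BroadPeakParams(
    C0=1.0,
    xi0=85.0,
    q0=2.0 * np.pi / 180.0,
    m0=1.0 / 0.66,
    C1=10.0,
    Xi1=160.0,
    m1=1.0 / 0.35,
    B=0.01,
)

NPM1_DETECTED_PARAMS = CorrLengthParams(C0=1.0, xi0=60.0, m0=2.0, B=0.01)


@dataclass
class SimulationSpec:
    """Provenance record of one synthetic artifact: kind, parameters, seed."""

    kind: str
    params: dict
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SimulationSpec":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(**payload)

    def generate(self):
        """Regenerate the artifact exactly from this spec.

        Pool-dependent kinds (lattice_curve, conformer_obs) carry the
        pool build arguments under params["pool_build"] so the pool
        itself is rebuilt deterministically.
        """
        if self.kind in ("lattice_curve", "conformer_obs"):
            from .conformers import build_pool

            params = dict(self.params)
            pool = build_pool(**params.pop("pool_build"))
            if self.kind == "lattice_curve":
                config = LatticeConfig(**params.pop("config"))
                return gen_lattice_curve(pool, config, seed=self.seed, **params)
            return gen_observations(pool, seed=self.seed, **params)
        fn = {
            "sans_curve": gen_sans,
            "frap_movie": gen_frap_movie,
            "cell_image": gen_cell_image,
            "cpmg_profile": gen_cpmg,
            "relaxation_series": gen_relaxation,
        }[self.kind]
        return fn(seed=self.seed, **self.params)


_SANS_MODELS = {
    "corrlen": (eval_corrlen, CorrLengthParams),
    "broadpeak": (eval_broad_peak, BroadPeakParams),
    "broadpeak-cl": (eval_broad_peak_corrlen, BroadPeakParams),
}


def gen_sans(
    model_id: str = "broadpeak-cl",
    params: dict | None = None,
    n_points: int = 100,
    qmin: float = SANS_Q_RANGE[0],
    qmax: float = SANS_Q_RANGE[1],
    rel_noise: float = 0.01,
    seed: int = 0,
) -> tuple[ScatteringCurve, SimulationSpec]:
    """Synthetic SANS curve: model evaluation plus relative Gaussian noise.

    ``params`` is a parameter dict for the chosen model (defaults to the
    p14ARF-detected reference condition for the peak models and the
    NPM1-detected condition for the correlation length model).  The
    sigma column is set to rel_noise * I(model).
    """
    evalf, cls = _SANS_MODELS[model_id]
    if params is None:
        ref = NPM1_DETECTED_PARAMS if model_id == "corrlen" else P14ARF_DETECTED_PARAMS
        params = {k: v for k, v in asdict(ref).items() if v is not None}
        if model_id == "broadpeak":
            params["q1"] = params["q0"] / 2.0
    p = cls(**params)
    q = np.geomspace(qmin, qmax, n_points)
    ideal = evalf(p, q)
    sigma = np.abs(rel_noise) * ideal
    rng = np.random.default_rng(seed)
    intensity = ideal + rng.normal(0.0, 1.0, size=q.size) * sigma if rel_noise > 0 else ideal.copy()
    if rel_noise == 0:
        sigma = np.full_like(q, max(float(ideal.max()) * 1e-4, 1e-12))
    curve = ScatteringCurve(q, intensity, sigma, label=f"synthetic {model_id}")
    spec = SimulationSpec(
        "sans_curve",
        {
            "model_id": model_id,
            "params": params,
            "n_points": n_points,
            "qmin": qmin,
            "qmax": qmax,
            "rel_noise": rel_noise,
        },
        seed,
    )
    return curve, spec


def gen_lattice_curve(
    pool,
    config: LatticeConfig,
    n_rep: int = 8,
    n_points: int = 100,
    qmin: float = SANS_Q_RANGE[0],
    qmax: float = SANS_Q_RANGE[1],
    rel_noise: float = 0.0,
    seed: int = 0,
    bin_width: float = 1.0,
) -> ScatteringCurve:
    """Ensemble-average lattice-assembly curve with optional noise.

    Uses the same per-configuration seed protocol as the grid search, so
    a target generated here is exactly reproduced by the search at the
    generating configuration.
    """
    q = np.geomspace(qmin, qmax, n_points)
    curve = ensemble_average_curve(pool, config, q, n_rep=n_rep, seed=seed, bin_width=bin_width)
    sigma = np.abs(curve.intensity) * (rel_noise if rel_noise > 0 else 0.01)
    intensity = curve.intensity
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, 1.0, size=q.size) * sigma
    return ScatteringCurve(q, intensity, sigma, label=curve.label)


def gen_observations(
    pool,
    true_weights=None,
    shift_keys: list | None = None,
    eps_cs: float = 0.1,
    eps_v: float = 0.296,
    rel_alpha: bool = True,
    noise: bool = True,
    seed: int = 0,
) -> ObservationSet:
    """Observations drawn from a weighted ensemble's own averages.

    The scaling-factor and chemical-shift observations are the
    ensemble averages under ``true_weights`` (uniform by default) plus
    Gaussian noise at the stated errors (none when ``noise=False``).
    ``shift_keys`` is a list of (residue_index, atom) pairs; default is
    CA of every 5th residue.
    """
    n = len(pool)
    w = np.full(n, 1.0 / n) if true_weights is None else np.asarray(true_weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    if shift_keys is None:
        n_res = len(pool.sequence)
        shift_keys = [(i, "CA") for i in range(1, n_res + 1, 5)]
    shift_obs = []
    if shift_keys:
        probe = [ShiftObservation(r, a, 0.0, eps_cs) for r, a in shift_keys]
        mat = pool_shift_matrix(pool, probe)
        avg = w @ mat
        for (r, a), mu in zip(shift_keys, avg):
            val = float(mu + rng.normal(0.0, eps_cs)) if noise else float(mu)
            shift_obs.append(ShiftObservation(r, a, val, eps_cs))
    nu_avg = float(w @ pool.nu)
    nu_val = float(nu_avg + rng.normal(0.0, eps_v)) if noise else nu_avg
    scaling = ScalingObservation(min(max(nu_val, 1e-3), 1.199), eps_v)
    return ObservationSet(shifts=shift_obs, scaling=scaling)


def gen_spanning_pool(
    n: int = 2000,
    n_res: int = 130,
    sequence: str | None = None,
    seed: int = 0,
):
    """A statistical-coil pool spanning polymer scaling factors ~0.5-0.8.

    Emulates the systematic variation of secondary-structure propensity
    across starting pools - from compact near-random sampling to
    partially strand-structured chains - by concatenating equal
    subpools: non-cooperative sampling at dispersion 115 deg, the coil
    library, and directives with the first 20/40/60 % of residues built
    as beta strand.  The resulting per-conformer scaling factors cover
    the theta-to-extended range continuously.
    """
    from .conformers import SecondaryStructureDirective, build_pool, ConformerPool

    if sequence is None:
        sequence = ("GASPL" * ((n_res + 4) // 5))[:n_res]
    n_res = len(sequence)
    rungs = [
        ("noncooperative", 115.0, None),
        ("cooperative", 0.0, None),
        ("cooperative", 0.0, 0.2),
        ("cooperative", 0.0, 0.4),
        ("cooperative", 0.0, 0.6),
    ]
    per = [n // len(rungs)] * len(rungs)
    per[-1] += n - sum(per)
    conformers = []
    for k, ((mode, param, strand_frac), m) in enumerate(zip(rungs, per)):
        if strand_frac is None:
            directive = None
        else:
            ns = int(strand_frac * n_res)
            states = ["strand"] * ns + ["coil"] * (n_res - ns)
            conf = np.where(np.array(states) == "strand", 9, 0)
            directive = SecondaryStructureDirective(states, conf)
        sub = build_pool(
            sequence, directive, mode=mode, mode_param=param, n=m, seed=seed * 10 + k
        )
        conformers.extend(sub.conformers)
    return ConformerPool(
        conformers,
        sequence,
        SecondaryStructureDirective.all_coil(n_res),
        mode="mixture",
        mode_param=0.0,
        seed=seed,
    )


# ------------------------------------------------------------- FRAP movies


def _diffuse_dct(field: np.ndarray, d_coeff: float, dt: float, dx: float) -> np.ndarray:
    """Exact heat-equation step on a reflecting grid via the cosine transform."""
    from scipy.fft import dctn, idctn

    ny, nx = field.shape
    ky = np.pi * np.arange(ny) / (ny * dx)
    kx = np.pi * np.arange(nx) / (nx * dx)
    damp = np.exp(-d_coeff * dt * (ky[:, None] ** 2 + kx[None, :] ** 2))
    return idctn(dctn(field, norm="ortho") * damp, norm="ortho")


def gen_frap_movie(
    d_coeff: float = 1.0,
    n_pixels: int = 256,
    pixel_size: float = 0.1,
    field_radius: float | None = None,
    bleach_depth: float = 1.0,
    r_e: float = 1.2,
    r_n: float = 1.0,
    photofade_rate: float = 0.002,
    background: float = 10.0,
    gain: float = 200.0,
    read_noise: float = 2.0,
    noise: bool = True,
    n_pre: int = 12,
    n_post: int = 120,
    frame_interval: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict, SimulationSpec]:
    """Pure-diffusion bleach-recovery movie with background and photofading.

    A uniform fluorophore field filling the reflecting grid (the
    interior of a closed droplet; restrict to a disk of radius
    ``field_radius`` um to emulate a droplet smaller than the view)
    evolves by 2D diffusion at ``d_coeff`` um^2/s (exact spectral
    propagation per frame).  At the
    bleach frame the concentration is multiplied by
    exp(-K exp(-2 r^2 / r_e^2)) (a Gaussian laser profile of effective
    radius ``r_e`` um and depth K = ``bleach_depth``); global
    exponential photofading, an additive background and Poisson-Gaussian
    camera noise complete the observation model.

    Returns (movie [frames, y, x], sidecar meta dict, SimulationSpec).
    The frame interval defaults to roughly one sixth of the expected
    recovery half-time so the recovery is well sampled for any D.
    """
    if frame_interval is None:
        expected_t_half = (r_e**2 + r_n**2) / (8.0 * max(d_coeff, 1e-6))
        frame_interval = float(np.clip(expected_t_half / 6.0, 1e-3, 5.0))
    rng = np.random.default_rng(seed)
    dx = pixel_size
    c0 = n_pixels // 2
    yy, xx = np.mgrid[0:n_pixels, 0:n_pixels]
    r2 = ((xx - c0) ** 2 + (yy - c0) ** 2) * dx**2
    if field_radius is None:
        conc = np.ones((n_pixels, n_pixels))
    else:
        conc = (r2 <= field_radius**2).astype(float)
    bleach_profile = np.exp(-bleach_depth * np.exp(-2.0 * r2 / r_e**2))

    frames = []
    t = 0.0
    n_frames = n_pre + n_post
    for k in range(n_frames):
        if k > 0:
            if d_coeff > 0:
                conc = _diffuse_dct(conc, d_coeff, frame_interval, dx)
            t += frame_interval
        if k == n_pre:
            # brief bleach pulse immediately before this frame is recorded
            conc = conc * bleach_profile
        fade = np.exp(-photofade_rate * t)
        signal = gain * conc * fade + background
        if noise:
            frame = rng.poisson(np.clip(signal - background, 0.0, None)).astype(float)
            frame += background + rng.normal(0.0, read_noise, size=signal.shape)
        else:
            frame = signal
        frames.append(frame.astype(np.float32))
    movie = np.stack(frames)

    r_field_px = (field_radius / dx) if field_radius is not None else n_pixels / 2.0
    ref_off = int(0.6 * r_field_px)
    meta = {
        "bleach_index": n_pre,
        "frame_interval": frame_interval,
        "pixel_size": pixel_size,
        "r_nominal": r_n,
        "roi_center": (c0, c0),
        # camera offset, as measured from a dark frame
        "background_value": background,
        "reference_center": (c0 + ref_off, c0),
        "field_center": (c0, c0),
        "field_radius_px": 0.9 * r_field_px,
        "true_d": d_coeff,
        "true_r_e": r_e,
    }
    spec = SimulationSpec(
        "frap_movie",
        {
            "d_coeff": d_coeff,
            "n_pixels": n_pixels,
            "pixel_size": pixel_size,
            "field_radius": field_radius,
            "bleach_depth": bleach_depth,
            "r_e": r_e,
            "r_n": r_n,
            "photofade_rate": photofade_rate,
            "background": background,
            "gain": gain,
            "read_noise": read_noise,
            "noise": noise,
            "n_pre": n_pre,
            "n_post": n_post,
            "frame_interval": frame_interval,
        },
        seed,
    )
    return movie, meta, spec


# ------------------------------------------------------------ cell images


def gen_cell_image(
    n_nuclei: int = 3,
    nucleoli_per_nucleus: int = 2,
    shape: tuple = (256, 256),
    tiers: tuple = (10.0, 60.0, 150.0),
    nucleus_radius: int = 34,
    nucleolus_radius: int = 8,
    noise: bool = True,
    read_noise: float = 2.0,
    seed: int = 0,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, dict, SimulationSpec]:
    """Synthetic nucleolar field: three intensity tiers plus camera noise.

    Nuclei are dim disks on a dark background; nucleoli are bright
    disks inside each nucleus (background < nucleus < nucleolus, the
    ``tiers``), placed at evenly spaced jittered angles so objects stay
    separated.  Poisson noise with unit gain plus Gaussian read noise;
    ``noise_seed`` varies the noise realization independently of the
    geometry (defaults to the geometry seed).
    Returns (image, ground-truth masks dict, SimulationSpec).
    """
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng(seed if noise_seed is None else noise_seed)
    ny, nx = shape
    img = np.full(shape, tiers[0], dtype=float)
    nuc_mask = np.zeros(shape, dtype=np.int32)
    no_mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:ny, 0:nx]

    # non-overlapping nucleus centers on a jittered grid
    margin = nucleus_radius + 6
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    cxs = np.linspace(margin, nx - margin, n_cols)
    cys = np.linspace(margin, ny - margin, n_rows)
    centers = [(cx, cy) for cy in cys for cx in cxs][:n_nuclei]
    no_id = 0
    for nid, (cx, cy) in enumerate(centers, start=1):
        cx += rng.uniform(-4, 4)
        cy += rng.uniform(-4, 4)
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_radius**2
        img[disk] = tiers[1]
        nuc_mask[disk] = nid
        base_ang = rng.uniform(0, 2 * np.pi)
        for k in range(nucleoli_per_nucleus):
            # evenly spaced angles with a small jitter keep nucleoli apart
            ang = base_ang + 2 * np.pi * k / max(nucleoli_per_nucleus, 1)
            ang += rng.uniform(-0.25, 0.25)
            rad = rng.uniform(0.38, 0.5) * nucleus_radius
            ox, oy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            nd = (xx - ox) ** 2 + (yy - oy) ** 2 <= nucleolus_radius**2
            no_id += 1
            img[nd] = tiers[2]
            no_mask[nd] = no_id
    if noise:
        img = noise_rng.poisson(img).astype(float) + noise_rng.normal(
            0.0, read_noise, size=shape
        )
    truth = {"nuclear": nuc_mask, "nucleolar": no_mask}
    spec = SimulationSpec(
        "cell_image",
        {
            "n_nuclei": n_nuclei,
            "nucleoli_per_nucleus": nucleoli_per_nucleus,
            "shape": list(shape),
            "tiers": list(tiers),
            "nucleus_radius": nucleus_radius,
            "nucleolus_radius": nucleolus_radius,
            "noise": noise,
            "read_noise": read_noise,
            "noise_seed": noise_seed,
        },
        seed,
    )
    return img, truth, spec


# ------------------------------------------------------------------- NMR


def gen_cpmg(
    model: str = "fast",
    params: dict | None = None,
    x=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DispersionProfile, SimulationSpec]:
    """Synthetic CPMG dispersion profile for one of the three models."""
    if x is None:
        x = np.geomspace(1e-4, 2e-2, 14)
    x = np.asarray(x, dtype=float)
    if params is None:
        params = {
            "flat": {"c": 12.0},
            "fast": {"r2o": 10.0, "kex": 2000.0, "phi": 5.0e4},
            "slow": {"r2o": 10.0, "kex": 8.0, "dw": 900.0},
        }[model]
    if model == "flat":
        y = eval_flat(x, **params)
    elif model == "fast":
        y = eval_fast_exchange(x, **params)
    elif model == "slow":
        y = eval_slow_exchange(x, **params)
    else:
        raise ValueError(model)
    rng = np.random.default_rng(seed)
    sigma = np.full(x.size, noise_sd if noise_sd > 0 else max(float(np.ptp(y)), 1.0) * 0.01)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    profile = DispersionProfile(x, y, sigma)
    spec = SimulationSpec(
        "cpmg_profile",
        {"model": model, "params": params, "x": list(map(float, x)), "noise_sd": noise_sd},
        seed,
    )
    return profile, spec


def gen_relaxation(
    rate: float = 5.0,
    i0: float = 1.0,
    delays=None,
    rel_noise: float = 0.0,
    seed: int = 0,
) -> tuple[RelaxationSeries, SimulationSpec]:
    """Synthetic single-exponential relaxation decay series."""
    if delays is None:
        delays = np.linspace(0.0, 3.0 / max(rate, 1e-6), 8)
    delays = np.asarray(delays, dtype=float)
    y = i0 * np.exp(-rate * delays)
    rng = np.random.default_rng(seed)
    if rel_noise > 0:
        y = y + rng.normal(0.0, rel_noise * i0, size=delays.size)
    series = RelaxationSeries(delays, y)
    spec = SimulationSpec(
        "relaxation_series",
        {"rate": rate, "i0": i0, "delays": list(map(float, delays)), "rel_noise": rel_noise},
        seed,
    )
    return series, spec
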