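"""Small-angle scattering models for condensed-phase protein assemblies.

Three empirical models describe the reduced SANS curves measured on
protein condensates under contrast variation:

* a **broad peak model** with two peak terms,
  ``I(q) = C0/(1 + (xi0|q - q0|)^m0) + C1/(1 + (Xi1|q - q1|)^m1) + B``,
  used when both a local and a long-range correlation peak are present;
* a **broad peak model with a correlation length term**,
  ``I(q) = C0/(1 + (xi0|q - q0|)^m0) + C1/(1 + (Xi1 q)^m1) + B``,
  describing a pseudo-Bragg peak riding on a low-q correlation decay
  (the form that fits curves where only the ordered species scatters);
* a **correlation length model**, ``I(q) = C0/(1 + (xi0 q)^m0) + B``,
  for a disordered chain fluid with no peak.

The peak position q0 maps to a real-space d-spacing d0 = 2*pi/q0 (the
characteristic distance between scattering inhomogeneities) and the
high-q exponent m0 maps to a polymer scaling exponent v0 = 1/m0
(v ~ 0.33 collapsed, 0.5 theta, ~0.6 expanded coil, -> 1 rod).

The absolute-value bars in the peak terms keep the exponent real for
non-integer m; printed renderings of such models often omit them.

Fitting is weighted least squares in linear intensity (curves carry
absolute-scaled intensities with per-point uncertainties); a log-space
mode is available as a diagnostic.  Initialization is deterministic and
a small seeded multi-start guards against local minima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields as dc_fields

import numpy as np
from scipy.optimize import least_squares

from .curves import ScatteringCurve

__all__ = [
    "BroadPeakParams",
    "CorrLengthParams",
    "FitResult",
    "FitConvergenceError",
    "eval_broad_peak",
    "eval_broad_peak_corrlen",
    "eval_corrlen",
    "fit_curve",
    "d_spacing",
    "scaling_exponent_from_m",
]

MODEL_IDS = ("corrlen", "broadpeak", "broadpeak-cl")


class FitConvergenceError(RuntimeError):
    """Raised when the optimizer fails; no parameters are reported."""


@dataclass
class BroadPeakParams:
    """Parameters of the broad peak models.

    q1 is only meaningful for the two-peak variant ("broadpeak"); the
    peak-plus-correlation-length variant ("broadpeak-cl") ignores it.
    Lengths xi0, Xi1 in A; q0, q1 in 1/A; m0, m1 dimensionless.
    """

    C0: float
    xi0: float
    q0: float
    m0: float
    C1: float
    Xi1: float
    m1: float
    B: float
    q1: float | None = None

    def validate(self) -> None:
        vals = [self.C0, self.xi0, self.q0, self.m0, self.C1, self.Xi1, self.m1, self.B]
        if self.q1 is not None:
            vals.append(self.q1)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite model parameter")
        if min(self.C0, self.C1, self.xi0, self.Xi1, self.B) < 0:
            raise ValueError("amplitudes, correlation lengths and background must be >= 0")
        if self.m0 <= 0 or self.m1 <= 0:
            raise ValueError("exponents m0, m1 must be > 0")


@dataclass
class CorrLengthParams:
    """Parameters of the correlation length model."""

    C0: float
    xi0: float
    m0: float
    B: float

    def validate(self) -> None:
        vals = [self.C0, self.xi0, self.m0, self.B]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite model parameter")
        if self.C0 < 0 or self.xi0 < 0 or self.B < 0:
            raise ValueError("C0, xi0 and B must be >= 0")
        if self.m0 <= 0:
            raise ValueError("m0 must be > 0")


@dataclass
class FitResult:
    """A converged weighted least-squares fit of one scattering model."""

    params: BroadPeakParams | CorrLengthParams
    chi2_reduced: float
    uncertainties: dict
    n_points: int
    model_id: str

    def to_json(self, path=None) -> str:
        payload = {
            "model_id": self.model_id,
            "params": {k: v for k, v in asdict(self.params).items() if v is not None},
            "uncertainties": self.uncertainties,
            "chi2_reduced": self.chi2_reduced,
            "n_points": self.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(~np.isfinite(q)) or np.any(q <= 0):
        raise ValueError("q grid must be finite and > 0")
    return q


def eval_broad_peak(params: BroadPeakParams, q) -> np.ndarray:
    """Two-peak broad peak model intensity on a q grid."""
    params.validate()
    if params.q1 is None:
        raise ValueError("two-peak model requires q1")
    q = _check_q(q)
    t0 = params.C0 / (1.0 + (params.xi0 * np.abs(q - params.q0)) ** params.m0)
    t1 = params.C1 / (1.0 + (params.Xi1 * np.abs(q - params.q1)) ** params.m1)
    return t0 + t1 + params.B


def eval_broad_peak_corrlen(params: BroadPeakParams, q) -> np.ndarray:
    """Broad peak plus correlation-length-term model intensity."""
    params.validate()
    q = _check_q(q)
    t0 = params.C0 / (1.0 + (params.xi0 * np.abs(q - params.q0)) ** params.m0)
    t1 = params.C1 / (1.0 + (params.Xi1 * q) ** params.m1)
    return t0 + t1 + params.B


def eval_corrlen(params: CorrLengthParams, q) -> np.ndarray:
    """Correlation length model intensity."""
    params.validate()
    q = _check_q(q)
    return params.C0 / (1.0 + (params.xi0 * q) ** params.m0) + params.B


def d_spacing(q0: float) -> float:
    """Real-space d-spacing d0 = 2*pi/q0 of a peak at q0 (> 0).

    The map is an involution: d_spacing(d_spacing(x)) == x.
    """
    if not np.isfinite(q0) or q0 <= 0:
        raise ValueError("q0 must be finite and > 0")
    return 2.0 * np.pi / q0


def scaling_exponent_from_m(m: float) -> float:
    """Polymer scaling exponent v = 1/m from a fitted model exponent m > 0."""
    if not np.isfinite(m) or m <= 0:
        raise ValueError("m must be finite and > 0")
    return 1.0 / m


# ---------------------------------------------------------------- fitting

_PARAM_ORDER = {
    "corrlen": ["C0", "xi0", "m0", "B"],
    "broadpeak-cl": ["C0", "xi0", "q0", "m0", "C1", "Xi1", "m1", "B"],
    "broadpeak": ["C0", "xi0", "q0", "m0", "C1", "Xi1", "m1", "B", "q1"],
}


def _vector_to_params(model_id: str, x: np.ndarray):
    names = _PARAM_ORDER[model_id]
    kw = dict(zip(names, x))
    if model_id == "corrlen":
        return CorrLengthParams(**kw)
    return BroadPeakParams(**kw)


def _model_eval(model_id: str, params, q):
    if model_id == "corrlen":
        return eval_corrlen(params, q)
    if model_id == "broadpeak-cl":
        return eval_broad_peak_corrlen(params, q)
    return eval_broad_peak(params, q)


def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        out[i] = np.median(y[lo:hi])
    return out


def _default_init(curve: ScatteringCurve, model_id: str) -> dict:
    """Deterministic initial guesses.

    q0 starts at the argmax of I minus a running median (a crude peak
    detector); correlation lengths start at 2*pi / (q-range width);
    exponents start at 2; the background at the minimum intensity.
    """
    q, I = curve.q, curve.intensity
    width = q[-1] - q[0]
    xi_init = 2.0 * np.pi / width
    B0 = max(float(np.min(I)), 0.0)
    # peak detector: ratio to a running median, evaluated away from the
    # edges where the centered median window is truncated
    win = max(7, I.size // 8)
    med = _running_median(I, win)
    ratio = I / np.clip(med, 1e-300, None)
    interior = slice(win // 2, max(I.size - win // 2, win // 2 + 1))
    ipk = int(np.argmax(ratio[interior])) + (win // 2)
    q0_init = float(np.clip(q[ipk], q[0], q[-1]))
    amp = max(float(np.max(I) - B0), 1e-12)
    init = {"C0": amp, "xi0": xi_init, "m0": 2.0, "B": max(B0, 1e-12)}
    if model_id in ("broadpeak", "broadpeak-cl"):
        init.update(
            q0=q0_init,
            C1=max(float(I[0] - B0), 1e-12),
            Xi1=xi_init,
            m1=2.0,
        )
    if model_id == "broadpeak":
        init["q1"] = max(q0_init / 2.0, q[0])
    return init


def _default_bounds(curve: ScatteringCurve, model_id: str) -> dict:
    q = curve.q
    Imax = float(np.max(curve.intensity))
    big = 100.0 * max(Imax, 1.0)
    bounds = {
        "C0": (0.0, big),
        "xi0": (1e-3, 1e5),
        "m0": (0.2, 12.0),
        "B": (0.0, big),
    }
    if model_id in ("broadpeak", "broadpeak-cl"):
        bounds.update(
            q0=(q[0], q[-1]),
            C1=(0.0, big),
            Xi1=(1e-3, 1e5),
            m1=(0.2, 12.0),
        )
    if model_id == "broadpeak":
        bounds["q1"] = (q[0], q[-1])
    return bounds


def fit_curve(
    curve: ScatteringCurve,
    model_id: str,
    init: dict | None = None,
    bounds: dict | None = None,
    qmin: float | None = None,
    qmax: float | None = None,
    log_space: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit one of the three scattering models by weighted least squares.

    Minimizes sum(((I_obs - I_model)/sigma)^2) over the stored q-range
    (optionally trimmed to [qmin, qmax]).  ``n_starts`` seeded restarts
    perturb the initial guess multiplicatively and the lowest-chi^2
    converged solution is kept.  Raises :class:`FitConvergenceError` if
    no restart converges - a failed fit is never silently reported.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    curve = curve.trim(qmin, qmax)
    names = _PARAM_ORDER[model_id]
    n_free = len(names)
    if len(curve) < 3 * n_free:
        raise ValueError(
            f"need at least {3 * n_free} points to fit {n_free} parameters, got {len(curve)}"
        )
    if curve.sigma is None:
        sigma = np.full(len(curve), max(np.abs(curve.intensity).max(), 1.0) * 1e-2)
    else:
        sigma = curve.sigma.copy()
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0 wherever used in fitting")

    full_init = _default_init(curve, model_id)
    if init:
        full_init.update(init)
    full_bounds = _default_bounds(curve, model_id)
    if bounds:
        full_bounds.update(bounds)
    x0 = np.array([full_init[n] for n in names], dtype=float)
    lo = np.array([full_bounds[n][0] for n in names], dtype=float)
    hi = np.array([full_bounds[n][1] for n in names], dtype=float)
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    q, I = curve.q, curve.intensity

    def residuals(x):
        params = _vector_to_params(model_id, x)
        model = _model_eval(model_id, params, q)
        if log_space:
            eps = 1e-300
            return (np.log(np.clip(I, eps, None)) - np.log(np.clip(model, eps, None))) * I / sigma
        return (I - model) / sigma

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            guess = x0
        else:
            factor = np.exp(rng.normal(0.0, 0.4, size=x0.size))
            guess = np.clip(x0 * factor, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(residuals, guess, bounds=(lo, hi), method="trf", max_nfev=20000)
        except ValueError:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitConvergenceError(f"{model_id} fit did not converge from any restart")

    dof = max(len(curve) - n_free, 1)
    chi2_red = float(2.0 * best.cost / dof)
    # parameter uncertainties from the Gauss-Newton covariance at the optimum
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (2.0 * best.cost / dof)
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        perr = np.full(n_free, np.nan)
    params = _vector_to_params(model_id, best.x)
    params.validate()
    return FitResult(
        params=params,
        chi2_reduced=chi2_red,
        uncertainties=dict(zip(names, (float(e) for e in perr))),
        n_points=len(curve),
        model_id=model_id,
    )
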