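"""Reduced 1D scattering curves and their plain-text I/O.

A :class:`ScatteringCurve` holds a momentum-transfer grid q (1/A), absolute-scaled
intensities I(q) and 1-sigma uncertainties, plus a free-text label recording the
contrast condition (e.g. "NPM1-matched, p14ARF detected").  It is the unit
consumed and produced by every scattering operation in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScatteringCurve:
    """A reduced small-angle scattering curve.

    Parameters
    ----------
    q : array
        Momentum transfer in 1/A, strictly increasing and positive.
    intensity : array
        Absolute-scaled I(q).
    sigma : array, optional
        1-sigma uncertainty per point.  Required for weighted fitting.
    label : str
        Free text describing the contrast condition.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1:
            raise ValueError("q must be one-dimensional")
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity lengths differ")
        if np.any(~np.isfinite(self.q)) or np.any(self.q <= 0):
            raise ValueError("q must be finite and > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.size != self.q.size:
                raise ValueError("sigma length differs from q")

    def __len__(self) -> int:
        return self.q.size

    def trim(self, qmin: float | None = None, qmax: float | None = None) -> "ScatteringCurve":
        """Return a copy restricted to qmin <= q <= qmax."""
        lo = -np.inf if qmin is None else qmin
        hi = np.inf if qmax is None else qmax
        keep = (self.q >= lo) & (self.q <= hi)
        if keep.sum() == 0:
            raise ValueError("q-range trim leaves no points")
        sig = None if self.sigma is None else self.sigma[keep]
        return ScatteringCurve(self.q[keep], self.intensity[keep], sig, self.label)


def read_curve(path, label: str = "") -> ScatteringCurve:
    """Read a 3-column (q, I, dI) whitespace- or comma-delimited text file.

    Lines starting with '#' are comments.  A 2-column file yields sigma=None.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            rows.append([float(x) for x in parts[:3]])
    arr = np.array(rows, dtype=float)
    if arr.shape[1] >= 3:
        return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], label=label)
    return ScatteringCurve(arr[:, 0], arr[:, 1], None, label=label)


def write_curve(path, curve: ScatteringCurve) -> None:
    """Write a curve as 3-column text with a '#' header."""
    with open(path, "w") as fh:
        fh.write(f"# {curve.label}\n# q[1/A]  I(q)  dI\n")
        sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
        for qi, ii, si in zip(curve.q, curve.intensity, sig):
            fh.write(f"{qi:.8g} {ii:.8g} {si:.8g}\n")
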