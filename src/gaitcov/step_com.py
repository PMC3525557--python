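"""Step-to-step correlations between the two CoM-related task variables.

Because step = bCoM + fCoM in each direction, Var(step) = Var(b) + Var(f)
+ 2 Cov(b, f): a positive step-to-step correlation of bCoM and fCoM inflates
step variability (the step measure is destabilized by the relation between
the two CoM positions), a negative correlation reduces it (stabilization).
Correlations are Fisher z'-transformed (atanh) before any averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's z' = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class StepComResult:
    direction: str  # 'X' or 'Y'
    r: float
    z: float
    n: int
    front_side: str
    flagged: bool = False
    meta: dict | None = None

    @property
    def destabilizing(self) -> bool:
        """True when the bCoM-fCoM relation inflates step variability."""
        return self.r > 0


def step_com_correlation(
    bcom: np.ndarray,
    fcom: np.ndarray,
    direction: str = "X",
    front_side: str = "left",
    step: np.ndarray | None = None,
    meta: dict | None = None,
) -> StepComResult:
    """Pearson correlation of per-step bCoM and fCoM in one direction.

    If the per-step ``step`` values are supplied, the additivity identity
    step = bCoM + fCoM is verified first.  Zero variance in either series
    leaves the correlation undefined (flagged result, r = NaN).
    """
    b = np.asarray(bcom, dtype=float).ravel()
    f = np.asarray(fcom, dtype=float).ravel()
    if direction not in ("X", "Y"):
        raise ValueError("direction must be 'X' or 'Y'")
    if b.shape != f.shape:
        raise ValueError("bCoM and fCoM series differ in length")
    n = b.size
    if n < 3:
        raise ValueError("need at least 3 steps for a correlation")
    if step is not None:
        step = np.asarray(step, dtype=float).ravel()
        if not np.allclose(b + f, step, atol=1e-10):
            raise ValueError("additivity violated: step != bCoM + fCoM")
    sb = b.std(ddof=1)
    sf = f.std(ddof=1)
    # constant series have SD at rounding level, not exactly zero
    tol_b = 1e-12 + 1e-10 * np.abs(b).max(initial=0.0)
    tol_f = 1e-12 + 1e-10 * np.abs(f).max(initial=0.0)
    if sb <= tol_b or sf <= tol_f:
        return StepComResult(direction, np.nan, np.nan, n, front_side,
                             flagged=True, meta=meta)
    r = float(np.cov(b, f, ddof=1)[0, 1] / (sb * sf))
    r = float(np.clip(r, -1.0, 1.0))
    z = float(np.arctanh(r)) if abs(r) < 1.0 else float(np.sign(r) * np.inf)
    return StepComResult(direction, r, z, n, front_side, flagged=False, meta=meta)
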