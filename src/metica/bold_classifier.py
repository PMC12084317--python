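"""BOLD vs non-BOLD labeling from the shape of a component's TE loading.

A genuinely hemodynamic (delta-R2*-driven) signal scales approximately
as TE * exp(-TE/T2*), which is bell-shaped across echo times and peaks
near tissue T2*; S0-driven artifacts decay monotonically with TE.  A
quadratic is fitted to the (sign-normalized) TE loadings and a
component is labeled BOLD when the fit is concave with its vertex
inside the 20-50 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tensor_ica import DecompositionResult

__all__ = ["TEProfileFit", "BoldLabel", "fit_te_profile", "classify_bold", "classify_components"]

DEFAULT_WINDOW_MS = (20.0, 50.0)


@dataclass
class TEProfileFit:
    coeffs: tuple[float, float, float]  # a, b, c of a*TE^2 + b*TE + c
    vertex_ms: Optional[float]  # -b / 2a, None when a ~ 0
    curvature_sign: int  # sign(a): -1 concave, +1 convex, 0 degenerate
    r_squared: float
    te_ms: np.ndarray
    loadings: np.ndarray


@dataclass
class BoldLabel:
    is_bold: bool
    reason: str  # vertex_in_window | convex | vertex_out_of_window | degenerate


def fit_te_profile(te_loading: np.ndarray, te_ms: np.ndarray) -> TEProfileFit:
    """Least-squares quadratic fit of TE loadings against echo time (ms)."""
    y = np.asarray(te_loading, dtype=float)
    te = np.asarray(te_ms, dtype=float)
    if len(te) < 3 or len(y) != len(te):
        raise ValueError("need >= 3 echoes with matching loadings")
    a, b, c = np.polyfit(te, y, 2)

    scale = max(np.abs(y).max(), 1e-300)
    span = te.max() - te.min()
    degenerate = abs(a) * span**2 < 1e-9 * scale
    vertex = None if degenerate else -b / (2 * a)
    curv = 0 if degenerate else (1 if a > 0 else -1)

    fitted = np.polyval([a, b, c], te)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return TEProfileFit(
        coeffs=(float(a), float(b), float(c)),
        vertex_ms=vertex,
        curvature_sign=curv,
        r_squared=r2,
        te_ms=te,
        loadings=y,
    )


def classify_bold(
    fit: TEProfileFit,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    min_r_squared: Optional[float] = None,
    min_relative_curvature: float = 0.2,
) -> BoldLabel:
    """Label a TE-profile fit: BOLD iff concave with vertex in the window.

    The window is closed ([20, 50] ms by default).  A profile is called
    degenerate (flat) when the fitted parabola's total curvature swing
    across the sampled TE range, ``|a| * span(TE)**2``, is below
    ``min_relative_curvature`` times the peak loading magnitude — TE
    dependence that small cannot support a peak-vs-decay call and is at
    the level of component estimation noise.  ``min_r_squared`` is an
    optional goodness-of-fit gate for noisy data; none by default.
    """
    scale = max(np.abs(fit.loadings).max(), 1e-300)
    span = fit.te_ms.max() - fit.te_ms.min()
    swing = abs(fit.coeffs[0]) * span**2 / scale
    if fit.curvature_sign == 0 or swing < min_relative_curvature:
        return BoldLabel(False, "degenerate")
    if min_r_squared is not None and fit.r_squared < min_r_squared:
        return BoldLabel(False, "degenerate")
    if fit.curvature_sign > 0:
        return BoldLabel(False, "convex")
    lo, hi = window_ms
    if lo <= fit.vertex_ms <= hi:
        return BoldLabel(True, "vertex_in_window")
    return BoldLabel(False, "vertex_out_of_window")


def classify_components(
    result: DecompositionResult,
    te_ms: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    min_r_squared: Optional[float] = None,
    min_relative_curvature: float = 0.2,
) -> list[tuple[TEProfileFit, BoldLabel]]:
    """Fit and label every component of a decomposition."""
    out = []
    for comp in result.components:
        fit = fit_te_profile(comp.te_loading, te_ms)
        out.append(
            (fit, classify_bold(fit, window_ms, min_r_squared, min_relative_curvature))
        )
    return out
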