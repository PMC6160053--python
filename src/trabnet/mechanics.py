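"""Beam mechanics of trabeculae: flexural stiffness and Euler buckling.

Each trabecula is idealized as a straight circular column with both ends
fixed.  The second moment of area I = pi r^4 / 4 sets the flexural
stiffness EI; the critical Euler buckling force is F_E = n pi^2 E I / L^2
with end-condition coefficient n = 4 for two fixed ends.  Young's modulus E
defaults to 1 (dimensionless mode): no calcite stereom modulus is assumed,
so absolute forces are meaningful only when the user supplies E.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: end-condition coefficient for a column with two fixed ends
FIXED_ENDS_COEFF = 4.0


def second_moment_area(r: float) -> float:
    """I = pi r^4 / 4 (µm^4) for a circular cross-section of radius r."""
    if r < 0:
        raise ValueError("radius must be >= 0")
    return math.pi * r ** 4 / 4.0


def euler_buckling_force(E: float, I: float, L: float,
                         n_coeff: float = FIXED_ENDS_COEFF) -> float:
    """F_E = n pi^2 E I / L^2, the load at which an ideal column buckles."""
    if L <= 0:
        raise ValueError("beam length must be > 0")
    if E <= 0:
        raise ValueError("Young's modulus must be > 0")
    if n_coeff <= 0:
        raise ValueError("end-condition coefficient must be > 0")
    return n_coeff * math.pi ** 2 * E * I / L ** 2


def per_segment_buckling(table: pd.DataFrame, E: float = 1.0,
                         n_coeff: float = FIXED_ENDS_COEFF) -> pd.DataFrame:
    """Augment a segment descriptor table with I, g_r, R_S and F_E columns.

    ``table`` must carry ``mean_radius`` and ``curved_length`` columns (as
    produced by :func:`trabnet.descriptors.segment_table`).  Zero-length or
    radius-free segments get NaN forces and are flagged in ``buckling_ok``.
    """
    out = table.copy()
    r = out["mean_radius"].to_numpy(dtype=float)
    L = out["curved_length"].to_numpy(dtype=float)
    I = np.pi * r ** 4 / 4.0
    g_r = r / 2.0  # d/4 = 2r/4
    ok = (L > 0) & np.isfinite(r) & (r > 0)
    F_E = np.full_like(I, np.nan)
    R_S = np.full_like(I, np.nan)
    F_E[ok] = n_coeff * np.pi ** 2 * E * I[ok] / L[ok] ** 2
    R_S[ok] = L[ok] / g_r[ok]
    out["second_moment_area"] = I
    out["radius_of_gyration"] = g_r
    out["slenderness"] = R_S
    out["euler_force"] = F_E
    out["buckling_ok"] = ok
    return out
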