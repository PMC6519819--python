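"""Global 2D gamma-index comparison of dose distributions.

The gamma index combines, per reference point, the dose difference and the
distance-to-agreement (DTA) into a single dimensionless figure:

    gamma(r_ref) = min over r_eval of
        sqrt( |r_eval - r_ref|^2 / dta^2  +  (D_eval - D_ref)^2 / dD^2 )

with ``dD = dose_tolerance * D_norm``.  Under *global* normalisation,
``D_norm`` is a single distribution-wide anchor -- here the maximum of the
reference map (the conventional choice for absolute-dose QA; the evaluated
map's maximum is available as an option).  A point passes when gamma <= 1.
Reference points at or below the low-dose threshold (fraction of ``D_norm``)
are excluded from evaluation.

The evaluated distribution is sampled by bilinear interpolation on a sub-grid
of spacing ``interp_step * dta`` inside a search disc of radius
``search_limit * dta`` (beyond 3 DTA the distance term alone exceeds any
practically reported gamma).  The implementation is an exhaustive vectorised
search over that sub-grid, which doubles as its own brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .dosemap import DoseMap

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "pass_rate_summary"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma evaluation parameters (defaults: 3%/3 mm, 10% threshold)."""

    dose_tolerance: float = 0.03
    dta: float = 3.0  # mm
    threshold: float = 0.10
    normalization: Literal["global_max_reference", "global_max_evaluated"] = (
        "global_max_reference"
    )
    search_limit: float = 3.0  # multiples of dta
    interp_step: float = 0.1  # fraction of dta

    def __post_init__(self) -> None:
        for name in ("dose_tolerance", "dta", "threshold", "search_limit", "interp_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.interp_step > 1:
            raise ValueError("interp_step must be <= 1")


@dataclass(frozen=True)
class GammaResult:
    """Gamma map plus its pass-rate summary.

    ``gamma_values`` has the reference shape with NaN at unevaluated points.
    """

    gamma_values: np.ndarray
    pass_rate: float
    evaluated_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pass_rate <= 100.0):
            raise ValueError("pass_rate must lie in [0, 100]")


def _pixel_coords_cm(dmap: DoseMap) -> tuple[np.ndarray, np.ndarray]:
    px = dmap.pixel_size / 10.0
    n_v, n_u = dmap.shape
    u = dmap.origin[0] + np.arange(n_u) * px
    v = dmap.origin[1] + np.arange(n_v) * px
    return u, v


def gamma_map(
    reference: DoseMap,
    evaluated: DoseMap,
    criteria: GammaCriteria | None = None,
) -> GammaResult:
    """Compute the gamma map of ``evaluated`` against ``reference``.

    The two maps are aligned through their physical (u, v) origins; they must
    overlap spatially.  Gamma is deliberately asymmetric: the reference map
    anchors both the evaluation grid and (by default) the normalisation dose.

    Raises
    ------
    ValueError
        If the maps do not overlap, or if every reference point falls at or
        below the low-dose threshold (reported distinctly).
    """
    crit = criteria or GammaCriteria()
    ref = reference.values
    if crit.normalization == "global_max_reference":
        d_norm = float(ref.max())
    else:
        d_norm = float(evaluated.values.max())
    if d_norm <= 0:
        raise ValueError("normalization dose is zero; cannot evaluate gamma")
    dd = crit.dose_tolerance * d_norm
    dta_cm = crit.dta / 10.0

    ru, rv = _pixel_coords_cm(reference)
    eu, ev = _pixel_coords_cm(evaluated)
    if ru[0] > eu[-1] or eu[0] > ru[-1] or rv[0] > ev[-1] or ev[0] > rv[-1]:
        raise ValueError("reference and evaluated maps do not overlap spatially")

    mask = ref > crit.threshold * d_norm
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise ValueError(
            "no evaluable points: all reference doses are at or below the "
            f"{crit.threshold:.0%} low-dose threshold"
        )

    # search-disc offsets on the interpolation sub-grid (cm)
    step = crit.interp_step * dta_cm
    reach = crit.search_limit * dta_cm
    n_off = int(np.floor(reach / step + 1e-9))
    line = np.arange(-n_off, n_off + 1) * step
    ou, ov = np.meshgrid(line, line)
    disc = ou**2 + ov**2 <= reach**2 + 1e-12
    off_u, off_v = ou[disc], ov[disc]
    dist2 = (off_u**2 + off_v**2) / dta_cm**2

    rv_idx, ru_idx = np.nonzero(mask)
    pu = ru[ru_idx]
    pv = rv[rv_idx]
    dref = ref[mask]

    e_px = evaluated.pixel_size / 10.0
    gamma2 = np.full(pu.shape, np.inf)
    # chunk over offsets to bound memory
    chunk = max(1, int(2e7 // max(pu.size, 1)))
    for start in range(0, off_u.size, chunk):
        sl = slice(start, start + chunk)
        qu = pu[None, :] + off_u[sl, None]
        qv = pv[None, :] + off_v[sl, None]
        # fractional indices into the evaluated grid
        iu = (qu - evaluated.origin[0]) / e_px
        iv = (qv - evaluated.origin[1]) / e_px
        inside = (
            (iu >= 0)
            & (iu <= evaluated.shape[1] - 1)
            & (iv >= 0)
            & (iv <= evaluated.shape[0] - 1)
        )
        de = map_coordinates(
            evaluated.values, [iv.ravel(), iu.ravel()], order=1, mode="nearest"
        ).reshape(qu.shape)
        g2 = dist2[sl, None] + (de - dref[None, :]) ** 2 / dd**2
        g2 = np.where(inside, g2, np.inf)
        gamma2 = np.minimum(gamma2, g2.min(axis=0))

    gamma_vals = np.sqrt(gamma2)
    out = np.full(ref.shape, np.nan)
    out[mask] = gamma_vals
    passed = int(np.count_nonzero(gamma_vals <= 1.0 + 1e-12))
    return GammaResult(
        gamma_values=out,
        pass_rate=100.0 * passed / n_eval,
        evaluated_points=n_eval,
    )


def pass_rate_summary(
    results: Sequence[GammaResult | float],
) -> dict[str, float]:
    """Mean, sample SD, min and max of pass rates.

    Accepts GammaResult objects or bare pass-rate percentages.  A single
    result reports SD = 0 by convention.
    """
    if len(results) == 0:
        raise ValueError("empty result list")
    rates = np.array(
        [r.pass_rate if isinstance(r, GammaResult) else float(r) for r in results]
    )
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return {
        "mean": float(rates.mean()),
        "sd": sd,
        "min": float(rates.min()),
        "max": float(rates.max()),
        "n": len(rates),
    }
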