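"""Forward velocity mapping and inversion to the Clausius-Mossotti factor.

The instrument observes, per cell, the incoming velocity vi, the
differential velocity v_diff = vi - vo across the electrode pair, and the
optically measured size.  The transport simulation provides the forward map

    (radius, Re{Kcm}, vi)  ->  v_diff

which is tabulated on a grid once per device configuration and then
inverted per cell: v_diff is monotone increasing in Re{Kcm} at fixed
(radius, vi), so a 1-D monotone interpolation along the Kcm axis (bilinear
in radius and vi) yields a unique estimate.

Entry heights are not observable; for each (radius, vi) node the entry
height is found by a root search so that the *simulated* fitted vi matches
the node value, mirroring how the physical device infers height from
velocity.  Heights are restricted to the lower half-channel, where cells
settle and where vi <-> height is single-valued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .field_solver import FieldGrid
from .transport import (MIN_GAP, ParticleState, TransportParams,
                        equilibrium_height, simulate_trajectory)

__all__ = [
    "MappingGrid",
    "KcmEstimate",
    "MappingBuildError",
    "build_mapping",
    "infer_kcm",
    "DEFAULT_NOISE_VDIFF",
]

#: Differential-velocity measurement noise (m/s) used for the inversion
#: confidence interval: the instrument's no-DEP standard deviation, 56 um/s.
DEFAULT_NOISE_VDIFF = 56e-6


class MappingBuildError(RuntimeError):
    """Raised when too many mapping nodes cannot be populated."""


@dataclass
class MappingGrid:
    """Tabulated forward map (radius, Re{Kcm}, vi) -> v_diff.

    ``v_diff`` has shape (n_r, n_kcm, n_vi); NaN marks invalid nodes (no
    entry height reproduces the target vi, or the trajectory was captured).
    ``entry_heights`` records the root-found entry height per (r, vi) node.
    """

    r_axis: np.ndarray
    kcm_axis: np.ndarray
    vi_axis: np.ndarray
    v_diff: np.ndarray
    entry_heights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.v_diff.shape == (self.r_axis.size, self.kcm_axis.size,
                                     self.vi_axis.size)

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.v_diff)))

    def is_monotone_in_kcm(self, atol: float = 1e-7) -> bool:
        """Check v_diff is non-decreasing along the Kcm axis at every valid
        (r, vi) node; atol in m/s absorbs integrator noise."""
        d = np.diff(self.v_diff, axis=1)
        return bool(np.all((d > -atol) | ~np.isfinite(d)))

    def save(self, path) -> None:
        np.savez_compressed(path, r_axis=self.r_axis, kcm_axis=self.kcm_axis,
                            vi_axis=self.vi_axis, v_diff=self.v_diff,
                            entry_heights=self.entry_heights,
                            provenance=np.array(repr(self.provenance)))

    @classmethod
    def load(cls, path) -> "MappingGrid":
        import ast

        d = np.load(path)
        return cls(r_axis=d["r_axis"], kcm_axis=d["kcm_axis"],
                   vi_axis=d["vi_axis"], v_diff=d["v_diff"],
                   entry_heights=d["entry_heights"],
                   provenance=ast.literal_eval(str(d["provenance"])))


@dataclass(frozen=True)
class KcmEstimate:
    """Inverted Re{Kcm} with a +/- one-noise-unit interval."""

    value: float
    lower: float
    upper: float
    flags: tuple[str, ...] = ()


def solve_entry_height(params: TransportParams, fieldgrid: FieldGrid,
                       target_vi: float, x_start: float, x_span: float,
                       rel_tol: float = 0.01) -> Optional[float]:
    """Entry height whose simulated fitted vi matches ``target_vi``.

    Run with Re{Kcm} = 0 (the pre-electrode fit is insensitive to the drive
    for the default exclusion margin).  The search is restricted to heights
    between the no-DEP equilibrium and just below mid-channel: below the
    equilibrium the wall repulsion restores cells within a few frames, so
    lower vi values are not sustained and None is returned.
    """
    p0 = params if params.re_kcm == 0 else \
        TransportParams(**{**params.__dict__, "re_kcm": 0.0})
    H, r = p0.channel_height, p0.radius

    def fitted_vi(h0: float) -> float:
        tr = simulate_trajectory(ParticleState(x=x_start, h=h0), p0,
                                 fieldgrid, x_span)
        return tr.observation.vi

    lo = equilibrium_height(p0)
    hi = H / 2.0 - max(0.02 * H, 10 * MIN_GAP)
    vi_lo, vi_hi = fitted_vi(lo), fitted_vi(hi)
    if not (vi_lo - rel_tol * target_vi <= target_vi
            <= vi_hi + rel_tol * target_vi):
        return None
    if target_vi <= vi_lo:
        return lo
    if target_vi >= vi_hi:
        return hi
    h0 = brentq(lambda h: fitted_vi(h) - target_vi, lo, hi,
                xtol=1e-8, rtol=1e-6, maxiter=60)
    if abs(fitted_vi(h0) - target_vi) > rel_tol * target_vi:
        return None
    return h0


def build_mapping(params_template: TransportParams, fieldgrid: FieldGrid,
                  r_axis, kcm_axis, vi_axis,
                  x_start: float = -450e-6, x_span: float = 900e-6,
                  max_invalid_fraction: float = 0.2) -> MappingGrid:
    """Populate the forward (radius, Re{Kcm}, vi) -> v_diff grid.

    ``params_template`` supplies the medium, flow and channel description;
    its radius and re_kcm are overridden per node.  Raises
    :class:`MappingBuildError` if more than ``max_invalid_fraction`` of the
    nodes cannot be populated.
    """
    r_axis = np.asarray(r_axis, float)
    kcm_axis = np.asarray(kcm_axis, float)
    vi_axis = np.asarray(vi_axis, float)
    for name, ax in (("r", r_axis), ("kcm", kcm_axis), ("vi", vi_axis)):
        if ax.size < 3:
            raise ValueError(f"{name} axis needs >= 3 points")
        if np.any(np.diff(ax) <= 0):
            raise ValueError(f"{name} axis must be strictly increasing")

    v_diff = np.full((r_axis.size, kcm_axis.size, vi_axis.size), np.nan)
    heights = np.full((r_axis.size, vi_axis.size), np.nan)
    base = params_template.__dict__

    for i, r in enumerate(r_axis):
        p_r = TransportParams(**{**base, "radius": float(r), "re_kcm": 0.0})
        for k, vi in enumerate(vi_axis):
            h0 = solve_entry_height(p_r, fieldgrid, float(vi), x_start, x_span)
            if h0 is None:
                continue
            heights[i, k] = h0
            for j, kcm in enumerate(kcm_axis):
                p = TransportParams(**{**base, "radius": float(r),
                                       "re_kcm": float(kcm)})
                tr = simulate_trajectory(ParticleState(x=x_start, h=h0), p,
                                         fieldgrid, x_span)
                if tr.captured or "partial" in tr.observation.flags:
                    continue
                v_diff[i, j, k] = tr.observation.v_diff

    grid = MappingGrid(
        r_axis=r_axis, kcm_axis=kcm_axis, vi_axis=vi_axis,
        v_diff=v_diff, entry_heights=heights,
        provenance={
            "vpp": fieldgrid.layout.applied_voltage_vpp,
            "frequency_hz": fieldgrid.layout.drive_frequency,
            "grid_step_m": fieldgrid.grid_step,
            "mean_flow_velocity": params_template.mean_flow_velocity,
            "lift_model": str(params_template.lift_model),
            "x_start": x_start, "x_span": x_span,
        })
    invalid = 1.0 - grid.valid_fraction
    if invalid > max_invalid_fraction:
        bad = np.argwhere(~np.isfinite(v_diff))
        raise MappingBuildError(
            f"{invalid:.0%} of mapping nodes invalid "
            f"(> {max_invalid_fraction:.0%}); first failures at "
            f"(r, kcm, vi) indices {bad[:5].tolist()}")
    return grid


def _bilinear_weights(axis: np.ndarray, value: float) -> tuple[int, int, float]:
    """Indices (i, i+1) and fraction for linear interpolation on an axis."""
    if not axis[0] <= value <= axis[-1]:
        raise ValueError(f"value {value} outside axis hull "
                         f"[{axis[0]}, {axis[-1]}]")
    i = int(np.clip(np.searchsorted(axis, value) - 1, 0, axis.size - 2))
    frac = (value - axis[i]) / (axis[i + 1] - axis[i])
    return i, i + 1, frac


def _kcm_curve(grid: MappingGrid, r: float, vi: float) -> np.ndarray:
    """v_diff as a function of the kcm axis at (r, vi), bilinear in (r, vi)."""
    i0, i1, fr = _bilinear_weights(grid.r_axis, r)
    k0, k1, fv = _bilinear_weights(grid.vi_axis, vi)
    c = (grid.v_diff[i0, :, k0] * (1 - fr) * (1 - fv)
         + grid.v_diff[i1, :, k0] * fr * (1 - fv)
         + grid.v_diff[i0, :, k1] * (1 - fr) * fv
         + grid.v_diff[i1, :, k1] * fr * fv)
    if not np.all(np.isfinite(c)):
        raise ValueError("mapping grid has invalid nodes at the query corner")
    return c


def infer_kcm(vi: float, v_diff: float, r: float, grid: MappingGrid,
              noise: float = DEFAULT_NOISE_VDIFF) -> KcmEstimate:
    """Invert a (vi, v_diff, radius) measurement to Re{Kcm}.

    Monotone 1-D interpolation along the Kcm axis of the forward grid;
    the interval is the inversion of v_diff +/- one measurement noise unit.
    Measurements outside the attainable v_diff range at (r, vi) are clamped
    to the grid edge and flagged ``out_of_range``.
    """
    curve = _kcm_curve(grid, r, vi)
    # enforce non-decreasing curve for interpolation (integrator noise)
    curve_m = np.maximum.accumulate(curve)
    kax = grid.kcm_axis
    flags = []

    def invert(v: float) -> float:
        if v <= curve_m[0]:
            return float(kax[0])
        if v >= curve_m[-1]:
            return float(kax[-1])
        return float(np.interp(v, curve_m, kax))

    if not curve_m[0] <= v_diff <= curve_m[-1]:
        flags.append("out_of_range")
    value = invert(v_diff)
    lo = invert(v_diff - noise)
    hi = invert(v_diff + noise)
    return KcmEstimate(value=value, lower=lo, upper=hi, flags=tuple(flags))
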