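"""Dielectric models and Clausius-Mossotti spectra for DEP analysis.

A particle in a non-uniform AC field experiences a dielectrophoretic force
whose sign and magnitude are set by the real part of the Clausius-Mossotti
factor (CMF),

    Kcm = (eps_p - eps_m) / (eps_p + 2 eps_m),

where ``eps_p`` and ``eps_m`` are the *complex* permittivities of particle
and medium, ``eps = eps0*eps_r - j*sigma/omega``.  Biological cells are
represented with a double-shell model (plasma membrane, cytoplasm, nuclear
envelope, nucleoplasm) reduced to a single equivalent homogeneous sphere by
repeated confocal shelled-sphere reduction; calibration polystyrene
microspheres (PSS) are homogeneous spheres whose conductivity is dominated
by surface conductance, ``sigma_p = 2*Ksurf/r``.

In the beta-dispersion window (100 kHz - 500 MHz) the double-shell model
captures the interfacial polarization that distinguishes viable cells
(intact, low-conductivity membrane -> positive Re{Kcm} at MHz frequencies)
from non-viable cells (depolarized cytoplasm -> negative Re{Kcm}), which is
the physical basis of DEP viability discrimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Sequence, Union

import numpy as np

__all__ = [
    "EPS0",
    "Medium",
    "DoubleShellCell",
    "SurfaceConductingSphere",
    "CMFSpectrum",
    "complex_permittivity",
    "clausius_mossotti",
    "shell_reduce",
    "cell_equivalent_permittivity",
    "particle_permittivity",
    "cmf_at",
    "cmf_spectrum",
    "sensitivity_band",
    "default_frequency_grid",
    "load_preset",
    "PRESETS",
]

#: Vacuum permittivity (F/m).
EPS0 = 8.854187817e-12


@dataclass(frozen=True)
class Medium:
    """Suspending medium: dielectric and fluid-dynamic properties (SI)."""

    rel_permittivity: float = 78.0
    conductivity: float = 0.17  # S/m
    mass_density: float = 1017.5  # kg/m^3
    viscosity: float = 1.0e-3  # Pa s

    def __post_init__(self) -> None:
        if self.rel_permittivity < 1:
            raise ValueError("relative permittivity must be >= 1")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")
        if self.viscosity <= 0 or self.mass_density <= 0:
            raise ValueError("viscosity and density must be positive")

    def complex_permittivity(self, f: float) -> complex:
        return complex_permittivity(self.rel_permittivity, self.conductivity, f)


@dataclass(frozen=True)
class DoubleShellCell:
    """Double-shell dielectric model of a cell.

    Geometry: nucleoplasm of radius ``r_n - d_n`` inside a nuclear envelope
    of thickness ``d_n`` (outer nucleus radius ``r_n``), inside cytoplasm,
    inside a plasma membrane of thickness ``d_mem`` (outer cell radius
    ``r_cell``).  Permittivities are stored as multiples of eps0,
    conductivities in S/m, lengths in m.
    """

    r_cell: float
    r_n: float
    d_n: float
    d_mem: float
    sigma_mem: float
    sigma_ne: float
    sigma_cyt: float
    sigma_n: float
    eps_mem: float
    eps_ne: float
    eps_cyt: float
    eps_n: float
    mass_density: float = 1050.0  # kg/m^3, used by the transport stage

    def __post_init__(self) -> None:
        if not (0 < self.r_n - self.d_n < self.r_n < self.r_cell - self.d_mem < self.r_cell):
            raise ValueError("invalid double-shell geometry ordering")
        for name in ("sigma_mem", "sigma_ne", "sigma_cyt", "sigma_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("eps_mem", "eps_ne", "eps_cyt", "eps_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (in units of eps0)")

    @property
    def radius(self) -> float:
        return self.r_cell

    def with_radius(self, r_cell: float) -> "DoubleShellCell":
        """Rescale the cell to a new outer radius, keeping r_n = 0.55*r_cell
        and the (thin) envelope/membrane thicknesses fixed."""
        return replace(self, r_cell=r_cell, r_n=0.55 * r_cell)


@dataclass(frozen=True)
class SurfaceConductingSphere:
    """Homogeneous dielectric sphere with surface conductance Ksurf.

    The effective bulk conductivity is ``sigma_p = 2*Ksurf/r``, the standard
    thin-double-layer result for latex microspheres.
    """

    radius: float
    bulk_rel_permittivity: float = 2.5
    surface_conductance: float = 1.0e-9  # S
    mass_density: float = 1050.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.surface_conductance < 0:
            raise ValueError("surface conductance must be >= 0")

    @property
    def conductivity(self) -> float:
        return 2.0 * self.surface_conductance / self.radius


ParticleModel = Union[DoubleShellCell, SurfaceConductingSphere]


def complex_permittivity(eps_r: float, sigma: float, f: float) -> complex:
    """Complex permittivity eps0*eps_r - j*sigma/omega (F/m) at frequency f (Hz)."""
    f = float(f)
    if f <= 0:
        raise ValueError("frequency must be positive")
    if eps_r < 1:
        raise ValueError("relative permittivity must be >= 1")
    if sigma < 0:
        raise ValueError("conductivity must be >= 0")
    omega = 2.0 * math.pi * f
    return complex(EPS0 * eps_r, -sigma / omega)


def clausius_mossotti(eps_p: complex, eps_m: complex) -> complex:
    """Clausius-Mossotti factor (eps_p - eps_m)/(eps_p + 2*eps_m)."""
    den = eps_p + 2.0 * eps_m
    if abs(den) == 0.0:
        raise ZeroDivisionError("Clausius-Mossotti denominator vanishes")
    return (eps_p - eps_m) / den


def shell_reduce(eps_inner: complex, eps_shell: complex,
                 r_inner: float, r_outer: float) -> complex:
    """Equivalent permittivity of a shelled sphere (confocal reduction).

    A core of permittivity ``eps_inner`` and radius ``r_inner`` covered by a
    shell of permittivity ``eps_shell`` out to ``r_outer`` is replaced by a
    homogeneous sphere of radius ``r_outer`` with

        eps_eq = eps_shell * (g^3 + 2K) / (g^3 - K),
        g = r_outer/r_inner,  K = (eps_inner - eps_shell)/(eps_inner + 2 eps_shell).

    Exact identity for a zero-thickness shell or matched materials.
    """
    if not (0 < r_inner <= r_outer):
        raise ValueError("need 0 < r_inner <= r_outer")
    g3 = (r_outer / r_inner) ** 3
    K = clausius_mossotti(eps_inner, eps_shell)
    den = g3 - K
    if abs(den) < 1e-300:
        raise ZeroDivisionError("degenerate shell reduction (g^3 == K)")
    return eps_shell * (g3 + 2.0 * K) / den


def cell_equivalent_permittivity(cell: DoubleShellCell, f: float) -> complex:
    """Equivalent homogeneous-sphere permittivity of a double-shell cell.

    Three nested confocal reductions: nucleoplasm|envelope at radii
    (r_n - d_n, r_n), then |cytoplasm at (r_n, r_cell - d_mem), then
    |membrane at (r_cell - d_mem, r_cell).
    """
    e_n = complex_permittivity(cell.eps_n, cell.sigma_n, f)
    e_ne = complex_permittivity(cell.eps_ne, cell.sigma_ne, f)
    e_cyt = complex_permittivity(cell.eps_cyt, cell.sigma_cyt, f)
    e_mem = complex_permittivity(cell.eps_mem, cell.sigma_mem, f)
    nucleus = shell_reduce(e_n, e_ne, cell.r_n - cell.d_n, cell.r_n)
    interior = shell_reduce(nucleus, e_cyt, cell.r_n, cell.r_cell - cell.d_mem)
    return shell_reduce(interior, e_mem, cell.r_cell - cell.d_mem, cell.r_cell)


def particle_permittivity(model: ParticleModel, f: float) -> complex:
    """Complex permittivity of any supported particle model at frequency f."""
    if isinstance(model, DoubleShellCell):
        return cell_equivalent_permittivity(model, f)
    if isinstance(model, SurfaceConductingSphere):
        return complex_permittivity(model.bulk_rel_permittivity, model.conductivity, f)
    raise TypeError(f"unsupported particle model: {type(model)!r}")


def cmf_at(model: ParticleModel, medium: Medium, f: float) -> complex:
    """Clausius-Mossotti factor of a particle model in a medium at f (Hz)."""
    return clausius_mossotti(particle_permittivity(model, f),
                             medium.complex_permittivity(f))


def default_frequency_grid(f_min: float = 1e4, f_max: float = 1e9,
                           n: int = 400) -> np.ndarray:
    """Logarithmic frequency grid covering the beta-dispersion window."""
    return np.logspace(math.log10(f_min), math.log10(f_max), n)


@dataclass(frozen=True)
class CMFSpectrum:
    """Clausius-Mossotti factor over a frequency grid."""

    frequencies: np.ndarray  # Hz, sorted
    kcm: np.ndarray  # complex, same length

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    @property
    def re(self) -> np.ndarray:
        return self.kcm.real

    def crossover_frequencies(self) -> list[float]:
        """Frequencies where Re{Kcm} changes sign, refined by bisection on the
        continuous model to relative tolerance 1e-6 (requires the spectrum to
        carry its generating model; see :func:`cmf_spectrum`)."""
        return list(self._crossovers)

    # populated by cmf_spectrum; not part of the public constructor contract
    _crossovers: tuple = field(default=(), repr=False, compare=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frequency_hz": self.frequencies,
            "re_kcm": self.kcm.real,
            "im_kcm": self.kcm.imag,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bisect_crossover(fun, f_lo: float, f_hi: float, rtol: float = 1e-6) -> float:
    v_lo = fun(f_lo)
    for _ in range(200):
        f_mid = math.sqrt(f_lo * f_hi)  # bisect in log-frequency
        v_mid = fun(f_mid)
        if v_lo * v_mid <= 0:
            f_hi = f_mid
        else:
            f_lo, v_lo = f_mid, v_mid
        if f_hi - f_lo <= rtol * f_lo:
            break
    return math.sqrt(f_lo * f_hi)


def cmf_spectrum(model: ParticleModel, medium: Medium,
                 f_grid: Sequence[float] | np.ndarray | None = None) -> CMFSpectrum:
    """Re/Im Clausius-Mossotti spectrum over a frequency grid.

    Crossover frequencies (sign changes of Re{Kcm}) are located from the grid
    and refined by bisection on the continuous model.
    """
    f = default_frequency_grid() if f_grid is None else np.asarray(f_grid, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(np.diff(f) < 0):
        raise ValueError("frequency grid must be sorted ascending")
    kcm = np.array([cmf_at(model, medium, fi) for fi in f])

    re = kcm.real
    fun = lambda fi: cmf_at(model, medium, fi).real  # noqa: E731
    crossings = []
    for i in np.nonzero(np.sign(re[:-1]) * np.sign(re[1:]) < 0)[0]:
        crossings.append(_bisect_crossover(fun, f[i], f[i + 1]))
    return CMFSpectrum(frequencies=f, kcm=kcm, _crossovers=tuple(crossings))


_SCALED_WITH_RADIUS = "r_cell"


def sensitivity_band(model: DoubleShellCell, medium: Medium,
                     f_grid: Sequence[float] | np.ndarray | None,
                     parameter: str, fraction: float = 0.2
                     ) -> tuple[CMFSpectrum, CMFSpectrum]:
    """Lower/upper Re{Kcm} envelopes for a +/-``fraction`` parameter sweep.

    ``parameter`` may be any scalar field of the cell model; for ``r_cell``
    the nucleus radius co-scales as r_n = 0.55*r_cell (cell geometry is
    approximately self-similar across sizes).  Returns (lower, upper)
    spectra, the pointwise min/max over the perturbed pair; the nominal
    spectrum lies inside the band by construction when fraction >= 0.
    """
    valid = {f.name for f in fields(model)} - {"mass_density"}
    if parameter not in valid:
        raise ValueError(f"unknown parameter {parameter!r}; one of {sorted(valid)}")
    if fraction < 0:
        raise ValueError("fraction must be >= 0")

    def perturbed(scale: float) -> DoubleShellCell:
        value = getattr(model, parameter) * scale
        if parameter == _SCALED_WITH_RADIUS:
            return model.with_radius(value)
        return replace(model, **{parameter: value})

    f = default_frequency_grid() if f_grid is None else np.asarray(f_grid, dtype=float)
    lo_s = cmf_spectrum(perturbed(1.0 - fraction), medium, f)
    hi_s = cmf_spectrum(perturbed(1.0 + fraction), medium, f)
    re_stack = np.vstack([lo_s.re, hi_s.re])
    im_stack = np.vstack([lo_s.kcm.imag, hi_s.kcm.imag])
    lower = CMFSpectrum(f, np.min(re_stack, axis=0) + 1j * np.min(im_stack, axis=0))
    upper = CMFSpectrum(f, np.max(re_stack, axis=0) + 1j * np.max(im_stack, axis=0))
    return lower, upper


def _cho(viable: bool) -> DoubleShellCell:
    r_cell = 6.25e-6 if viable else 5.5e-6
    return DoubleShellCell(
        r_cell=r_cell,
        r_n=0.55 * r_cell,
        d_n=40e-9,
        d_mem=5e-9,
        sigma_mem=1e-6,
        sigma_ne=1e-3,
        sigma_cyt=0.53 if viable else 0.07,
        sigma_n=1.5 if viable else 0.56,
        eps_mem=8.5 if viable else 5.0,
        eps_ne=11.5,
        eps_cyt=54.5,
        eps_n=120.0 if viable else 69.0,
    )


#: Bundled particle presets: viable/non-viable CHO cells (double-shell) and
#: the two calibration polystyrene microsphere sizes.
PRESETS: dict[str, ParticleModel] = {
    "cho_viable": _cho(True),
    "cho_nonviable": _cho(False),
    "pss_10um": SurfaceConductingSphere(radius=5.0e-6),
    "pss_15p7um": SurfaceConductingSphere(radius=15.7e-6 / 2),
}

#: Media presets: the 0.17 S/m DEP assay medium and DI water for PSS runs.
MEDIA: dict[str, Medium] = {
    "dep_medium": Medium(78.0, 0.17, 1017.5, 1.0e-3),
    "di_water": Medium(78.0, 5.5e-6, 1000.0, 1.0e-3),
}


def load_preset(name: str) -> ParticleModel:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def iter_presets() -> Iterator[tuple[str, ParticleModel]]:
    return iter(PRESETS.items())
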