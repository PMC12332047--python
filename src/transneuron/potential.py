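"""Electro-chemical potential of the mobile Ag cluster inside the gap.

The gap spans ``[-L/2, +L/2]`` with the filament tip at ``-L/2`` and the
counter-electrode at ``+L/2``.  The potential has a single well near the
filament tip; to the electrode side the slope first rises to a local
maximum (the escape barrier), dips to a shallow minimum slope near the gap
centre (the return plateau), then rises steeply at the confinement wall.
That slope profile is what turns the voltage-divider feedback into a
relaxation oscillator: the electric force must exceed the barrier slope to
pull the cluster off the well, and once the circuit voltage has collapsed
the residual force falls below the plateau slope so the cluster slides
back.

Two representations are supported: a polynomial (coefficients of U in
ascending powers of x) and a tabulated ``(x, U)`` sample interpolated with
a cubic spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar


class ConfigurationError(ValueError):
    """Raised when a parameter container or spec is internally inconsistent."""


@dataclass(frozen=True)
class PotentialSpec:
    """Shape of the electro-chemical potential U(x) in the gap.

    Parameters
    ----------
    kind :
        ``"polynomial"`` or ``"tabulated"``.
    coefficients :
        Polynomial coefficients of U in ascending powers of x
        (``kind="polynomial"`` only).
    x_grid, u_grid :
        Samples of U covering the whole gap (``kind="tabulated"`` only).
    well_position :
        Location of the potential minimum.  If ``None`` it is located
        numerically at construction via :func:`locate_well`.
    """

    kind: str = "polynomial"
    coefficients: Optional[Sequence[float]] = None
    x_grid: Optional[Sequence[float]] = None
    u_grid: Optional[Sequence[float]] = None
    well_position: Optional[float] = None
    _spline: CubicSpline = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.kind == "polynomial":
            if self.coefficients is None:
                raise ConfigurationError("polynomial PotentialSpec needs coefficients")
            object.__setattr__(
                self, "coefficients", np.asarray(self.coefficients, dtype=float)
            )
            if not np.all(np.isfinite(self.coefficients)):
                raise ConfigurationError("potential coefficients must be finite")
        elif self.kind == "tabulated":
            if self.x_grid is None or self.u_grid is None:
                raise ConfigurationError("tabulated PotentialSpec needs x_grid and u_grid")
            x = np.asarray(self.x_grid, dtype=float)
            u = np.asarray(self.u_grid, dtype=float)
            if x.ndim != 1 or x.shape != u.shape or x.size < 4:
                raise ConfigurationError("x_grid/u_grid must be matching 1-D arrays (n >= 4)")
            if not np.all(np.diff(x) > 0):
                raise ConfigurationError("x_grid must be strictly increasing")
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(u))):
                raise ConfigurationError("tabulated potential must be finite")
            object.__setattr__(self, "x_grid", x)
            object.__setattr__(self, "u_grid", u)
            object.__setattr__(self, "_spline", CubicSpline(x, u))
        else:
            raise ConfigurationError(f"unknown potential kind {self.kind!r}")

    # -- evaluation ---------------------------------------------------------

    def energy(self, x):
        """U(x)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "polynomial":
            return np.polynomial.polynomial.polyval(x, self.coefficients)
        self._check_cover(x)
        return self._spline(x)

    def force(self, x):
        """-dU/dx, the conservative force on the cluster."""
        x = np.asarray(x, dtype=float)
        if self.kind == "polynomial":
            dcoef = np.polynomial.polynomial.polyder(self.coefficients)
            return -np.polynomial.polynomial.polyval(x, dcoef)
        self._check_cover(x)
        return -self._spline(x, 1)

    def _check_cover(self, x) -> None:
        lo, hi = float(self.x_grid[0]), float(self.x_grid[-1])
        if np.any(np.asarray(x) < lo) or np.any(np.asarray(x) > hi):
            raise ConfigurationError(
                f"tabulated potential grid [{lo}, {hi}] does not cover requested x"
            )

    def check_covers_gap(self, L: float) -> None:
        """Raise unless a tabulated grid spans the whole gap [-L/2, L/2]."""
        if self.kind == "tabulated":
            if self.x_grid[0] > -L / 2 or self.x_grid[-1] < L / 2:
                raise ConfigurationError(
                    "tabulated potential grid does not cover the gap [-L/2, L/2]"
                )


def locate_well(spec: PotentialSpec, L: float, x0: Optional[float] = None) -> float:
    """Numerically locate the potential minimum inside the gap.

    Searches near ``x0`` (default: coarse grid argmin over the gap).
    """
    half = L / 2
    if x0 is None:
        grid = np.linspace(-half, half, 2001)
        x0 = float(grid[np.argmin(spec.energy(grid))])
    lo = max(-half, x0 - 0.1 * L)
    hi = min(half, x0 + 0.1 * L)
    res = minimize_scalar(lambda x: float(spec.energy(x)), bounds=(lo, hi), method="bounded")
    return float(res.x)


def default_potential(L: float = 1.0) -> PotentialSpec:
    """Reference potential: quartic with a single well at -0.4 L.

    In units of the gap (L = 1) the slope is

        U'(x) = (x + 0.4) ((x - 0.05)^2 + 0.004)

    i.e. U = x^4/4 + 0.1 x^3 - 0.01675 x^2 + 0.0026 x: a well at
    x = -0.4 (filament-tip side), an escape-barrier slope peaking near
    x = -0.25, a shallow minimum of the slope just right of the gap
    centre (where the tunnelling resistance is minimal) and a steadily
    steepening climb toward the counter-electrode.  This profile makes
    the voltage-divider feedback a relaxation oscillator: the electric
    force q V / L must exceed the barrier slope to pull the cluster off
    the well, and once the circuit voltage has collapsed the residual
    force drops below the slope minimum so the cluster slides back.  At
    high drive the force balances on the steep far flank instead, pinning
    the cluster near the counter-electrode in a low-conductance state.

    For general L the coordinate is rescaled (energy scale unchanged), so
    the shape stays geometrically similar.
    """
    base = np.array([0.0, 0.0026, -0.01675, 0.1, 0.25])
    if L != 1.0:
        base = base / L ** np.arange(5)
    spec = PotentialSpec(kind="polynomial", coefficients=base)
    well = locate_well(spec, L)
    return PotentialSpec(kind="polynomial", coefficients=base, well_position=well)


def reference_potential(L: float = 1.0, wall_onset: float = 0.05,
                        wall_strength: float = 2000.0,
                        n_grid: int = 4001) -> PotentialSpec:
    """Reference potential: the quartic well of :func:`default_potential`
    plus a steep one-sided confinement shoulder right of the gap centre,

        U'(x) = (x + 0.4)((x - 0.05)^2 + 0.004)
                + wall_strength * max(x - wall_onset, 0)^3 ,

    which stops the cluster while the gap is still conducting.  The
    resulting high-drive attractor is a latched-conducting state (the
    field holds the cluster near the gap centre against the shoulder), so
    the circuit can alternate between relaxation spiking and latching —
    the switching that produces intermittent bursting.  The piecewise
    form is C^2 and shipped as a dense tabulated spec (cubic spline);
    for general L the coordinate is rescaled.
    """
    xg = np.linspace(-0.5, 0.5, n_grid)
    u = xg ** 4 / 4 + 0.1 * xg ** 3 - 0.01675 * xg ** 2 + 0.0026 * xg
    u = u + wall_strength / 4.0 * np.clip(xg - wall_onset, 0.0, None) ** 4
    if L != 1.0:
        xg = xg * L
    spec = PotentialSpec(kind="tabulated", x_grid=xg, u_grid=u)
    well = locate_well(spec, L)
    return PotentialSpec(kind="tabulated", x_grid=xg, u_grid=u, well_position=well)
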