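"""Periodic grid geometry and the field containers used throughout the package.

The solver operates on the fixed periodic domain [0, 2pi)^d, d in {2, 3}, with a
uniform grid of even size per axis. Images are samples of a scalar field on the
grid nodes; the control variable is a stationary d-component velocity field on
the same nodes. All arithmetic is 64-bit floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = ["Grid", "ScalarField", "VelocityField", "TWO_PI"]


class FieldError(ValueError):
    """Raised for non-finite values or mismatched grids."""


@dataclass(frozen=True)
class Grid:
    """Uniform periodic grid on [0, 2pi)^d.

    Parameters
    ----------
    dims
        Number of nodes per axis; each must be even and at least 4.
        Length 2 or 3 selects the spatial dimension.
    """

    dims: tuple[int, ...]

    def __post_init__(self) -> None:
        dims = tuple(int(n) for n in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got {len(dims)} axes")
        for n in dims:
            if n < 4 or n % 2 != 0:
                raise ValueError(f"each axis needs an even size >= 4, got {n}")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def spacing(self) -> tuple[float, ...]:
        """Node spacing h = 2pi / n per axis (so h * n = 2pi exactly)."""
        return tuple(TWO_PI / n for n in self.dims)

    @property
    def cell_volume(self) -> float:
        """h^d, the quadrature weight of one node."""
        vol = 1.0
        for h in self.spacing:
            vol *= h
        return vol

    @cached_property
    def coords(self) -> np.ndarray:
        """Node coordinates, shape (d, *dims)."""
        axes = [np.arange(n) * h for n, h in zip(self.dims, self.spacing)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)

    # -- spectral layout -------------------------------------------------
    # Real-to-complex transforms: the last axis stores the half spectrum.

    @property
    def rfft_shape(self) -> tuple[int, ...]:
        return self.dims[:-1] + (self.dims[-1] // 2 + 1,)

    @cached_property
    def wavenumbers(self) -> list[np.ndarray]:
        """Signed integer wavenumbers per axis, broadcastable to rfft_shape."""
        ks = []
        d = self.ndim
        for ax, n in enumerate(self.dims):
            if ax == d - 1:
                k = np.arange(n // 2 + 1, dtype=np.float64)
            else:
                k = np.fft.fftfreq(n, d=1.0 / n)
            shape = [1] * d
            shape[ax] = k.size
            ks.append(k.reshape(shape))
        return ks

    @cached_property
    def deriv_wavenumbers(self) -> list[np.ndarray]:
        """Wavenumbers for first derivatives: Nyquist mode zeroed per axis.

        The Nyquist mode of an even real grid carries no sign information for
        an odd derivative, so its derivative is set to zero (the standard
        convention).
        """
        ks = []
        for ax, k in enumerate(self.wavenumbers):
            nyq = self.dims[ax] // 2
            k = k.copy()
            k[np.abs(k) == nyq] = 0.0
            ks.append(k)
        return ks

    @cached_property
    def laplacian_symbol(self) -> np.ndarray:
        """|k|^2 on the half spectrum (the symbol of -Laplacian)."""
        sym = np.zeros(self.rfft_shape)
        for k in self.wavenumbers:
            sym = sym + k**2
        return sym


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise FieldError(f"{what} contains non-finite values")


@dataclass
class ScalarField:
    """A real scalar sampled on the grid nodes (an image, or a multiplier)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise FieldError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        _check_finite(self.values, "scalar field")

    @classmethod
    def zeros(cls, grid: Grid) -> "ScalarField":
        return cls(grid, np.zeros(grid.dims))

    @classmethod
    def from_function(cls, grid: Grid, fn) -> "ScalarField":
        return cls(grid, fn(*grid.coords))

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


@dataclass
class VelocityField:
    """A stationary d-component vector field; data has shape (d, *dims)."""

    grid: Grid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.grid.ndim,) + self.grid.dims
        if self.data.shape != expected:
            raise FieldError(
                f"velocity shape {self.data.shape} != expected {expected}"
            )
        _check_finite(self.data, "velocity field")

    @classmethod
    def zeros(cls, grid: Grid) -> "VelocityField":
        return cls(grid, np.zeros((grid.ndim,) + grid.dims))

    @classmethod
    def from_components(cls, *components: ScalarField) -> "VelocityField":
        grid = components[0].grid
        for c in components[1:]:
            if c.grid.dims != grid.dims:
                raise FieldError("velocity components on different grids")
        return cls(grid, np.stack([c.values for c in components], axis=0))

    @property
    def components(self) -> tuple[ScalarField, ...]:
        return tuple(ScalarField(self.grid, c) for c in self.data)

    def copy(self) -> "VelocityField":
        return VelocityField(self.grid, self.data.copy())

    def max_norm(self) -> float:
        """Max over nodes of the Euclidean vector norm |v(x)|."""
        return float(np.sqrt((self.data**2).sum(axis=0)).max())


def same_grid(*fields) -> Grid:
    """Return the shared grid or raise on mismatch."""
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid.dims != grid.dims:
            raise FieldError("fields live on different grids")
    return grid


def inner(a, b) -> float:
    """L2 inner product h^d * sum(a*b) for scalar or velocity fields."""
    grid = same_grid(a, b)
    va = a.values if isinstance(a, ScalarField) else a.data
    vb = b.values if isinstance(b, ScalarField) else b.data
    return float(grid.cell_volume * np.sum(va * vb))


def norm(a) -> float:
    return float(np.sqrt(max(inner(a, a), 0.0)))
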