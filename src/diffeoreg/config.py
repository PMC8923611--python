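"""Registration configuration: regularization model and weights, time
discretization, solver tolerances."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .spectral import REG_MODELS

__all__ = ["RegistrationConfig"]


@dataclass
class RegistrationConfig:
    """All tunables of the registration solver.

    Attributes
    ----------
    reg_model
        Sobolev regularization model: ``h1s`` (H1 seminorm, default), ``h1``
        (full H1), or ``h2s`` (H2 seminorm).
    alpha
        Regularization weight (> 0). Larger values give smoother, smaller
        deformations.
    div_gamma
        Weight of the quadratic penalty on div v (>= 0); 0 disables the
        penalty, large values approach incompressible flow.
    nt
        Number of semi-Lagrangian time steps on [0, 1].
    interp_order
        Interpolation order for transport: 1 (linear) or 3 (cubic).
    outer_tol
        Outer loop stops when the gradient norm falls below
        ``outer_tol * ||g0||``.
    krylov_tol, krylov_maxit
        Relative tolerance and cap for the inner preconditioned CG solve.
    ls_c1, ls_maxit
        Armijo sufficient-decrease constant and maximum number of halvings.
    precond_shift
        Identity shift of the preconditioner (alpha*A + shift*I)^-1. Left
        unset it defaults to 1e-3 * alpha, the convention that regularizes
        the zero mode of the seminorm models.
    """

    reg_model: str = "h1s"
    alpha: float = 5e-3
    div_gamma: float = 0.0
    nt: int = 8
    interp_order: int = 3
    outer_tol: float = 5e-2
    outer_maxit: int = 50
    krylov_tol: float = 1e-1
    krylov_maxit: int = 50
    ls_c1: float = 1e-4
    ls_maxit: int = 20
    precond_shift: float | None = None

    def __post_init__(self) -> None:
        if self.reg_model not in REG_MODELS:
            raise ValueError(
                f"unknown regularization model {self.reg_model!r}; choose from {REG_MODELS}"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.div_gamma < 0:
            raise ValueError("div_gamma must be nonnegative")
        if self.nt < 1:
            raise ValueError("nt must be >= 1")
        if self.interp_order not in (1, 3):
            raise ValueError("interp_order must be 1 or 3")
        if not (0.0 < self.outer_tol < 1.0):
            raise ValueError("outer_tol must lie in (0, 1)")
        if not (0.0 < self.krylov_tol < 1.0):
            raise ValueError("krylov_tol must lie in (0, 1)")
        if not (0.0 < self.ls_c1 < 0.5):
            raise ValueError("ls_c1 must lie in (0, 1/2)")
        if self.precond_shift is None:
            self.precond_shift = 1e-3 * self.alpha
        if self.precond_shift <= 0:
            raise ValueError("precond_shift must be positive")

    # flat key=value config files ---------------------------------------

    _FLOAT_KEYS = (
        "alpha",
        "div_gamma",
        "outer_tol",
        "krylov_tol",
        "ls_c1",
        "precond_shift",
    )
    _INT_KEYS = ("nt", "interp_order", "outer_maxit", "krylov_maxit", "ls_maxit")

    @classmethod
    def from_file(cls, path) -> "RegistrationConfig":
        """Read a flat ``key = value`` text file mirroring the field names."""
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key == "reg_model":
                    kwargs[key] = val
                elif key in cls._FLOAT_KEYS:
                    kwargs[key] = float(val)
                elif key in cls._INT_KEYS:
                    kwargs[key] = int(val)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")
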