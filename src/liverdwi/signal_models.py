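"""Forward diffusion signal-decay models for multi-b-value liver DWI.

Three models are used throughout the package:

* mono-exponential (MEM):      S(b) = S0 * exp(-b * ADC)
* bi-exponential / IVIM (BEM): S(b) = S0 * [f * exp(-b * D*) + (1 - f) * exp(-b * D)]
* stretched exponential (SEM): S(b) = S0 * exp(-(b * DDC) ** alpha)

All diffusion coefficients are stored in mm^2/s (so liver ADC is ~1e-3 and
pseudo-diffusion D* is ~3e-2); the reporting layer multiplies by 1e3 to match
the conventional "x10^-3 mm^2/s" printed unit.  The perfusion fraction ``f``
is stored as a fraction in [0, 1] and rendered as percent only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STUDY_B_VALUES",
    "BValueScheme",
    "MonoExpParams",
    "BiExpParams",
    "StretchedExpParams",
    "mem_signal",
    "bem_signal",
    "sem_signal",
]

#: The 10-b-value diffusion-weighting scheme used by the pipeline by default,
#: in s/mm^2.
STUDY_B_VALUES: tuple[float, ...] = (0, 25, 50, 75, 100, 150, 200, 400, 600, 800)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion-weighting scheme in s/mm^2.

    Must be non-negative, strictly increasing and start at b = 0 (the
    unweighted image every fit needs for S0).
    """

    values: tuple[float, ...] = STUDY_B_VALUES

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError("b-value scheme needs at least two b-values")
        if vals[0] != 0:
            raise ValueError("first b-value must be 0 (unweighted image)")
        arr = np.asarray(vals)
        if np.any(arr < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class MonoExpParams:
    """Mono-exponential parameters: S0 (a.u.) and ADC (mm^2/s)."""

    S0: float
    ADC: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if self.ADC < 0:
            raise ValueError(f"ADC must be >= 0, got {self.ADC}")


@dataclass(frozen=True)
class BiExpParams:
    """IVIM bi-exponential parameters.

    D is the slow (true water) diffusion coefficient, Dstar the fast
    perfusion-driven pseudo-diffusion coefficient (both mm^2/s), f the
    perfusion fraction in [0, 1].  Requires 0 <= D < Dstar so the two
    compartments are identifiable.
    """

    S0: float
    D: float
    Dstar: float
    f: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if not self.D < self.Dstar:
            raise ValueError(f"need D < Dstar, got D={self.D}, Dstar={self.Dstar}")
        if not 0 <= self.f <= 1:
            raise ValueError(f"perfusion fraction must be in [0, 1], got {self.f}")


@dataclass(frozen=True)
class StretchedExpParams:
    """Stretched-exponential parameters: DDC (mm^2/s) and alpha in (0, 1].

    alpha = 1 collapses to the mono-exponential model with ADC = DDC; lower
    alpha means more intravoxel diffusion heterogeneity.
    """

    S0: float
    DDC: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if self.DDC < 0:
            raise ValueError(f"DDC must be >= 0, got {self.DDC}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def mem_signal(p: MonoExpParams, b) -> np.ndarray | float:
    """Mono-exponential signal S0 * exp(-b * ADC); scalar in, scalar out."""
    barr = _check_b(b)
    out = p.S0 * np.exp(-barr * p.ADC)
    return out if barr.ndim else float(out)


def bem_signal(p: BiExpParams, b) -> np.ndarray | float:
    """IVIM signal S0 * [f * exp(-b * D*) + (1 - f) * exp(-b * D)]."""
    barr = _check_b(b)
    out = p.S0 * (p.f * np.exp(-barr * p.Dstar) + (1.0 - p.f) * np.exp(-barr * p.D))
    return out if barr.ndim else float(out)


def sem_signal(p: StretchedExpParams, b) -> np.ndarray | float:
    """Stretched-exponential signal S0 * exp(-(b * DDC)**alpha)."""
    barr = _check_b(b)
    out = p.S0 * np.exp(-np.power(barr * p.DDC, p.alpha))
    return out if barr.ndim else float(out)
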