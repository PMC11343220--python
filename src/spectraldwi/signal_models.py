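"""Closed-form multi-component DWI signal models.

A voxel's diffusion-weighted signal is modelled as a sum of exponential
decays, one per physiologic component (tissue parenchyma, tubular flow,
vascular pseudo-diffusion).  Two forms are provided:

* Gaussian (Brownian): ``S(b)/S0 = sum_i f_i * exp(-b * D_i)``
* stretched-exponential (anomalous): ``S(b)/S0 = sum_i f_i * exp(-(b*D_i)**gamma_i)``

with ``gamma < 1`` sub-diffusion, ``gamma = 1`` Brownian and ``gamma > 1``
super-diffusion (ballistic at 2).  The stretch applies to the dimensionless
product ``b*D``, which makes the Gaussian model the exact ``gamma = 1``
special case and keeps the exponent unit-free.

Units are strictly internal: ``D`` in mm^2/s, ``b`` in s/mm^2.  Reporting
layers convert to the conventional 1e-3 mm^2/s display scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ComponentParams",
    "DecayCurve",
    "REGIME_B_CENTERS",
    "gaussian_signal",
    "anomalous_signal",
    "effective_gaussian_fD",
]

#: b-value (s/mm^2) at the center of each diffusion regime, used when the
#: b-dependent anomalous product f*D^gamma*b^(gamma-1) is summarized by a
#: single number per regime.
REGIME_B_CENTERS = {"tissue": 500.0, "tubule": 100.0, "vascular": 10.0}


@dataclass(frozen=True)
class ComponentParams:
    """Signal fraction, diffusion coefficient and anomalous exponent of one component.

    Parameters
    ----------
    f : float
        Signal fraction in [0, 1].
    D : float
        Diffusion coefficient in mm^2/s (>= 0).
    gamma : float, optional
        Anomalous stretch exponent (> 0).  Default 1 (Brownian).
    """

    f: float
    D: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"signal fraction must be in [0, 1], got {self.f}")
        if self.D < 0.0:
            raise ValueError(f"diffusion coefficient must be >= 0, got {self.D}")
        if self.gamma <= 0.0:
            raise ValueError(f"anomalous exponent must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class DecayCurve:
    """A normalized multi-b-value decay curve S(b)/S0 for one voxel."""

    bvalues: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if b.ndim != 1 or s.ndim != 1 or b.size != s.size:
            raise ValueError("bvalues and signal must be 1-D arrays of equal length")
        if b.size < 2:
            raise ValueError("a decay curve needs at least two b-values")
        if b[0] != 0.0:
            raise ValueError("the first b-value must be 0 (the S0 reference)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.bvalues.size


def _validate_components(
    components: Sequence[ComponentParams], require_normalized: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(components) == 0:
        raise ValueError("at least one component is required")
    f = np.array([c.f for c in components], dtype=float)
    D = np.array([c.D for c in components], dtype=float)
    g = np.array([c.gamma for c in components], dtype=float)
    if require_normalized and abs(f.sum() - 1.0) > 1e-8:
        raise ValueError(
            f"signal fractions must sum to 1 (got {f.sum():.6g}); "
            "normalize before calling the signal generators"
        )
    return f, D, g


def _validate_bvalues(bvalues: Iterable[float]) -> np.ndarray:
    b = np.asarray(list(bvalues) if not isinstance(bvalues, np.ndarray) else bvalues,
                   dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def gaussian_signal(
    components: Sequence[ComponentParams],
    bvalues: Iterable[float],
    *,
    require_normalized: bool = True,
) -> DecayCurve:
    """Multi-exponential Gaussian signal ``S(b) = sum_i f_i exp(-b D_i)``.

    Fractions are validated, not normalized here: normalization is an explicit
    step owned by the caller (simulator or fitter).  Set
    ``require_normalized=False`` to evaluate unnormalized mixtures, e.g. when
    reconstructing a fitted model whose fractions do not sum to one.
    """
    f, D, _ = _validate_components(components, require_normalized)
    b = _validate_bvalues(bvalues)
    s = np.exp(-np.outer(b, D)) @ f
    return DecayCurve(b, s)


def anomalous_signal(
    components: Sequence[ComponentParams],
    bvalues: Iterable[float],
    *,
    require_normalized: bool = True,
) -> DecayCurve:
    """Stretched-exponential signal ``S(b) = sum_i f_i exp(-(b D_i)**gamma_i)``.

    Collapses exactly onto :func:`gaussian_signal` when every component has
    ``gamma == 1``.
    """
    f, D, g = _validate_components(components, require_normalized)
    b = _validate_bvalues(bvalues)
    bD = np.outer(b, D)  # dimensionless argument of the stretch
    s = np.exp(-np.power(bD, g[None, :])) @ f
    return DecayCurve(b, s)


def effective_gaussian_fD(f: float, D: float, gamma: float, b_ref: float) -> float:
    """Gaussian-equivalent flow product of an anomalous component.

    Around a reference b-value the stretched exponential
    ``exp(-(b*D)**gamma) = exp(-b * D**gamma * b**(gamma-1))`` behaves like a
    Gaussian decay with apparent coefficient ``D**gamma * b_ref**(gamma-1)``,
    so the component's flow product is approximated by
    ``f * D**gamma * b_ref**(gamma-1)`` (mm^2/s scaled by the fraction).

    For ``gamma == 1`` this is exactly ``f * D`` independent of ``b_ref``.
    ``b_ref`` defaults per regime are given by :data:`REGIME_B_CENTERS`.
    """
    if b_ref < 0:
        raise ValueError("b_ref must be non-negative")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if gamma == 1.0:
        return f * D
    if b_ref == 0.0:
        raise ValueError("b_ref = 0 is singular for gamma != 1")
    return f * D**gamma * b_ref ** (gamma - 1.0)
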