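"""Fitness maps from substitution loads to relative cell fitness.

A diploid host cell carrying ``n`` cytoplasmic genomes is assigned a relative
fitness that depends only on the *total* number of beneficial (x) and
deleterious (y) substitutions summed over its genomes.  Both axes saturate at
``X = n_ref * gamma_ref`` total substitutions (a cell whose genomes carry an
average of ``gamma_ref`` substitutions each):

* beneficial axis: fitness ``1 - s_b`` at x = 0, rising to exactly 1 at x >= X;
* deleterious axis: fitness 1 at y = 0, falling to exactly ``1 - s_d`` at y >= X.

Between the endpoints the curve is an endpoint-anchored power law in
``u = min(x, X) / X``: convex ("concave_up"), affine ("linear") or concave
("concave_down") for the beneficial axis, and slow-then-steep concave
("concave_down") or affine for the deleterious axis.  The two axes combine
additively as deviations from 1, floored at 0 so the result remains a valid
sampling weight.

Free-living single-genome cells use the linear forms with a scaling factor
``s_FL``: one substitution on a free-living genome moves fitness ``s_FL``
times as far as one substitution on a single cytoplasmic genome moves its
host's fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FitnessSpec",
    "beneficial_factor",
    "deleterious_factor",
    "cell_fitness",
    "free_living_fitness",
]

_BENEFICIAL_SHAPES = ("concave_up", "linear", "concave_down")
_DELETERIOUS_SHAPES = ("concave_down", "linear")

# Exponent of the endpoint-anchored power law for each named curvature.
# u**2 bends below the chord (convex rise / slow-then-steep fall); u**0.5
# bends above it.
_BENEFICIAL_EXPONENT = {"concave_up": 2.0, "linear": 1.0, "concave_down": 0.5}
_DELETERIOUS_EXPONENT = {"concave_down": 2.0, "linear": 1.0}


@dataclass(frozen=True)
class FitnessSpec:
    """Parameters of the cell-level fitness map.

    Parameters
    ----------
    s_b, s_d
        Selection coefficients of the beneficial and deleterious axes,
        ``0 <= s < 1``.  ``1 - s_b`` is the fitness of a cell with zero
        beneficial substitutions; ``1 - s_d`` the fitness of a cell whose
        deleterious load has saturated.
    beneficial_shape, deleterious_shape
        Curvature of each axis between its endpoints.
    n_ref, gamma_ref
        Reference genomes-per-cell count and per-genome substitution target;
        their product ``X = n_ref * gamma_ref`` is the saturation load of
        both axes.
    s_FL
        Free-living scaling: fold-effect of one substitution on a free-living
        genome relative to one substitution on a single cytoplasmic genome.
        Only used by :func:`free_living_fitness`.
    """

    s_b: float = 0.1
    s_d: float = 0.1
    beneficial_shape: str = "linear"
    deleterious_shape: str = "concave_down"
    n_ref: int = 50
    gamma_ref: int = 5
    s_FL: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_b < 1.0) or not (0.0 <= self.s_d < 1.0):
            raise ValueError("selection coefficients must lie in [0, 1)")
        if self.beneficial_shape not in _BENEFICIAL_SHAPES:
            raise ValueError(f"unknown beneficial_shape {self.beneficial_shape!r}")
        if self.deleterious_shape not in _DELETERIOUS_SHAPES:
            raise ValueError(f"unknown deleterious_shape {self.deleterious_shape!r}")
        if self.n_ref <= 0 or self.gamma_ref <= 0:
            raise ValueError("n_ref and gamma_ref must be positive")
        if self.s_FL < 1.0:
            raise ValueError("s_FL must be >= 1")

    @property
    def saturation(self) -> int:
        """Total substitutions at which either fitness axis saturates."""
        return self.n_ref * self.gamma_ref

    def with_linear_shapes(self) -> "FitnessSpec":
        return replace(self, beneficial_shape="linear", deleterious_shape="linear")


def _check_nonnegative(value, name: str) -> np.ndarray:
    arr = np.asarray(value)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def beneficial_factor(x, spec: FitnessSpec):
    """Beneficial fitness component in ``[1 - s_b, 1]``.

    Accepts scalars or arrays of total beneficial substitution counts.
    """
    arr = _check_nonnegative(x, "beneficial substitution count")
    X = spec.saturation
    u = np.minimum(arr, X) / X
    theta = _BENEFICIAL_EXPONENT[spec.beneficial_shape]
    out = (1.0 - spec.s_b) + spec.s_b * u**theta
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def deleterious_factor(y, spec: FitnessSpec):
    """Deleterious fitness component in ``[1 - s_d, 1]``."""
    arr = _check_nonnegative(y, "deleterious substitution count")
    X = spec.saturation
    u = np.minimum(arr, X) / X
    theta = _DELETERIOUS_EXPONENT[spec.deleterious_shape]
    out = 1.0 - spec.s_d * u**theta
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def cell_fitness(x, y, spec: FitnessSpec):
    """Relative fitness of a cell with total loads ``(x, y)``.

    The two axes are additive in their deviations from 1,
    ``w = w_b(x) + w_d(y) - 1``, floored at 0 so that fitness values remain
    valid sampling weights.
    """
    w = beneficial_factor(x, spec) + deleterious_factor(y, spec) - 1.0
    out = np.maximum(w, 0.0)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def free_living_fitness(alpha, kappa, spec: FitnessSpec):
    """Relative fitness of a free-living cell from its single genome's loads.

    Requires linear shapes.  Each substitution moves fitness by
    ``s_FL * s / X`` where ``X = n_ref * gamma_ref`` references the
    cytoplasmic comparison, clamped to the same ``[1 - s, 1]`` band per axis
    and combined additively as in :func:`cell_fitness`.
    """
    if spec.beneficial_shape != "linear" or spec.deleterious_shape != "linear":
        raise ValueError(
            "free-living fitness is defined for linear shapes only; got "
            f"({spec.beneficial_shape}, {spec.deleterious_shape})"
        )
    a = _check_nonnegative(alpha, "alpha")
    k = _check_nonnegative(kappa, "kappa")
    X = spec.saturation
    w_b = np.minimum(1.0, (1.0 - spec.s_b) + spec.s_b * spec.s_FL * a / X)
    w_d = np.maximum(1.0 - spec.s_d, 1.0 - spec.s_d * spec.s_FL * k / X)
    out = np.maximum(w_b + w_d - 1.0, 0.0)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)
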