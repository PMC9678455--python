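"""Prior regimes for the variance components and fixed effects.

Two matched regimes are compared throughout the package:

* **uniform** — flat priors on the variances themselves:
  ``sigma2_U ~ U(0, 0.23)``, ``sigma2_eC ~ U(0, 0.69)``,
  ``sigma2_eU ~ U(0, 0.69)``.
* **gamma** — informative gamma priors on the variances:
  ``sigma2_U ~ G(13, 0.03)``, ``sigma2_eC ~ G(13, 0.03)``,
  ``sigma2_eU ~ G(9, 0.03)``.

The gamma hyperparameters are read as shape--scale on the variance scale,
under which G(13, 0.03) has mean 0.39 and G(9, 0.03) has mean 0.27 --
magnitudes on the order of the residual variances of the truth model.  A
shape--rate reading is available via ``gamma_parameterization="rate"`` for
sensitivity analysis, but it concentrates the priors orders of magnitude
away from any plausible variance and is not the default.

Fixed effects always receive normal priors: the control mean
``b0 ~ N(3, 2.25)`` and the treatment effect ``b1 ~ N(0, 1)``.  Cluster
effects are ``u_j ~ N(0, sigma2_U)`` as part of the model itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "VariancePrior",
    "FixedEffectPriors",
    "PriorRegime",
    "canonical_regime",
    "log_density",
]


@dataclass(frozen=True)
class VariancePrior:
    """Prior on a single variance component.

    Exactly the fields of the active family are consulted: ``shape`` and
    ``scale`` for ``family="gamma"``, ``upper`` for ``family="uniform"``.
    """

    family: str
    shape: float | None = None
    scale: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family == "gamma":
            if self.shape is None or self.scale is None:
                raise ValueError("gamma prior requires shape and scale")
            if self.shape <= 0 or self.scale <= 0:
                raise ValueError("gamma shape and scale must be positive")
        elif self.family == "uniform":
            if self.upper is None:
                raise ValueError("uniform prior requires an upper bound")
            if self.upper <= 0:
                raise ValueError("uniform upper bound must be positive")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "VariancePrior":
        return cls(family="gamma", shape=shape, scale=scale)

    @classmethod
    def uniform(cls, upper: float) -> "VariancePrior":
        return cls(family="uniform", upper=upper)

    @property
    def mean(self) -> float:
        """Prior mean (shape * scale for gamma, upper / 2 for uniform)."""
        if self.family == "gamma":
            return self.shape * self.scale
        return self.upper / 2.0

    def to_dict(self) -> dict:
        out = {"family": self.family}
        if self.family == "gamma":
            out.update(shape=self.shape, scale=self.scale)
        else:
            out.update(upper=self.upper)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "VariancePrior":
        return cls(
            family=d["family"],
            shape=d.get("shape"),
            scale=d.get("scale"),
            upper=d.get("upper"),
        )


@dataclass(frozen=True)
class FixedEffectPriors:
    """Normal priors for the control mean b0 and treatment effect b1."""

    b0_mean: float = 3.0
    b0_var: float = 2.25
    b1_mean: float = 0.0
    b1_var: float = 1.0

    def __post_init__(self) -> None:
        if self.b0_var <= 0 or self.b1_var <= 0:
            raise ValueError("fixed-effect prior variances must be positive")

    def to_dict(self) -> dict:
        return {
            "b0_mean": self.b0_mean,
            "b0_var": self.b0_var,
            "b1_mean": self.b1_mean,
            "b1_var": self.b1_var,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixedEffectPriors":
        return cls(**d)


@dataclass(frozen=True)
class PriorRegime:
    """A matched set of priors for (sigma2_U, sigma2_eC, sigma2_eU) plus
    the fixed-effect priors."""

    prior_U: VariancePrior
    prior_eC: VariancePrior
    prior_eU: VariancePrior
    fixed: FixedEffectPriors = field(default_factory=FixedEffectPriors)

    @property
    def family(self) -> str:
        """The shared family when all three variance priors agree, else
        ``"mixed"``."""
        fams = {self.prior_U.family, self.prior_eC.family, self.prior_eU.family}
        return fams.pop() if len(fams) == 1 else "mixed"

    def to_dict(self) -> dict:
        return {
            "prior_U": self.prior_U.to_dict(),
            "prior_eC": self.prior_eC.to_dict(),
            "prior_eU": self.prior_eU.to_dict(),
            "fixed": self.fixed.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorRegime":
        return cls(
            prior_U=VariancePrior.from_dict(d["prior_U"]),
            prior_eC=VariancePrior.from_dict(d["prior_eC"]),
            prior_eU=VariancePrior.from_dict(d["prior_eU"]),
            fixed=FixedEffectPriors.from_dict(d["fixed"]),
        )


def canonical_regime(
    family: str,
    gamma_parameterization: str = "scale",
    swap_gamma_residual_priors: bool = False,
) -> PriorRegime:
    """The two canonical prior regimes.

    Parameters
    ----------
    family
        ``"gamma"`` or ``"uniform"``.
    gamma_parameterization
        ``"scale"`` (default) reads G(a, b) as shape--scale; ``"rate"``
        reads b as a rate, i.e. scale ``1/b``.
    swap_gamma_residual_priors
        If True, exchange the gamma priors of the two residual variances
        (G(9, 0.03) onto sigma2_eC and G(13, 0.03) onto sigma2_eU), which
        aligns each prior mean with its own arm's truth value.  Off by
        default; the canonical regime assigns them the other way around.
    """
    if family == "uniform":
        return PriorRegime(
            prior_U=VariancePrior.uniform(0.23),
            prior_eC=VariancePrior.uniform(0.69),
            prior_eU=VariancePrior.uniform(0.69),
        )
    if family == "gamma":
        if gamma_parameterization == "scale":
            second = lambda b: b  # noqa: E731
        elif gamma_parameterization == "rate":
            second = lambda b: 1.0 / b  # noqa: E731
        else:
            raise ValueError(
                f"unknown gamma parameterization {gamma_parameterization!r}"
            )
        g13 = VariancePrior.gamma(13.0, second(0.03))
        g9 = VariancePrior.gamma(9.0, second(0.03))
        if swap_gamma_residual_priors:
            return PriorRegime(prior_U=g13, prior_eC=g9, prior_eU=g13)
        return PriorRegime(prior_U=g13, prior_eC=g13, prior_eU=g9)
    raise ValueError(f"unknown prior family {family!r}")


def log_density(prior: VariancePrior, sigma2: float) -> float:
    """Log prior density at a variance value.

    Returns ``-inf`` (zero density) for any value outside the support,
    including non-positive values, so samplers may propose freely.
    """
    if sigma2 <= 0.0:
        return -math.inf
    if prior.family == "uniform":
        return -math.log(prior.upper) if sigma2 < prior.upper else -math.inf
    k, theta = prior.shape, prior.scale
    return (
        (k - 1.0) * math.log(sigma2)
        - sigma2 / theta
        - k * math.log(theta)
        - math.lgamma(k)
    )
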