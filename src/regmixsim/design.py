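"""Factorial simulation design for the two-class regression mixture study.

The design crosses four model families (single- or two-predictor, with or
without a class-intercept difference of 1), three levels of residual-variance
separation, four sample sizes and two class-proportion settings, giving
4 x 3 x 4 x 2 = 96 conditions.  Population values follow the convention that
within-class Var(Y) = 1 in the single-predictor families, so the residual
variance is 1 - slope^2 there; the two-predictor slopes are correlation-adjusted
rescalings of the single-predictor ones with their own printed residual
variances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "ClassSpec",
    "Condition",
    "MODEL_FAMILIES",
    "SEPARATIONS",
    "SAMPLE_SIZES",
    "CLASS_PROPORTIONS",
    "POPULATION_SPECS",
    "enumerate_conditions",
    "get_condition",
    "conditions_to_json",
]

MODEL_FAMILIES = (
    "single_no_intdiff",
    "single_intdiff1",
    "two_no_intdiff",
    "two_intdiff1",
)
SEPARATIONS = ("large", "moderate", "none")
SAMPLE_SIZES = (300, 500, 1000, 2000)
CLASS_PROPORTIONS = ((0.5, 0.5), (0.75, 0.25))

# Population values per (family, separation): per-class slope values and
# residual variances.  Single-predictor families satisfy sigma_k^2 = 1 - beta_k^2
# exactly; the two-predictor families use one common slope for both predictors
# within a class.  Intercepts are (0, 0) in the no-difference families and
# (1, 0) in the intercept-difference families.
_SINGLE = {
    "large": ((0.7,), (0.2,), 0.51, 0.96),
    "moderate": ((0.7,), (0.4,), 0.51, 0.84),
    "none": ((0.5,), (-0.5,), 0.75, 0.75),
}
_TWO = {
    "large": ((0.6261, 0.6261), (0.17889, 0.17889), 0.02, 0.92),
    "moderate": ((0.6261, 0.6261), (0.35777, 0.35777), 0.02, 0.68),
    "none": ((0.44721, 0.44721), (-0.44721, -0.44721), 0.5, 0.5),
}

POPULATION_SPECS = {
    "single_no_intdiff": {"slopes": _SINGLE, "intercepts": (0.0, 0.0)},
    "single_intdiff1": {"slopes": _SINGLE, "intercepts": (1.0, 0.0)},
    "two_no_intdiff": {"slopes": _TWO, "intercepts": (0.0, 0.0)},
    "two_intdiff1": {"slopes": _TWO, "intercepts": (1.0, 0.0)},
}


@dataclass(frozen=True)
class ClassSpec:
    """Population parameters of one latent class.

    Parameters
    ----------
    slopes : tuple of float
        Regression weight per predictor.
    intercept : float
    residual_variance : float
        Within-class residual variance, strictly positive.
    proportion : float
        Mixing proportion, in (0, 1].
    """

    slopes: tuple[float, ...]
    intercept: float
    residual_variance: float
    proportion: float

    def __post_init__(self) -> None:
        if self.residual_variance <= 0:
            raise ValueError("residual_variance must be positive")
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must lie in [0, 1]")


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design."""

    model_family: str
    separation: str
    class_specs: tuple[ClassSpec, ClassSpec]
    n: int
    predictor_correlation: float
    n_replications: int = 100
    condition_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.separation not in SEPARATIONS:
            raise ValueError(f"unknown separation {self.separation!r}")
        if len(self.class_specs) != 2:
            raise ValueError("exactly two classes are supported")
        total = sum(cs.proportion for cs in self.class_specs)
        if abs(total - 1.0) > 1e-12:
            raise ValueError("class proportions must sum to 1")
        if self.n < 1:
            raise ValueError("n must be positive")
        p = len(self.class_specs[0].slopes)
        if any(len(cs.slopes) != p for cs in self.class_specs):
            raise ValueError("slope vectors must share one predictor count")
        if not self.condition_id:
            object.__setattr__(self, "condition_id", _condition_id(self))

    @property
    def n_predictors(self) -> int:
        return len(self.class_specs[0].slopes)

    @property
    def proportions(self) -> tuple[float, float]:
        return tuple(cs.proportion for cs in self.class_specs)

    def to_dict(self) -> dict:
        return asdict(self)


def _proportion_tag(p1: float) -> str:
    return "balanced" if abs(p1 - 0.5) < 1e-12 else "unbalanced"


def _condition_id(cond: Condition) -> str:
    tag = _proportion_tag(cond.class_specs[0].proportion)
    return f"{cond.model_family}-{cond.separation}-n{cond.n}-{tag}"


def make_condition(
    family: str,
    separation: str,
    n: int,
    proportions: tuple[float, float] = (0.5, 0.5),
    n_replications: int = 100,
) -> Condition:
    """Build the design cell with the population values for (family, separation)."""
    spec = POPULATION_SPECS[family]
    s1, s2, rv1, rv2 = spec["slopes"][separation]
    i1, i2 = spec["intercepts"]
    rho = 0.5 if len(s1) == 2 else 0.0
    return Condition(
        model_family=family,
        separation=separation,
        class_specs=(
            ClassSpec(slopes=s1, intercept=i1, residual_variance=rv1, proportion=proportions[0]),
            ClassSpec(slopes=s2, intercept=i2, residual_variance=rv2, proportion=proportions[1]),
        ),
        n=n,
        predictor_correlation=rho,
        n_replications=n_replications,
    )


def enumerate_conditions(n_replications: int = 100) -> list[Condition]:
    """All 96 cells of the design, in a fixed deterministic order."""
    out = []
    for family in MODEL_FAMILIES:
        for separation in SEPARATIONS:
            for n in SAMPLE_SIZES:
                for props in CLASS_PROPORTIONS:
                    out.append(make_condition(family, separation, n, props, n_replications))
    return out


def get_condition(condition_id: str, n_replications: int = 100) -> Condition:
    """Look a condition up by its id (e.g. ``two_no_intdiff-large-n2000-balanced``)."""
    for cond in enumerate_conditions(n_replications):
        if cond.condition_id == condition_id:
            return cond
    raise KeyError(f"no such condition: {condition_id!r}")


def conditions_to_json(conditions: list[Condition] | None = None) -> str:
    """Serialize the condition grid as JSON (for manifests and export)."""
    conds = enumerate_conditions() if conditions is None else conditions
    return json.dumps([c.to_dict() for c in conds], indent=2)
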