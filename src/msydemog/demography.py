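"""Piecewise demographic models for a single haploid locus.

Five single-population histories (M1-M5) describe the male effective
population size backwards in time, built from uniform priors on sizes and
change times.  All sizes are haploid effective numbers of males (the locus
is the non-recombining MSY), times are in generations before present with a
generation time of 30 years, and the onset of the first demographic change
(T1 = T2 + LEX) is bounded by the Last Glacial Maximum (~20,000 years, i.e.
~666.7 generations).

Exponential size change between two epoch endpoint sizes is log-linear in
size, the standard meaning of exponential growth/decline at constant rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GENERATION_TIME_YEARS",
    "LOCUS_LENGTH_BP",
    "LGM_BOUND_GENERATIONS",
    "MU_MEAN",
    "MU_SD",
    "MODEL_IDS",
    "UniformPrior",
    "NormalPrior",
    "ModelSpec",
    "model_spec",
    "DemographyParams",
    "Epoch",
    "PiecewiseDemography",
    "sample_prior",
    "build_demography",
]

#: Generation time used to convert between years and generations.
GENERATION_TIME_YEARS = 30.0

#: Length in bp of the resequenced MSY regions after depth filtering.
LOCUS_LENGTH_BP = 3_724_156

#: Upper bound for the onset of the first demographic change (LGM ~20 kya).
LGM_BOUND_GENERATIONS = 20_000.0 / GENERATION_TIME_YEARS

#: Per-site per-generation mutation-rate prior: Normal mean, and sd derived
#: from the 95% CI 2.77-3.26e-8 as half-width / 1.96.
MU_MEAN = 3.01e-8
MU_SD = (3.26e-8 - 2.77e-8) / 2.0 / 1.96

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class UniformPrior:
    """Uniform prior over (lower, upper) in the parameter's own units."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"uniform prior requires lower < upper, got ({self.lower}, {self.upper})"
            )

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lower, self.upper))

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior truncated to (0, inf); used for the mutation rate."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("normal prior requires positive mean and sd")

    def sample(self, rng: np.random.Generator) -> float:
        while True:
            x = float(rng.normal(self.mean, self.sd))
            if x > 0:
                return x


# Parameter sets per model.  Sizes in haploid individuals, LEX/T2 in
# generations.  NA is the ancient size, NC the current size, NBOT the
# bottleneck size (M2), NER the size at the end of the reduction (M3),
# NEE the size at the end of the expansion (M5).
_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "M1": ("N",),
    "M2": ("NA", "NBOT", "LEX", "T2"),
    "M3": ("NA", "NER", "NC", "LEX", "T2"),
    "M4": ("NA", "NC", "LEX", "T2"),
    "M5": ("NA", "NEE", "NC", "LEX", "T2"),
}

_LEX_PRIOR = UniformPrior(5.0, 634.0)
_T2_PRIOR = UniformPrior(0.0, 30.0)

_DEFAULT_PRIORS: dict[str, dict[str, UniformPrior]] = {
    "M1": {"N": UniformPrior(20.0, 20_000.0)},
    "M2": {
        "NA": UniformPrior(1_001.0, 20_000.0),
        "NBOT": UniformPrior(20.0, 1_000.0),
        "LEX": _LEX_PRIOR,
        "T2": _T2_PRIOR,
    },
    "M3": {
        "NA": UniformPrior(1_001.0, 20_000.0),
        "NER": UniformPrior(20.0, 1_000.0),
        "NC": UniformPrior(1_001.0, 20_000.0),
        "LEX": _LEX_PRIOR,
        "T2": _T2_PRIOR,
    },
    "M4": {
        "NA": UniformPrior(20.0, 1_000.0),
        "NC": UniformPrior(1_001.0, 20_000.0),
        "LEX": _LEX_PRIOR,
        "T2": _T2_PRIOR,
    },
    "M5": {
        "NA": UniformPrior(20.0, 1_000.0),
        "NEE": UniformPrior(1_001.0, 20_000.0),
        "NC": UniformPrior(20.0, 1_000.0),
        "LEX": _LEX_PRIOR,
        "T2": _T2_PRIOR,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A demographic model: identifier, priors, and locus constants.

    Parameters
    ----------
    model_id
        One of ``M1``..``M5``.
    priors
        Uniform prior per demographic parameter.  The parameter set must
        match the model (M1: N; M2: NA, NBOT, LEX, T2; M3: NA, NER, NC,
        LEX, T2; M4: NA, NC, LEX, T2; M5: NA, NEE, NC, LEX, T2).
    """

    model_id: str
    priors: dict[str, UniformPrior]
    generation_time_years: float = GENERATION_TIME_YEARS
    locus_length_bp: int = LOCUS_LENGTH_BP
    mu_prior: NormalPrior = field(default_factory=lambda: NormalPrior(MU_MEAN, MU_SD))

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_PARAMS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        expected = set(_MODEL_PARAMS[self.model_id])
        if set(self.priors) != expected:
            raise ValueError(
                f"{self.model_id} requires parameters {sorted(expected)}, "
                f"got {sorted(self.priors)}"
            )
        for name, prior in self.priors.items():
            if prior.lower < 0:
                raise ValueError(f"prior for {name} must have non-negative bounds")
            if name not in ("LEX", "T2") and prior.lower <= 0:
                raise ValueError(f"size prior for {name} must be positive")
        if self.locus_length_bp < 1:
            raise ValueError("locus_length_bp must be >= 1")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be positive")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return _MODEL_PARAMS[self.model_id]


def model_spec(model_id: str, **prior_overrides: UniformPrior) -> ModelSpec:
    """Build a ModelSpec with the default priors, optionally overridden.

    >>> spec = model_spec("M1")
    >>> spec.priors["N"].upper
    20000.0
    """
    if model_id not in _DEFAULT_PRIORS:
        raise ValueError(f"unknown model_id {model_id!r}")
    priors = dict(_DEFAULT_PRIORS[model_id])
    for name, prior in prior_overrides.items():
        if name not in priors:
            raise ValueError(f"{model_id} has no parameter {name!r}")
        priors[name] = prior
    return ModelSpec(model_id=model_id, priors=priors)


@dataclass(frozen=True)
class DemographyParams:
    """One draw from a model's priors, plus the replicate's mutation rate."""

    model_id: str
    values: dict[str, float]
    mu: float

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_PARAMS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if set(self.values) != set(_MODEL_PARAMS[self.model_id]):
            raise ValueError("parameter values do not match model")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.model_id != "M1":
            t1 = self.values["T2"] + self.values["LEX"]
            if t1 > LGM_BOUND_GENERATIONS + 1e-9:
                raise ValueError(
                    f"T1 = T2 + LEX = {t1:.2f} exceeds the LGM bound of "
                    f"{LGM_BOUND_GENERATIONS:.2f} generations"
                )

    @property
    def t1(self) -> float:
        """Onset of the first demographic change, T1 = T2 + LEX (generations)."""
        if self.model_id == "M1":
            return math.nan
        return self.values["T2"] + self.values["LEX"]


def sample_prior(spec: ModelSpec, rng: np.random.Generator | int) -> DemographyParams:
    """Draw one parameter vector independently from the model's priors.

    The mutation rate is drawn from the truncated-Normal prior; T1 is derived
    as T2 + LEX, never sampled.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = {name: spec.priors[name].sample(rng) for name in spec.parameter_names}
    mu = spec.mu_prior.sample(rng)
    return DemographyParams(model_id=spec.model_id, values=values, mu=mu)


@dataclass(frozen=True)
class Epoch:
    """One epoch of a piecewise trajectory, in backwards time.

    ``size(t)`` interpolates log-linearly between ``size_recent`` at
    ``t_recent`` and ``size_ancient`` at ``t_ancient``; a constant epoch has
    equal endpoint sizes.
    """

    t_recent: float
    t_ancient: float  # may be math.inf
    size_recent: float
    size_ancient: float

    def __post_init__(self) -> None:
        if self.t_recent < 0 or self.t_ancient <= self.t_recent:
            raise ValueError("epoch times must satisfy 0 <= t_recent < t_ancient")
        if self.size_recent <= 0 or self.size_ancient <= 0:
            raise ValueError("epoch sizes must be positive")
        if math.isinf(self.t_ancient) and self.size_recent != self.size_ancient:
            raise ValueError("the most ancient epoch must be constant")

    @property
    def constant(self) -> bool:
        return self.size_recent == self.size_ancient

    @property
    def rate(self) -> float:
        """Backward-time exponential rate r with N(t) = size_recent * exp(r (t - t_recent))."""
        if self.constant:
            return 0.0
        return math.log(self.size_ancient / self.size_recent) / (self.t_ancient - self.t_recent)

    def size(self, t: float) -> float:
        if self.constant:
            return self.size_recent
        return self.size_recent * math.exp(self.rate * (t - self.t_recent))


@dataclass(frozen=True)
class PiecewiseDemography:
    """Haploid effective size through backwards time as contiguous epochs."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("demography requires at least one epoch")
        if self.epochs[0].t_recent != 0.0:
            raise ValueError("first epoch must start at t = 0")
        if not math.isinf(self.epochs[-1].t_ancient):
            raise ValueError("last epoch must extend to +inf")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not math.isclose(a.t_ancient, b.t_recent, rel_tol=0, abs_tol=1e-9):
                raise ValueError("epochs must be contiguous")

    def size(self, t: float) -> float:
        """Effective size N(t) at t generations before present."""
        if t < 0:
            raise ValueError("t must be >= 0")
        for ep in self.epochs:
            if t < ep.t_ancient:
                return ep.size(t)
        return self.epochs[-1].size_ancient


def build_demography(params: DemographyParams) -> PiecewiseDemography:
    """Compile a parameter draw into its piecewise size trajectory.

    Backwards in time: M1 is a single constant epoch; M2/M4 are constant at
    the recent size on [0, T2), exponential between the recent and ancient
    sizes on [T2, T2+LEX), then constant at NA; M3/M5 are exponential on
    [0, T2) between NC and the intermediate size (NER or NEE), exponential on
    [T2, T2+LEX) between the intermediate size and NA, then constant at NA.
    Zero-width epochs (T2 = 0) are omitted.
    """
    v = params.values
    if params.model_id == "M1":
        return PiecewiseDemography((Epoch(0.0, math.inf, v["N"], v["N"]),))

    t2, lex = v["T2"], v["LEX"]
    t1 = t2 + lex
    na = v["NA"]
    if params.model_id in ("M2", "M4"):
        recent = v["NBOT"] if params.model_id == "M2" else v["NC"]
        epochs = []
        if t2 > 0:
            epochs.append(Epoch(0.0, t2, recent, recent))
        epochs.append(Epoch(t2, t1, recent, na))
        epochs.append(Epoch(t1, math.inf, na, na))
        return PiecewiseDemography(tuple(epochs))
    if params.model_id in ("M3", "M5"):
        mid = v["NER"] if params.model_id == "M3" else v["NEE"]
        epochs = []
        if t2 > 0:
            epochs.append(Epoch(0.0, t2, v["NC"], mid))
        epochs.append(Epoch(t2, t1, mid, na))
        epochs.append(Epoch(t1, math.inf, na, na))
        return PiecewiseDemography(tuple(epochs))
    raise ValueError(f"unknown model_id {params.model_id!r}")
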