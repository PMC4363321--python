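"""Parametric uncertainty models for inventory parameters.

Every uncertain quantity in a product system — a unit-process exchange or a
characterization factor — carries a :class:`DistributionSpec`: one of five
parametric families (point, lognormal, normal, triangular, uniform), the four
non-degenerate ones being the families available in common LCA databases,
with lognormal the generic assumption for background data.

The central value of a spec is always its *arithmetic mean*, because the
inventory matrices are populated with expected central values.  For the
lognormal family the parameters are the geometric mean and geometric standard
deviation; a negative geometric mean denotes a mirrored lognormal (all mass on
the negative axis), which is how uncertain consumption entries of the
technology matrix are encoded.

Total dispersion of a parameter may combine a fitted base dispersion with
three additional ln-space variance components: *inherent* uncertainty
(measurement and model inaccuracy), *spread* (variability removed by
horizontal averaging, e.g. across the farms in a survey group) and
*unrepresentativeness* (mismatch between the data's context and its use).
The components add on the ln-variance scale, the standard practice for
pedigree-style dispersion accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "DispersionComponents",
    "FitReport",
    "FittingError",
    "back_calc_sigma",
    "combine_components",
    "fit_distribution",
    "lognormal_from_mean",
    "sample",
]

KINDS = ("point", "lognormal", "normal", "triangular", "uniform")
#: Candidate order for goodness-of-fit selection; lognormal first so that
#: ties fall back to the generic background-database assumption.
FIT_CANDIDATES = ("lognormal", "normal", "triangular", "uniform")

_MAX_REJECTIONS = 1000


class FittingError(ValueError):
    """Raised when a distribution cannot be fitted to the given samples."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric distribution attached to one parameter.

    Parameters
    ----------
    kind
        One of ``point``, ``lognormal``, ``normal``, ``triangular``,
        ``uniform``.
    p1, p2, p3
        Family parameters: point → (value, -, -); lognormal → (geometric
        mean, geometric sd, -); normal → (mean, sd, -); triangular →
        (min, mode, max); uniform → (min, max, -).
    """

    kind: str
    p1: float
    p2: float | None = None
    p3: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "lognormal":
            if self.p2 is None or self.p2 < 1.0:
                raise ValueError("lognormal geometric sd must be >= 1")
            if self.p1 == 0.0:
                raise ValueError("lognormal geometric mean must be nonzero")
        elif self.kind == "normal":
            if self.p2 is None or self.p2 < 0.0:
                raise ValueError("normal sd must be >= 0")
        elif self.kind == "triangular":
            if self.p2 is None or self.p3 is None:
                raise ValueError("triangular needs (min, mode, max)")
            if not (self.p1 <= self.p2 <= self.p3):
                raise ValueError("triangular requires min <= mode <= max")
        elif self.kind == "uniform":
            if self.p2 is None or self.p1 > self.p2:
                raise ValueError("uniform requires min <= max")

    @property
    def mean(self) -> float:
        """Arithmetic mean — the central value used in the matrices."""
        if self.kind == "point":
            return self.p1
        if self.kind == "lognormal":
            # sign carried by the geometric mean (mirrored lognormal)
            return self.p1 * math.exp(0.5 * math.log(self.p2) ** 2)
        if self.kind == "normal":
            return self.p1
        if self.kind == "triangular":
            return (self.p1 + self.p2 + self.p3) / 3.0
        return (self.p1 + self.p2) / 2.0

    def params(self) -> tuple[float | None, float | None, float | None]:
        return (self.p1, self.p2, self.p3)


def lognormal_from_mean(mean: float, gsd: float) -> DistributionSpec:
    """Lognormal spec with a prescribed *arithmetic* mean.

    Solves gm = mean / exp(ln(gsd)^2 / 2); the sign of ``mean`` is carried by
    the geometric mean (mirrored lognormal for negative quantities).
    """
    if mean == 0.0:
        raise ValueError("lognormal cannot have zero mean")
    gm = mean / math.exp(0.5 * math.log(gsd) ** 2)
    return DistributionSpec("lognormal", gm, gsd)


@dataclass(frozen=True)
class DispersionComponents:
    """Additional ln-space variance components for one parameter."""

    inherent: float = 0.0
    spread: float = 0.0
    unrepresentativeness: float = 0.0

    def __post_init__(self) -> None:
        for name in ("inherent", "spread", "unrepresentativeness"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} variance must be >= 0")

    @property
    def total(self) -> float:
        return self.inherent + self.spread + self.unrepresentativeness


def combine_components(
    base: DistributionSpec, comp: DispersionComponents
) -> DistributionSpec:
    """Widen a base distribution by additional dispersion components.

    For a lognormal base the total ln-variance is ``ln(gsd)^2 + inherent +
    spread + unrepresentativeness``; the geometric mean is rescaled so the
    arithmetic mean (the central value) is preserved.  For a normal base the
    components are treated as squared-cv equivalents added to the base cv²;
    the mean is unchanged.
    """
    if base.kind == "lognormal":
        ln_var = math.log(base.p2) ** 2 + comp.total
        gsd = math.exp(math.sqrt(ln_var))
        return lognormal_from_mean(base.mean, gsd)
    if base.kind == "normal":
        if comp.total == 0.0:
            return base
        if base.p1 == 0.0:
            raise ValueError(
                "cannot combine cv-based components with a zero-mean normal"
            )
        cv2 = (base.p2 / abs(base.p1)) ** 2 + comp.total
        return DistributionSpec("normal", base.p1, abs(base.p1) * math.sqrt(cv2))
    raise ValueError(
        f"dispersion components combine only with lognormal or normal bases, "
        f"not {base.kind!r}; refit the parameter first"
    )


def back_calc_sigma(p05: float, p95: float) -> float:
    """Standard deviation back-calculated from a 90% uncertainty range.

    Uses sigma = (P95 - P05) / (2 * 1.645), with 1.645 the rounded normal
    z-score as conventionally printed.
    """
    if p95 < p05:
        raise ValueError(f"p95 ({p95}) must be >= p05 ({p05})")
    return (p95 - p05) / (2.0 * 1.645)


def _draw(spec: DistributionSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if spec.kind == "lognormal":
        sign = 1.0 if spec.p1 > 0 else -1.0
        return sign * rng.lognormal(math.log(abs(spec.p1)), math.log(spec.p2), size)
    if spec.kind == "normal":
        return rng.normal(spec.p1, spec.p2, size)
    if spec.kind == "triangular":
        if spec.p1 == spec.p3:
            return np.full(size, spec.p1)
        return rng.triangular(spec.p1, spec.p2, spec.p3, size)
    if spec.kind == "uniform":
        return rng.uniform(spec.p1, spec.p2, size)
    raise AssertionError(spec.kind)


def sample(
    spec: DistributionSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw from a spec, preserving the sign of its central value.

    Draws whose sign is opposite to the central value's are rejected and
    redrawn (a sign flip in a technology-matrix entry would corrupt the
    linear system).  Zero draws are accepted.  After 1000 rejections per
    value the spec is considered pathological and an error is raised.
    """
    if spec.kind == "point":
        return spec.p1 if size is None else np.full(size, spec.p1)
    n = 1 if size is None else int(size)
    out = _draw(spec, rng, n)
    central = spec.mean
    if central != 0.0 and spec.kind in ("normal", "triangular", "uniform"):
        bad = out * central < 0.0
        attempts = 0
        while bad.any():
            attempts += 1
            if attempts > _MAX_REJECTIONS:
                raise RuntimeError(
                    f"sign-preserving rejection limit exceeded for {spec}; "
                    "the distribution puts most of its mass on the wrong sign"
                )
            out[bad] = _draw(spec, rng, int(bad.sum()))
            bad = out * central < 0.0
    return float(out[0]) if size is None else out


# ---------------------------------------------------------------------------
# Goodness-of-fit selection
# ---------------------------------------------------------------------------


@dataclass
class FitReport:
    """Anderson-Darling statistics for every candidate family."""

    n: int
    statistics: dict[str, float] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)
    selected: str | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "statistics": dict(self.statistics),
            "excluded": dict(self.excluded),
            "selected": self.selected,
        }


def _anderson_darling(x: np.ndarray, cdf) -> float:
    """A² statistic of sorted data against a fully specified CDF."""
    n = len(x)
    z = np.clip(cdf(np.sort(x)), 1e-12, 1.0 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log(1.0 - z[::-1]))))


def _fit_candidate(kind: str, x: np.ndarray) -> tuple[DistributionSpec, float]:
    lo, hi = float(x.min()), float(x.max())
    width = hi - lo
    if kind == "lognormal":
        logs = np.log(x)
        gm = math.exp(float(np.mean(logs)))
        gsd = math.exp(max(float(np.std(logs, ddof=1)), 1e-12))
        spec = DistributionSpec("lognormal", gm, gsd)
        frozen = stats.lognorm(s=math.log(gsd), scale=gm)
    elif kind == "normal":
        spec = DistributionSpec("normal", float(np.mean(x)), float(np.std(x, ddof=1)))
        frozen = stats.norm(spec.p1, spec.p2)
    elif kind == "triangular":
        # extremes widened by 1% of the range; mode by likelihood grid
        a, b = lo - 0.01 * width, hi + 0.01 * width
        grid = np.linspace(a, b, 101)
        best_ll, best_m = -np.inf, 0.5 * (a + b)
        for m in grid:
            ll = stats.triang(c=(m - a) / (b - a), loc=a, scale=b - a).logpdf(x).sum()
            if ll > best_ll:
                best_ll, best_m = ll, float(m)
        spec = DistributionSpec("triangular", a, best_m, b)
        frozen = stats.triang(c=(best_m - a) / (b - a), loc=a, scale=b - a)
    elif kind == "uniform":
        a, b = lo - 0.01 * width, hi + 0.01 * width
        spec = DistributionSpec("uniform", a, b)
        frozen = stats.uniform(a, b - a)
    else:
        raise AssertionError(kind)
    return spec, _anderson_darling(x, frozen.cdf)


def fit_distribution(
    samples, candidates: tuple[str, ...] | None = None
) -> tuple[DistributionSpec, FitReport]:
    """Fit candidate families by ML and select by the Anderson-Darling test.

    Each candidate is fitted to the samples by maximum likelihood and scored
    with the Anderson-Darling A² statistic against its own fitted CDF; the
    candidate with the smallest statistic wins, ties broken by candidate
    order (lognormal first).  Lognormal is excluded (and noted in the
    report) when any sample is non-positive.

    Raises
    ------
    FittingError
        With fewer than 5 samples, or when every candidate is excluded.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if len(x) < 5:
        raise FittingError(
            f"refusing to fit {len(x)} samples (minimum 5); supply a spec instead"
        )
    report = FitReport(n=len(x))
    if np.ptp(x) == 0.0:
        spec = DistributionSpec("point", float(x[0]))
        report.selected = "point"
        return spec, report

    cands = list(candidates) if candidates is not None else list(FIT_CANDIDATES)
    if not cands:
        raise FittingError("candidate list is empty")
    for k in cands:
        if k not in FIT_CANDIDATES:
            raise ValueError(f"unknown fit candidate {k!r}")
    if "lognormal" in cands and (x <= 0).any():
        cands.remove("lognormal")
        report.excluded["lognormal"] = "non-positive samples"
    if not cands:
        raise FittingError(
            "all candidates excluded (lognormal requires strictly positive samples)"
        )

    best_spec, best_stat, best_kind = None, np.inf, None
    for kind in cands:
        spec, a2 = _fit_candidate(kind, x)
        report.statistics[kind] = a2
        if a2 < best_stat:  # strict: ties keep earlier candidate
            best_spec, best_stat, best_kind = spec, a2, kind
    report.selected = best_kind
    return best_spec, report
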