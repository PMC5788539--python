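"""Zero-truncated-Poisson colonization-bottleneck model.

Each ephemeral resource patch (deme) is seeded by ``i`` immigrating
individuals, with ``i`` drawn from a Poisson distribution of mean ``lam``
conditioned on ``i >= 1`` (colonization did occur). If the colonizing pool
contains two genotypes at frequencies ``f`` and ``1 - f``, the probability
that a colonized deme ends up with a single genotype is

    p_single(lam, f) = sum_{i>=1} lam^i e^{-lam} (f^i + (1-f)^i)
                                  / (i! (1 - e^{-lam}))

The mean founder number ``lam`` is estimated by solving
``p_single(lam, f) = 1 - p_multi`` for the observed (or corrected)
proportion ``p_multi`` of demes carrying more than one genotype, either at
a fixed ``f`` or averaging over a prior on ``f`` (one draw per Monte-Carlo
trial). The series is truncated at ``i = I_MAX`` founders and the solver is
bounded by the same cap; for extreme allele frequencies the equation has no
root below the cap and the estimate is clipped there (flagged). This
clipping is deliberate, documented behaviour: it is what bounds the
heavy-tailed uniform-prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError

#: Default summation/solver cap on the founder number.
I_MAX: int = 200

#: Default solver bracket for lambda.
DEFAULT_BOUNDS: tuple[float, float] = (1e-6, float(I_MAX))

__all__ = [
    "I_MAX",
    "DEFAULT_BOUNDS",
    "FrequencyPrior",
    "FounderFit",
    "p_single_truncated",
    "p_single_closed_form",
    "fit_lambda",
    "fit_lambda_mc",
]


def _validate_lambda(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ConfigError("lambda must be > 0")
    return lam


def p_single_truncated(lam, f, i_max: int = I_MAX):
    """Probability that a colonized deme carries a single genotype.

    Evaluates the zero-truncated Poisson mixture series up to ``i_max``
    founders. The Poisson summand is accumulated by the multiplicative
    recurrence ``term_i = term_{i-1} * lam / i`` starting from
    ``term_0 = exp(-lam)``; no factorial is ever formed. Accepts scalars or
    broadcastable arrays; ``f = 1`` (monomorphic source) returns exactly 1
    because ``(1-f)^i`` vanishes for every ``i >= 1``.
    """
    lam = _validate_lambda(lam)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ConfigError("f must lie in [0, 1]")
    if i_max < 1:
        raise ConfigError("i_max must be >= 1")
    lam_b, f_b = np.broadcast_arrays(lam, f)
    term = np.exp(-lam_b)            # Poisson pmf at i = 0
    f_pow = np.ones_like(term)
    g_pow = np.ones_like(term)
    total = np.zeros_like(term)
    for i in range(1, i_max + 1):
        term = term * lam_b / i
        f_pow = f_pow * f_b
        g_pow = g_pow * (1.0 - f_b)
        total += term * (f_pow + g_pow)
    out = total / -np.expm1(-lam_b)  # expm1: stable 1 - e^-lam at small lam
    # a monomorphic source yields a single genotype with certainty
    out = np.where((f_b == 0.0) | (f_b == 1.0), 1.0, out)
    return out if out.ndim else float(out)


def p_single_closed_form(lam, f):
    """Analytic limit of the single-genotype series (``i_max -> inf``).

    ``(e^{-(1-f)lam} + e^{-f lam} - 2 e^{-lam}) / (1 - e^{-lam})`` — the
    geometric-in-``f`` series summed to infinity. Serves as the correctness
    oracle for :func:`p_single_truncated`.
    """
    lam = _validate_lambda(lam)
    f = np.asarray(f, dtype=float)
    # e^-l (expm1(f l) + expm1((1-f) l)) / -expm1(-l): cancellation-free
    out = (
        np.exp(-lam) * (np.expm1(f * lam) + np.expm1((1.0 - f) * lam))
    ) / -np.expm1(-lam)
    return out if out.ndim else float(out)


def _bisect_lambda(
    f: np.ndarray,
    p_multi: float,
    bounds: tuple[float, float],
    i_max: int,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised bracketed bisection of ``p_single(lam, f) = 1 - p_multi``.

    ``p_single`` is strictly decreasing in ``lam`` for ``f`` in (0, 1), so a
    plain bisection is exact. Returns ``(lam, clipped)`` where ``clipped``
    marks trials whose root fell outside the bracket and was pinned to the
    nearest bound.
    """
    lo, hi = bounds
    if not (0.0 < lo < hi):
        raise ConfigError("solver bounds must satisfy 0 < lo < hi")
    if hi > i_max:
        raise ConfigError("upper solver bound must not exceed the summation cap")
    f = np.atleast_1d(np.asarray(f, dtype=float))
    target = 1.0 - p_multi
    lo_a = np.full(f.shape, lo)
    hi_a = np.full(f.shape, hi)
    clip_hi = p_single_truncated(np.full(f.shape, hi), f, i_max) > target
    clip_lo = p_single_truncated(np.full(f.shape, lo), f, i_max) < target
    n_iter = int(np.ceil(np.log2((hi - lo) / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo_a + hi_a)
        go_right = p_single_truncated(mid, f, i_max) > target
        lo_a = np.where(go_right, mid, lo_a)
        hi_a = np.where(go_right, hi_a, mid)
    lam = 0.5 * (lo_a + hi_a)
    lam = np.where(clip_hi, hi, lam)
    lam = np.where(clip_lo, lo, lam)
    return lam, clip_hi | clip_lo


def fit_lambda(
    p_multi_target: float,
    f: float,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    i_max: int = I_MAX,
    full_output: bool = False,
):
    """Mean founder number accounting for a multi-genotype deme proportion.

    Solves ``p_single_truncated(lam, f) = 1 - p_multi_target`` for ``lam``
    by bracketed bisection to ``|dlam| <= 1e-8``. When the target is not
    bracketed (extreme ``f`` or ``p_multi`` near 0/1) the bound achieving
    the closest value is returned and flagged as clipped.

    Returns ``lam`` (float), or ``(lam, clipped)`` if ``full_output``.
    """
    if not (0.0 < p_multi_target < 1.0):
        raise ConfigError("p_multi_target must lie in (0, 1)")
    if not (0.0 < f < 1.0):
        raise ConfigError("f must lie in (0, 1)")
    lam, clipped = _bisect_lambda(np.array([f]), p_multi_target, bounds, i_max)
    if full_output:
        return float(lam[0]), bool(clipped[0])
    return float(lam[0])


@dataclass(frozen=True)
class FrequencyPrior:
    """Prior on the minor/major genotype frequency in the colonizing source.

    ``kind`` is one of ``fixed`` (requires ``f``), ``uniform`` (U(0,1)) or
    ``beta`` (requires ``a, b > 0``; the symmetric beta(2,2) encodes that a
    locally detected second haplotype cannot be vanishingly rare).
    """

    kind: str
    f: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform", "beta"):
            raise ConfigError(f"unknown prior kind {self.kind!r}")
        if self.kind == "fixed":
            if self.f is None or not (0.0 < self.f < 1.0):
                raise ConfigError("fixed prior requires f in (0, 1)")
        if self.kind == "beta":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ConfigError("beta prior requires a, b > 0")

    @classmethod
    def parse(cls, text: str) -> "FrequencyPrior":
        """Parse ``fixed:0.5``, ``uniform``, or ``beta:2,2``."""
        text = text.strip()
        if text == "uniform":
            return cls("uniform")
        if text.startswith("fixed:"):
            return cls("fixed", f=float(text.split(":", 1)[1]))
        if text.startswith("beta:"):
            a, b = (float(x) for x in text.split(":", 1)[1].split(","))
            return cls("beta", a=a, b=b)
        raise ConfigError(f"cannot parse prior spec {text!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.f, dtype=float)
        if self.kind == "uniform":
            return rng.uniform(0.0, 1.0, n)
        return rng.beta(self.a, self.b, n)


@dataclass
class FounderFit:
    """Monte-Carlo founder-number fit over a frequency prior."""

    lambdas: np.ndarray
    clipped: np.ndarray
    seed: int
    bounds: tuple[float, float]
    prior: FrequencyPrior

    @property
    def n_trials(self) -> int:
        return len(self.lambdas)

    @property
    def mean(self) -> float:
        return float(np.mean(self.lambdas))

    @property
    def median(self) -> float:
        # even trial count -> midpoint of the central order statistics
        return float(np.median(self.lambdas))

    @property
    def n_clipped(self) -> int:
        return int(np.sum(self.clipped))

    def summary(self) -> dict:
        return {
            "prior": self.prior.kind,
            "n_trials": self.n_trials,
            "mean_lambda": self.mean,
            "median_lambda": self.median,
            "mean_lambda_rounded": round(self.mean),
            "median_lambda_rounded": round(self.median),
            "n_clipped": self.n_clipped,
            "seed": self.seed,
            "bounds": list(self.bounds),
        }


def fit_lambda_mc(
    p_multi_target: float,
    prior: FrequencyPrior,
    n_trials: int = 10_000,
    seed: int = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    i_max: int = I_MAX,
) -> FounderFit:
    """Founder-number fit averaging over a prior on the source frequency.

    One ``f`` is drawn per trial (frequencies vary between demes/trials,
    not within one), each trial solves the fixed-``f`` equation, and the
    distribution of per-trial estimates is summarised by its mean and
    median. Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if not (0.0 < p_multi_target < 1.0):
        raise ConfigError("p_multi_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    f = prior.draw(rng, n_trials)
    # degenerate draws at exactly 0/1 would make the root undefined
    eps = np.finfo(float).tiny
    f = np.clip(f, eps, 1.0 - 1e-16)
    lam, clipped = _bisect_lambda(f, p_multi_target, bounds, i_max)
    return FounderFit(
        lambdas=lam, clipped=clipped, seed=seed, bounds=bounds, prior=prior
    )
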