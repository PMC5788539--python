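"""Spatial co-occurrence of haplotypes and the under-sampling correction.

Two questions about mixing at the metre scale: (1) when two haplotypes are
both found within a given distance of a sample, how often does that single
rotting fruit or stem carry both of them (the co-occurrence curve)?
(2) given that only 2-12 individuals are genotyped per sample, what is the
maximum-likelihood estimate of the *true* proportion of multi-genotype
samples, correcting for genotype pairs missed by the small per-sample
draw?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    DemeseedError,
    DEFAULT_SUBSTRATE_EXCLUDES,
    SampleFrame,
)

__all__ = [
    "project_transect",
    "individual_haplotypes",
    "CooccurrenceCurve",
    "cooccurrence_curve",
    "MultiProportion",
    "observed_multi_proportion",
    "MLEProportionResult",
    "mle_true_multi_proportion",
    "closed_form_miss_probability",
]


def project_transect(coordinates: np.ndarray) -> np.ndarray:
    """Project 2-D sample positions onto the main axis of the sampling.

    Positions are orthogonal projections onto the first principal axis of
    the point cloud, oriented to increase southward (decreasing y) and
    shifted so the northmost projected point sits at the 0 m origin.
    """
    xy = np.asarray(coordinates, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ConfigError("need at least two 2-D points")
    centered = xy - xy.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ConfigError("all points identical: principal axis is degenerate")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[1] > 0 or (axis[1] == 0 and axis[0] < 0):
        axis = -axis  # point the axis southward (or east when exactly E-W)
    t = centered @ axis
    return t - t.min()


_HOM_KINDS = ("haplotype", "minor_variant")


def individual_haplotypes(assignments: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Haplotype labels carried by each classified individual.

    Homozygous individuals (including minor variants and recombinants)
    carry their major haplotype label; an F1 attests that both parental
    haplotypes were locally present and contributes both. Contaminated and
    unassigned individuals contribute nothing.
    """
    out: dict[str, frozenset[str]] = {}
    for row in assignments.itertuples(index=False):
        if row.kind in _HOM_KINDS or row.kind == "recombinant":
            out[row.individual_id] = frozenset({row.haplotype})
        elif row.kind == "F1":
            out[row.individual_id] = frozenset({row.h1, row.h2})
        else:
            out[row.individual_id] = frozenset()
    return out


def _sample_tables(
    assignments: pd.DataFrame,
    frame: SampleFrame,
    min_n: int,
    substrate_excludes: frozenset[str] | set[str],
) -> tuple[pd.DataFrame, dict[str, frozenset[str]], np.ndarray]:
    """Eligible samples with their genotyped counts and haplotype sets."""
    hap_of = individual_haplotypes(assignments)
    sample_of = frame.sample_of()
    counts: dict[str, int] = {}
    haps: dict[str, set[str]] = {}
    for ind, hs in hap_of.items():
        sid = sample_of.get(ind)
        if sid is None:
            raise ConfigError(f"individual {ind!r} missing from the sample frame")
        counts[sid] = counts.get(sid, 0) + 1
        haps.setdefault(sid, set()).update(hs)
    excludes = set(substrate_excludes)
    samples = frame.samples.copy()
    samples["n_genotyped"] = samples["sample_id"].map(counts).fillna(0).astype(int)
    substrate_ok = ~samples["substrate"].fillna("unknown").isin(excludes | {"unknown"})
    if not excludes:
        substrate_ok[:] = True
    eligible = (samples["n_genotyped"] >= min_n) & substrate_ok
    dist = frame.pairwise_distances()
    sets = {
        sid: frozenset(haps.get(sid, set())) for sid in samples["sample_id"]
    }
    samples["eligible"] = eligible.to_numpy()
    return samples, sets, dist


@dataclass
class CooccurrenceCurve:
    """Probability that two locally available haplotypes share a sample,
    as a function of the distance at which both are available."""

    thresholds: np.ndarray
    min_n: int
    numerator: np.ndarray
    denominator: np.ndarray

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.denominator > 0, self.numerator / self.denominator, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_m": self.thresholds,
                "min_n": self.min_n,
                "cooccurring_events": self.numerator,
                "events": self.denominator,
                "probability": self.probability,
            }
        )


def cooccurrence_curve(
    assignments: pd.DataFrame,
    frame: SampleFrame,
    thresholds,
    min_n: int = 2,
    substrate_excludes: frozenset[str] | set[str] = DEFAULT_SUBSTRATE_EXCLUDES,
) -> CooccurrenceCurve:
    """Haplotype co-occurrence probability versus distance threshold.

    An *event* is a pair (eligible sample ``s``, unordered haplotype pair
    ``{h1, h2}``) such that each of ``h1``, ``h2`` is observed in at least
    one eligible sample within the threshold distance of ``s`` (``s``
    itself included) and at least one of the two is observed in ``s``. The
    event co-occurs when both are observed in ``s``. Eligibility requires
    at least ``min_n`` genotyped individuals and a non-excluded substrate.
    Thresholds are inclusive (distance <= threshold).
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    samples, sets, dist = _sample_tables(assignments, frame, min_n, substrate_excludes)
    el_idx = np.flatnonzero(samples["eligible"].to_numpy())
    sids = samples["sample_id"].to_numpy()
    all_haps = sorted(set().union(*(sets[sids[i]] for i in el_idx)) if len(el_idx) else set())
    numer = np.zeros(len(thresholds), dtype=int)
    denom = np.zeros(len(thresholds), dtype=int)
    for ti, t in enumerate(thresholds):
        for i in el_idx:
            near = [j for j in el_idx if dist[i, j] <= t]
            avail = set().union(*(sets[sids[j]] for j in near))
            here = sets[sids[i]]
            for a in range(len(all_haps)):
                for b in range(a + 1, len(all_haps)):
                    h1, h2 = all_haps[a], all_haps[b]
                    if h1 in avail and h2 in avail and (h1 in here or h2 in here):
                        denom[ti] += 1
                        if h1 in here and h2 in here:
                            numer[ti] += 1
    return CooccurrenceCurve(
        thresholds=thresholds, min_n=min_n, numerator=numer, denominator=denom
    )


@dataclass
class MultiProportion:
    """Observed proportion of mixed samples among locally-mixed-context
    samples, with the per-sample inputs the MLE correction consumes."""

    k: int
    m: int
    samples: pd.DataFrame  # sample_id, n_genotyped, n_haplotypes, multi

    @property
    def fraction(self) -> float:
        return self.k / self.m


def observed_multi_proportion(
    assignments: pd.DataFrame,
    frame: SampleFrame,
    min_n: int = 2,
    substrate_excludes: frozenset[str] | set[str] = DEFAULT_SUBSTRATE_EXCLUDES,
    radius: float = 1.0,
) -> MultiProportion:
    """Fraction of samples carrying two haplotypes, among eligible samples
    with two haplotypes locally available within ``radius`` metres.

    Eligibility: at least ``min_n`` genotyped individuals, non-excluded
    substrate. Local availability is evaluated over eligible samples within
    ``radius`` of the focal sample, the focal sample included.
    """
    samples, sets, dist = _sample_tables(assignments, frame, min_n, substrate_excludes)
    el_idx = np.flatnonzero(samples["eligible"].to_numpy())
    sids = samples["sample_id"].to_numpy()
    rows = []
    for i in el_idx:
        near = [j for j in el_idx if dist[i, j] <= radius]
        avail = set().union(*(sets[sids[j]] for j in near))
        if len(avail) < 2:
            continue
        n_hap = len(sets[sids[i]])
        rows.append(
            dict(
                sample_id=sids[i],
                n_genotyped=int(samples["n_genotyped"].iloc[i]),
                n_haplotypes=n_hap,
                multi=n_hap >= 2,
            )
        )
    if not rows:
        raise DemeseedError(
            "no eligible sample has two haplotypes locally available"
        )
    tbl = pd.DataFrame(rows)
    return MultiProportion(k=int(tbl["multi"].sum()), m=len(tbl), samples=tbl)


def closed_form_miss_probability(n: int) -> float:
    """Exact ``E_f[f^n + (1-f)^n]`` for ``f ~ U(0,1)``: equals 2/(n+1).

    The probability that ``n`` genotyped individuals all show the same one
    of two genotypes whose within-sample frequency is uniform."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    return 2.0 / (n + 1)


def _golden_section_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


@dataclass
class MLEProportionResult:
    """ML estimate of the true multi-genotype sample proportion."""

    theta_hat: float
    sd: float
    n_replicates: int
    per_replicate: np.ndarray
    samples: pd.DataFrame
    boundary: bool
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "theta_hat": self.theta_hat,
            "sd": self.sd,
            "n_replicates": self.n_replicates,
            "boundary": self.boundary,
            "n_samples": len(self.samples),
            "seed": self.seed,
        }


def _theta_mle(miss: np.ndarray, multi: np.ndarray) -> float:
    """Maximize L(theta) = prod_multi theta (1 - miss_j)
    x prod_single [(1 - theta) + theta miss_j] over theta in [0, 1]."""
    eps = 1e-12

    def loglik(theta: float) -> float:
        ll = np.sum(np.log(np.maximum(theta * (1.0 - miss[multi]), eps)))
        ll += np.sum(
            np.log(np.maximum((1.0 - theta) + theta * miss[~multi], eps))
        )
        return ll

    return _golden_section_max(loglik, 0.0, 1.0)


def mle_true_multi_proportion(
    samples,
    n_replicates: int = 100,
    seed: int = 0,
    n_draws: int = 10_000,
    use_closed_form: bool = False,
) -> MLEProportionResult:
    """Correct the observed multi-genotype proportion for under-sampling.

    ``samples`` is a sequence of ``(n_j, multi_j)`` pairs (or the
    :class:`MultiProportion` table). A sample with a single observed
    genotype may still hold two: with within-sample genotype frequency
    ``f ~ U(0, 1)``, the miss probability for ``n_j`` genotyped individuals
    is ``E_f[f^{n_j} + (1-f)^{n_j}]``. Each replicate re-estimates the miss
    probabilities by Monte Carlo (``n_draws`` uniform draws) and maximizes
    the likelihood of the observed single/multi flags over the true
    proportion ``theta``; the estimate is the replicate mean (SD attached).
    With ``use_closed_form=True`` the exact miss probability ``2/(n_j+1)``
    replaces the Monte-Carlo step (single deterministic estimate).
    """
    tbl = _as_sample_table(samples)
    n = tbl["n_genotyped"].to_numpy(int)
    multi = tbl["multi"].to_numpy(bool)
    if (n < 1).any():
        raise ConfigError("every sample needs n_j >= 1")
    if len(tbl) == 0:
        raise ConfigError("at least one sample required")
    if use_closed_form:
        miss = 2.0 / (n + 1.0)
        theta = _theta_mle(miss, multi)
        per = np.array([theta])
        return MLEProportionResult(
            theta_hat=theta, sd=0.0, n_replicates=1, per_replicate=per,
            samples=tbl, boundary=theta > 1.0 - 1e-5, seed=None,
        )
    rng = np.random.default_rng(seed)
    per = np.empty(n_replicates)
    for r in range(n_replicates):
        f = rng.uniform(0.0, 1.0, size=(n_draws, 1))
        miss = np.mean(f**n + (1.0 - f) ** n, axis=0)
        per[r] = _theta_mle(miss, multi)
    theta = float(per.mean())
    return MLEProportionResult(
        theta_hat=theta,
        sd=float(per.std(ddof=1)) if n_replicates > 1 else 0.0,
        n_replicates=n_replicates,
        per_replicate=per,
        samples=tbl,
        boundary=theta > 1.0 - 1e-5 or bool(multi.all()) or bool((n == 1).all()),
        seed=seed,
    )


def _as_sample_table(samples) -> pd.DataFrame:
    if isinstance(samples, MultiProportion):
        return samples.samples[["n_genotyped", "multi"]].reset_index(drop=True)
    if isinstance(samples, pd.DataFrame):
        return samples[["n_genotyped", "multi"]].reset_index(drop=True)
    return pd.DataFrame(
        [(int(n), bool(m)) for n, m in samples], columns=["n_genotyped", "multi"]
    )
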