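"""Synthetic selfing-metapopulation generator with ground truth.

Emulates the statistical structure of a local selfing nematode
metapopulation survey: a small pool of homozygous multilocus haplotypes, a
handful of demes (one rotting fruit/stem sample each), founder numbers per
deme drawn from a zero-truncated Poisson, 2-12 genotyped individuals per
sample, rare F1 heterozygotes and single-breakpoint recombinants, ~275
biallelic sites spread over six chromosomes, plus missing data and
genotyping error. Every simulated dataset carries a :class:`SimTruth`
record so downstream recovery can be checked exactly.

Demes are generated independently (no migration kinetics, no explicit
generation timeline); founder lineages expand equally, i.e. sampled
individuals draw their lineage uniformly over the deme's founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CHROMOSOMES,
    ConfigError,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleFrame,
)

__all__ = ["SimConfig", "SimTruth", "sample_zt_poisson", "simulate_metapopulation"]

#: 275 sites over the six chromosomes.
DEFAULT_CHROMOSOME_LAYOUT: dict[str, int] = {
    "I": 46, "II": 46, "III": 46, "IV": 46, "V": 46, "X": 45,
}

#: Minimum pairwise Hamming distance between generated major haplotypes, so
#: that clustering is identifiable (real major haplotypes differ by tens of
#: SNPs; e.g. 52 between the two most distant orchard haplotypes).
MIN_HAPLOTYPE_DISTANCE = 5


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic metapopulation.

    Defaults mirror the field survey the generator emulates: three major
    haplotypes at intermediate frequencies, a mean of ~3 founders per deme,
    2-12 genotyped individuals per sample, heterozygotes under 1%, and a
    ~200 m x 10 m transect band of sampling positions.
    """

    n_haplotypes: int = 3
    pool_frequencies: tuple[float, ...] = (0.21, 0.46, 0.33)
    lambda_founders: float = 2.9
    n_demes: int = 30
    deme_positions: np.ndarray | None = None
    individuals_per_deme: tuple[int, int] = (2, 12)
    outcross_rate: float = 0.009
    recombinant_rate: float = 0.003
    n_sites: int = 275
    chromosome_layout: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LAYOUT)
    )
    missing_rate: float = 0.05
    error_rate: float = 0.002
    substrate_labels: tuple[str, ...] = ("stem", "fruit")
    location: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.pool_frequencies, dtype=float)
        if len(freqs) != self.n_haplotypes:
            raise ConfigError("pool_frequencies length must equal n_haplotypes")
        if abs(freqs.sum() - 1.0) > 1e-12 or (freqs < 0).any():
            raise ConfigError("pool_frequencies must be non-negative and sum to 1")
        for name in ("outcross_rate", "recombinant_rate", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.lambda_founders <= 0:
            raise ConfigError("lambda_founders must be > 0")
        if sum(self.chromosome_layout.values()) != self.n_sites:
            raise ConfigError("n_sites must equal the chromosome_layout total")
        unknown = set(self.chromosome_layout) - set(CHROMOSOMES)
        if unknown:
            raise ConfigError(f"unknown chromosomes {sorted(unknown)}")
        lo, hi = self.individuals_per_deme
        if not (1 <= lo <= hi):
            raise ConfigError("individuals_per_deme must be a (lo, hi) range with lo >= 1")
        if self.deme_positions is not None:
            pos = np.asarray(self.deme_positions, dtype=float)
            if pos.shape != (self.n_demes, 2):
                raise ConfigError("deme_positions must have shape (n_demes, 2)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset.

    ``labels`` has one row per individual: ``individual_id, sample_id,
    kind`` (``haplotype`` | ``F1`` | ``recombinant``), ``h1, h2`` (haplotype
    indices into the pool; ``h2`` = -1 for pure selfers), and for
    recombinants the mosaic chromosome and first foreign site index.
    """

    founder_counts: np.ndarray
    founder_haplotypes: list[list[int]]
    haplotype_calls: np.ndarray  # (n_haplotypes, n_sites), hom codes
    labels: pd.DataFrame
    seed: int

    def true_partition(self) -> dict[str, int]:
        """individual_id -> true pool haplotype index (selfers only)."""
        sel = self.labels[self.labels["kind"] == "haplotype"]
        return dict(zip(sel["individual_id"], sel["h1"]))


def sample_zt_poisson(lam: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` founder counts from Poisson(``lam``) conditioned on >= 1.

    Exact inverse-CDF sampling on the truncated distribution: a uniform
    deviate is mapped into the untruncated CDF above the zero class.
    """
    if lam <= 0:
        raise ConfigError("lambda must be > 0")
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = np.exp(-lam)
    u = rng.uniform(0.0, 1.0, n)
    q = np.minimum(p0 + u * (1.0 - p0), np.nextafter(1.0, 0.0))
    draws = stats.poisson.ppf(q, lam).astype(np.int64)
    return np.maximum(draws, 1)


def _make_sites(layout: dict[str, int], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    locus = 0
    for chrom in CHROMOSOMES:
        k = layout.get(chrom, 0)
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, 15_000_000), size=k, replace=False))
        for p in pos:
            locus += 1
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            rows.append((chrom, int(p), f"RAD{locus}", ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "rad_locus", "ref", "alt"])


def _make_haplotypes(n_hap: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct homozygous consensus vectors, pairwise distance >= 5."""
    for _ in range(1000):
        haps = rng.choice([HOM_REF, HOM_ALT], size=(n_hap, n_sites)).astype(np.int8)
        ok = all(
            (haps[i] != haps[j]).sum() >= MIN_HAPLOTYPE_DISTANCE
            for i in range(n_hap)
            for j in range(i + 1, n_hap)
        )
        if ok:
            return haps
    raise ConfigError(
        "could not draw haplotypes with the required pairwise distance; "
        "increase n_sites or decrease n_haplotypes"
    )


def simulate_metapopulation(
    config: SimConfig,
) -> tuple[GenotypeMatrix, SampleFrame, SimTruth]:
    """Simulate one metapopulation snapshot: one sample per deme.

    All randomness flows from ``config.seed`` through spawned sub-streams
    (haplotype pool / demography / noise), so e.g. raising the error rate
    does not reshuffle which founders seeded each deme.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_pool, rng_demo, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    sites = _make_sites(cfg.chromosome_layout, rng_pool)
    haps = _make_haplotypes(cfg.n_haplotypes, cfg.n_sites, rng_pool)
    chrom_index: dict[str, np.ndarray] = {
        c: np.flatnonzero((sites["chrom"] == c).to_numpy()) for c in CHROMOSOMES
    }
    mosaic_chroms = [c for c in CHROMOSOMES if len(chrom_index[c]) >= 2]

    if cfg.deme_positions is not None:
        positions = np.asarray(cfg.deme_positions, dtype=float)
    else:  # thin sampling band, ~200 m x 10 m
        positions = np.column_stack(
            [rng_demo.uniform(0, 10, cfg.n_demes), rng_demo.uniform(0, 200, cfg.n_demes)]
        )

    founder_counts = sample_zt_poisson(cfg.lambda_founders, cfg.n_demes, rng_demo)
    lo, hi = cfg.individuals_per_deme

    individuals: list[str] = []
    sample_rows: list[tuple] = []
    indiv_rows: list[tuple[str, str]] = []
    label_rows: list[tuple] = []
    call_rows: list[np.ndarray] = []
    founder_haplotypes: list[list[int]] = []

    for d in range(cfg.n_demes):
        sample_id = f"{cfg.location}{d + 1:04d}"
        substrate = cfg.substrate_labels[
            rng_demo.integers(0, len(cfg.substrate_labels))
        ]
        sample_rows.append(
            (sample_id, cfg.location, "2009-10-01", substrate,
             float(positions[d, 0]), float(positions[d, 1]))
        )
        founders = list(
            rng_demo.choice(cfg.n_haplotypes, size=founder_counts[d], p=cfg.pool_frequencies)
        )
        founder_haplotypes.append([int(h) for h in founders])
        distinct = sorted(set(founders))
        n_ind = int(rng_demo.integers(lo, hi + 1))
        for i in range(n_ind):
            ind_id = f"{sample_id}.{i + 1}"
            lineage = founders[rng_demo.integers(0, len(founders))]
            u = rng_demo.uniform()
            kind, h1, h2 = "haplotype", int(lineage), -1
            chrom_lab, brk = "", -1
            if u < cfg.outcross_rate and len(distinct) >= 2:
                partner = int(
                    rng_demo.choice([h for h in distinct if h != lineage])
                )
                kind, h2 = "F1", partner
                calls = np.where(
                    haps[h1] != haps[h2], HET, haps[h1]
                ).astype(np.int8)
            elif (
                u < cfg.outcross_rate + cfg.recombinant_rate
                and len(distinct) >= 2
                and mosaic_chroms
            ):
                partner = int(
                    rng_demo.choice([h for h in distinct if h != lineage])
                )
                kind, h2 = "recombinant", partner
                chrom_lab = mosaic_chroms[rng_demo.integers(0, len(mosaic_chroms))]
                idx = chrom_index[chrom_lab]
                brk = int(rng_demo.integers(1, len(idx)))  # first foreign site
                calls = haps[h1].copy()
                calls[idx[brk:]] = haps[h2][idx[brk:]]
            else:
                calls = haps[h1].copy()
            individuals.append(ind_id)
            indiv_rows.append((ind_id, sample_id))
            label_rows.append((ind_id, sample_id, kind, h1, h2, chrom_lab, brk))
            call_rows.append(calls)

    calls = np.array(call_rows, dtype=np.int8)

    # genotyping error: flip to a uniformly chosen different called state
    if cfg.error_rate > 0:
        err = rng_noise.uniform(size=calls.shape) < cfg.error_rate
        shift = rng_noise.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng_noise.uniform(size=calls.shape) < cfg.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    matrix = GenotypeMatrix(individuals=individuals, sites=sites, calls=calls)
    frame = SampleFrame(
        samples=pd.DataFrame(
            sample_rows,
            columns=["sample_id", "location", "date", "substrate", "x_m", "y_m"],
        ),
        individuals=pd.DataFrame(indiv_rows, columns=["individual_id", "sample_id"]),
    )
    truth = SimTruth(
        founder_counts=founder_counts,
        founder_haplotypes=founder_haplotypes,
        haplotype_calls=haps,
        labels=pd.DataFrame(
            label_rows,
            columns=[
                "individual_id", "sample_id", "kind", "h1", "h2",
                "mosaic_chrom", "mosaic_first_site",
            ],
        ),
        seed=cfg.seed,
    )
    return matrix, frame, truth
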