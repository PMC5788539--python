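"""Population statistics: spectra, contingency tests, hierarchical Fst.

The fixation index is estimated from Weir & Cockerham (1984) variance
components computed here from the genotype matrix (nothing is delegated to
an external Fst implementation): per-locus components ``a`` (among
groups), ``b`` (among individuals within groups) and ``c`` (within
individuals), combined across loci as a ratio of summed components (the
"weighted" multi-locus estimator), plus a nested moment-ANOVA extension
for samples within locations. Temporal heterogeneity of haplotype
frequencies is tested with Pearson's chi-squared statistic against a
Monte-Carlo null of tables with both margins fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ConfigError,
    DemeseedError,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleFrame,
)
from .haplocall import HaplotypeCatalog

__all__ = [
    "haplotype_spectrum",
    "ContingencyTest",
    "chisq_simulated_p",
    "FstResult",
    "weir_cockerham_fst",
    "hierarchical_fst",
    "pairwise_divergence",
    "ExpectedPolymorphism",
    "expected_polymorphic_sites",
]


def _classified(assignments: pd.DataFrame, frame: SampleFrame) -> pd.DataFrame:
    """Assignments joined with sample metadata, restricted to individuals
    carrying a haplotype label or an F1 call."""
    meta = frame.samples.set_index("sample_id")
    tbl = assignments.merge(
        frame.individuals, on="individual_id", how="left", validate="1:1"
    )
    tbl["location"] = tbl["sample_id"].map(meta["location"])
    tbl["year"] = tbl["sample_id"].map(meta["date"]).astype(str).str[:4]
    keep = tbl["kind"].isin(("haplotype", "minor_variant", "recombinant", "F1"))
    tbl = tbl[keep].copy()
    tbl["label"] = np.where(
        tbl["kind"] == "F1",
        "F1(" + tbl["h1"].astype(str) + "," + tbl["h2"].astype(str) + ")",
        tbl["haplotype"],
    )
    return tbl


def haplotype_spectrum(
    assignments: pd.DataFrame,
    frame: SampleFrame,
    by: str = "individuals",
    grouping: tuple[str, ...] = ("location",),
) -> pd.DataFrame:
    """Haplotype frequency spectrum per group.

    ``by='individuals'``: per-haplotype count and proportion of classified
    individuals (proportions sum to 1 within a group; F1 heterozygotes form
    their own category). ``by='samples'``: count and proportion of
    positive samples carrying the haplotype — a sample can carry several
    haplotypes, so these proportions may sum to more than 1.
    """
    if assignments.empty:
        raise ConfigError("assignments are empty")
    if by not in ("individuals", "samples"):
        raise ConfigError("by must be 'individuals' or 'samples'")
    tbl = _classified(assignments, frame)
    for col in grouping:
        if col not in tbl.columns:
            raise ConfigError(f"unknown grouping column {col!r}")
    rows = []
    for keys, grp in tbl.groupby(list(grouping), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        if by == "individuals":
            total = len(grp)
            counts = grp.groupby("label").size()
        else:
            total = grp["sample_id"].nunique()
            counts = grp.groupby("label")["sample_id"].nunique()
        for label, cnt in counts.sort_values(ascending=False).items():
            rows.append((*keys, label, int(cnt), cnt / total, total))
    return pd.DataFrame(
        rows, columns=[*grouping, "haplotype", "count", "proportion", "total"]
    )


@dataclass
class ContingencyTest:
    observed: np.ndarray
    statistic: float
    p_value: float
    n_sim: int
    seed: int

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _pearson_stat(tables: np.ndarray, expected: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (tables - expected) ** 2 / expected
    return np.nansum(contrib, axis=(-2, -1))


def chisq_simulated_p(
    table: np.ndarray,
    n_sim: int = 100_000,
    seed: int = 0,
    chunk: int = 100_000,
) -> ContingencyTest:
    """Pearson chi-squared test with a simulated P-value.

    The null tables are drawn uniformly over contingency tables with both
    margins fixed (Patefield's algorithm) and the P-value uses the add-one
    estimator ``(1 + #{sim >= obs}) / (n_sim + 1)``, so P is never 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ConfigError("table must be a non-negative integer matrix")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        obs = obs[np.ix_(row_ok, col_ok)]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ConfigError("need at least 2 rows and 2 columns with positive margins")
    rows, cols = obs.sum(axis=1).astype(int), obs.sum(axis=0).astype(int)
    expected = np.outer(rows, cols) / obs.sum()
    statistic = float(_pearson_stat(obs, expected))
    rng = np.random.default_rng(seed)
    dist = stats.random_table(rows, cols)
    n_ge = 0
    done = 0
    while done < n_sim:
        k = min(chunk, n_sim - done)
        sims = dist.rvs(k, random_state=rng)
        n_ge += int((_pearson_stat(sims, expected) >= statistic - 1e-12).sum())
        done += k
    p = (1 + n_ge) / (n_sim + 1)
    return ContingencyTest(
        observed=obs.astype(int), statistic=statistic, p_value=p,
        n_sim=n_sim, seed=seed,
    )


@dataclass
class FstResult:
    """Variance components and fixation indices.

    ``components`` holds per-locus sums; estimates are ratios of summed
    components across loci, never means of per-locus ratios.
    """

    components: pd.DataFrame
    estimates: dict[str, float]
    loci_used: int

    def summary(self) -> dict:
        return {"loci_used": self.loci_used, **self.estimates}


def _allele_stats(calls: np.ndarray):
    """Alt-allele dosage (0/1/2), het flag and called flag per entry."""
    called = calls != MISSING
    dosage = np.where(calls == HOM_ALT, 2, np.where(calls == HET, 1, 0))
    return dosage, (calls == HET), called


def weir_cockerham_fst(matrix: GenotypeMatrix, groups: list) -> FstResult:
    """Two-level Weir & Cockerham (1984) estimator.

    ``groups`` assigns each individual to a subpopulation. Per locus the
    components are computed from subpopulation allele frequencies, observed
    heterozygosities and sample sizes; loci with fewer than two populated
    groups are skipped.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ConfigError("need at least two groups")
    dosage, het, called = _allele_stats(matrix.calls)
    rows = []
    for s in range(matrix.n_sites):
        n_i, p_i, h_i = [], [], []
        for lab in labels:
            sel = (groups == lab) & called[:, s]
            n = int(sel.sum())
            if n == 0:
                continue
            n_i.append(n)
            p_i.append(dosage[sel, s].sum() / (2 * n))
            h_i.append(het[sel, s].mean())
        r = len(n_i)
        if r < 2:
            continue
        n_i = np.asarray(n_i, float)
        p_i = np.asarray(p_i, float)
        h_i = np.asarray(h_i, float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        rows.append((s, a, b, c))
    if not rows:
        raise DemeseedError("no usable locus (all monomorphic or single-group)")
    comp = pd.DataFrame(rows, columns=["site", "a", "b", "c"])
    denom = comp[["a", "b", "c"]].to_numpy().sum()
    if denom == 0:
        raise DemeseedError("monomorphic locus set: Fst undefined")
    est = {
        "fst": float(comp["a"].sum() / denom),
        "fit": float((comp["a"].sum() + comp["b"].sum()) / denom),
    }
    return FstResult(components=comp, estimates=est, loci_used=len(comp))


def _nested_anova_components(
    x: np.ndarray, loc: np.ndarray, samp: np.ndarray
) -> tuple[float, float, float, float] | None:
    """Moment estimates of nested variance components for one locus.

    ``x`` is the per-allele alt indicator (2 entries per called
    individual), ``loc``/``samp`` the location and sample of each allele.
    Returns (sigma2_loc, sigma2_samp, sigma2_ind, sigma2_e); the lowest
    level is balanced (always two alleles per individual) which keeps the
    unequal-size Searle coefficients simple.
    """
    n_alleles = len(x)
    C = n_alleles // 2  # individuals
    ind = np.repeat(np.arange(C), 2)
    locs = pd.unique(loc)
    a = len(locs)
    if a < 2:
        return None
    xbar = x.mean()
    # group sizes in alleles
    N_i = np.array([(loc == g).sum() for g in locs], float)
    sample_keys = pd.unique(samp)
    B = len(sample_keys)
    N_ij = np.array([(samp == sid).sum() for sid in sample_keys], float)
    loc_of_samp = np.array(
        [loc[samp == sid][0] for sid in sample_keys], dtype=object
    )
    # sums of squares
    mean_loc = {g: x[loc == g].mean() for g in locs}
    mean_samp = {sid: x[samp == sid].mean() for sid in sample_keys}
    mean_ind = x.reshape(C, 2).mean(axis=1)
    ss_loc = sum(((mean_loc[g] - xbar) ** 2) * (loc == g).sum() for g in locs)
    ss_samp = sum(
        ((mean_samp[sid] - mean_loc[loc_of_samp[k]]) ** 2) * N_ij[k]
        for k, sid in enumerate(sample_keys)
    )
    samp_of_ind = samp[::2]
    ss_ind = float(
        (2 * (mean_ind - np.array([mean_samp[s] for s in samp_of_ind])) ** 2).sum()
    )
    ss_e = float(((x - np.repeat(mean_ind, 2)) ** 2).sum())
    df_loc, df_samp, df_ind, df_e = a - 1, B - a, C - B, n_alleles - C
    if df_samp < 1 or df_ind < 1 or df_e < 1:
        return None
    ms_loc, ms_samp = ss_loc / df_loc, ss_samp / df_samp
    ms_ind, ms_e = ss_ind / df_ind, ss_e / df_e
    # Searle coefficients; lowest level balanced (2 alleles/individual)
    N = float(n_alleles)
    sumNij2_over_Ni = sum(
        (N_ij[loc_of_samp == g] ** 2).sum() / N_i[list(locs).index(g)] for g in locs
    )
    m_s = (N - sumNij2_over_Ni) / df_samp
    m_l = (sumNij2_over_Ni - (N_ij**2).sum() / N) / df_loc
    k_l = (N - (N_i**2).sum() / N) / df_loc
    s2_e = ms_e
    s2_ind = (ms_ind - s2_e) / 2.0
    s2_samp = (ms_samp - s2_e - 2.0 * s2_ind) / m_s
    s2_loc = (ms_loc - s2_e - 2.0 * s2_ind - m_l * s2_samp) / k_l
    return s2_loc, s2_samp, s2_ind, s2_e


def hierarchical_fst(
    matrix: GenotypeMatrix,
    frame: SampleFrame,
    levels: tuple[str, str] = ("location", "sample_id"),
) -> FstResult:
    """Hierarchical fixation indices for individuals in samples in
    locations.

    Per locus, a nested moment ANOVA on allele indicators yields variance
    components for locations, samples within locations, individuals within
    samples, and alleles within individuals; components are summed across
    loci and turned into F-statistics as ratios of sums. The plain
    two-level sample-wise estimator (the one applied per year in spatial
    analyses) is available through :func:`weir_cockerham_fst`.
    """
    meta = frame.samples.set_index("sample_id")
    sample_of = frame.sample_of()
    samp = np.array([sample_of[i] for i in matrix.individuals])
    lvl_loc, lvl_samp = levels
    if lvl_samp != "sample_id":
        raise ConfigError("inner level must be 'sample_id'")
    loc = np.array([meta.loc[s, lvl_loc] for s in samp], dtype=object)
    if len(pd.unique(loc)) < 2 or len(pd.unique(samp)) < 2:
        raise ConfigError("need at least two groups at each level")
    dosage, het, called = _allele_stats(matrix.calls)
    rows = []
    for s_idx in range(matrix.n_sites):
        sel = called[:, s_idx]
        if sel.sum() < 2:
            continue
        d = dosage[sel, s_idx]
        h = het[sel, s_idx]
        # two alleles per individual: (first, second) dosage split
        first = np.where(d == 2, 1, np.where(h, 1, 0))
        second = np.where(d == 2, 1, 0)
        x = np.column_stack([first, second]).reshape(-1).astype(float)
        res = _nested_anova_components(
            x, np.repeat(loc[sel], 2), np.repeat(samp[sel], 2)
        )
        if res is None:
            continue
        rows.append((s_idx, *res))
    if not rows:
        raise DemeseedError("no usable locus for hierarchical Fst")
    comp = pd.DataFrame(
        rows, columns=["site", "s2_loc", "s2_samp", "s2_ind", "s2_e"]
    )
    sums = comp[["s2_loc", "s2_samp", "s2_ind", "s2_e"]].sum()
    total = float(sums.sum())
    if total == 0:
        raise DemeseedError("monomorphic locus set: Fst undefined")
    within = float(total - sums["s2_loc"])
    est = {
        "fst_location": float(sums["s2_loc"] / total),
        "fst_sample_total": float((sums["s2_loc"] + sums["s2_samp"]) / total),
        "fst_sample_within_location": (
            float(sums["s2_samp"] / within) if within > 0 else float("nan")
        ),
    }
    return FstResult(components=comp, estimates=est, loci_used=len(comp))


#: 7760 RAD fragments x ~30 informative bp each.
DEFAULT_SURVEYED_BP = 30 * 7760


def pairwise_divergence(
    catalog: HaplotypeCatalog,
    surveyed_bp: int = DEFAULT_SURVEYED_BP,
    include_minor: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Pairwise haplotype divergence in substitutions per surveyed
    nucleotide.

    Entry (h1, h2) counts consensus sites at which both haplotypes are
    called and differ, divided by the surveyed base-pair total. Returns the
    symmetric matrix and the mean over unordered pairs (NaN for catalogs of
    one haplotype).
    """
    if surveyed_bp <= 0:
        raise ConfigError("surveyed_bp must be > 0")
    names = catalog.names() if include_minor else list(catalog.majors)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    vals = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            c1, c2 = catalog.consensus(names[i]), catalog.consensus(names[j])
            both = (c1 != MISSING) & (c2 != MISSING)
            d = int((c1[both] != c2[both]).sum()) / surveyed_bp
            mat.iloc[i, j] = mat.iloc[j, i] = d
            vals.append(d)
    return mat, (float(np.mean(vals)) if vals else float("nan"))


@dataclass(frozen=True)
class ExpectedPolymorphism:
    value: float

    @property
    def display(self) -> int:
        return round(self.value)


def expected_polymorphic_sites(
    n_fragments: int, bp_per_fragment: float, diversity_per_bp: float
) -> ExpectedPolymorphism:
    """Expected polymorphic sites between two random isolates:
    fragments x informative bp per fragment x nucleotide diversity."""
    if n_fragments <= 0 or bp_per_fragment <= 0 or diversity_per_bp < 0:
        raise ConfigError("arguments must be positive")
    return ExpectedPolymorphism(n_fragments * bp_per_fragment * diversity_per_bp)
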