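"""Multilocus haplotype calling for highly selfing populations.

In a selfing population nearly every individual is homozygous genome-wide,
so individuals collapse into a handful of multilocus haplotypes (clonal
genotype labels). This module filters a raw biallelic genotype matrix
(call-rate and mostly-het site filters, collapsing of fully in-phase SNPs
within one RAD locus), groups homozygous individuals into named haplotypes
with minor one-to-few-SNP variants, and classifies the rare remainder:
F1 heterozygotes (het at essentially all sites diagnostic between two
haplotypes), single-breakpoint recombinant mosaics, and contaminated or
unassignable individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigError, GenotypeMatrix, HET, HOM_REF, MISSING

__all__ = [
    "HaplotypeCatalog",
    "filter_sites",
    "collapse_in_phase",
    "cluster_haplotypes",
    "classify_heterozygotes",
    "detect_recombinants",
    "call_haplotypes",
]

ASSIGNMENT_COLUMNS = [
    "individual_id", "kind", "haplotype", "h1", "h2", "entry",
    "k_diffs", "matched", "mismatched", "het_sites", "segments",
]


@dataclass
class HaplotypeCatalog:
    """Named multilocus haplotypes with homozygous consensus genotypes.

    ``entries`` maps a name to its consensus call vector (hom codes, missing
    allowed, never het). Major haplotypes are named ``H<loc><n>`` in order
    of descending individual count; minor variants ``H<loc><n>-<k>`` hang
    off their parent major.
    """

    entries: dict[str, np.ndarray]
    majors: list[str]
    parent: dict[str, str] = field(default_factory=dict)
    n_individuals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cons in self.entries.items():
            if (np.asarray(cons) == HET).any():
                raise ConfigError(f"consensus for {name} contains het calls")

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return list(self.entries)

    def consensus(self, name: str) -> np.ndarray:
        return self.entries[name]

    def to_frame(self, site_labels: list[str]) -> pd.DataFrame:
        """Long-format (haplotype, site, call) table."""
        rows = []
        for name, cons in self.entries.items():
            for lab, c in zip(site_labels, cons):
                rows.append((name, lab, int(c)))
        return pd.DataFrame(rows, columns=["haplotype", "site", "call"])


def filter_sites(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.7,
    max_het_fraction: float = 0.5,
) -> GenotypeMatrix:
    """Drop low-call-rate and mostly-heterozygous sites.

    A site is kept when it has calls for at least ``min_call_rate`` of the
    individuals and when the heterozygous fraction among its non-missing
    calls is at most ``max_het_fraction`` (mostly-het sites being the
    signature of mismapping/duplications rather than real variation).
    Individuals and site order are untouched; idempotent.
    """
    if not (0.0 < min_call_rate <= 1.0) or not (0.0 < max_het_fraction <= 1.0):
        raise ConfigError("filter fractions must lie in (0, 1]")
    if matrix.n_sites == 0 or matrix.n_individuals == 0:
        warnings.warn("filter_sites called on an empty matrix", stacklevel=2)
        return matrix.take_sites(np.arange(matrix.n_sites))
    called = matrix.calls != MISSING
    call_rate = called.mean(axis=0)
    n_called = called.sum(axis=0)
    n_het = (matrix.calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    keep = (call_rate >= min_call_rate) & (het_frac <= max_het_fraction)
    return matrix.take_sites(np.flatnonzero(keep))


def _in_phase(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two call columns define identical partitions of the
    individuals over their mutually non-missing entries (a bijection maps
    the states of one onto the states of the other)."""
    both = (a != MISSING) & (b != MISSING)
    if not both.any():
        return False  # no shared data: phase cannot be established
    pairs = set(zip(a[both].tolist(), b[both].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def collapse_in_phase(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Within each RAD locus keep one SNP per set of fully in-phase SNPs.

    A 36-bp RAD locus can carry two (or more) SNPs; when their calls are
    fully in phase across the dataset they carry one signal and only the
    lowest-position one is retained. SNPs not fully in phase are all kept.
    """
    keep = np.ones(matrix.n_sites, dtype=bool)
    locus = matrix.sites["rad_locus"].to_numpy()
    for loc in pd.unique(locus):
        idx = np.flatnonzero(locus == loc)
        if len(idx) < 2:
            continue
        kept_in_locus: list[int] = []
        for j in idx:  # site order == position order within chromosome
            if any(
                _in_phase(matrix.calls[:, j], matrix.calls[:, k])
                for k in kept_in_locus
            ):
                keep[j] = False
            else:
                kept_in_locus.append(j)
    return matrix.take_sites(np.flatnonzero(keep))


def _consensus(calls: np.ndarray) -> np.ndarray:
    """Per-site majority homozygous call; ties toward hom-ref; all-missing
    stays missing."""
    n_ref = (calls == HOM_REF).sum(axis=0)
    n_alt = (calls == 2).sum(axis=0)
    cons = np.full(calls.shape[1], MISSING, dtype=np.int8)
    cons[n_ref >= n_alt] = HOM_REF
    cons[n_alt > n_ref] = 2
    cons[(n_ref == 0) & (n_alt == 0)] = MISSING
    return cons


def _compatible(a: np.ndarray, b: np.ndarray, min_overlap_sites: int) -> bool:
    both = (a != MISSING) & (b != MISSING)
    if both.sum() < min_overlap_sites:
        return False
    return bool((a[both] == b[both]).all())


def _distance(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(mismatches, overlap) over mutually non-missing sites."""
    both = (a != MISSING) & (b != MISSING)
    return int((a[both] != b[both]).sum()), int(both.sum())


def cluster_haplotypes(
    matrix: GenotypeMatrix,
    minor_variant_max_diff: int = 2,
    min_overlap: float = 0.5,
    location_code: str = "L",
) -> tuple[HaplotypeCatalog, pd.DataFrame]:
    """Partition homozygous individuals into named multilocus haplotypes.

    Individuals without het calls are grouped by exact identity of their
    non-missing calls (joining a group requires agreement at every mutually
    non-missing site with each member, with at least ``min_overlap`` of all
    sites mutually called). Groups of two or more individuals — plus
    singletons farther than ``minor_variant_max_diff`` sites from every
    group — become major haplotypes; remaining singletons become minor
    variants of their nearest major. Het-bearing individuals are deferred
    (``kind == 'het_deferred'``) for :func:`classify_heterozygotes`.
    """
    if minor_variant_max_diff < 1:
        raise ConfigError("minor_variant_max_diff must be >= 1")
    n_sites = matrix.n_sites
    min_overlap_sites = int(np.ceil(min_overlap * n_sites))
    calls = matrix.calls
    het_mask = (calls == HET).any(axis=1)

    # Most-complete individuals first, and each joins the largest compatible
    # group: an individual carrying a private error founds a group that stays
    # a singleton (-> minor variant) instead of seeding a spurious major.
    hom_idx = np.flatnonzero(~het_mask)
    n_called = (calls[hom_idx] != MISSING).sum(axis=1)
    order_idx = hom_idx[np.lexsort((hom_idx, -n_called))]
    groups: list[list[int]] = []
    for i in order_idx:
        best = None
        for g in sorted(groups, key=len, reverse=True):
            if all(_compatible(calls[i], calls[j], min_overlap_sites) for j in g):
                best = g
                break
        if best is None:
            groups.append([int(i)])
        else:
            best.append(int(i))

    major_groups = [g for g in groups if len(g) >= 2]
    singleton_idx = [g[0] for g in groups if len(g) == 1]
    major_cons = [_consensus(calls[g]) for g in major_groups]

    # classify singletons against the multi-member groups
    minor_of: dict[int, tuple[int, int]] = {}   # singleton -> (major group #, diffs)
    unassigned: list[int] = []
    for s in singleton_idx:
        dists = []
        for cons in major_cons:
            d, ov = _distance(calls[s], cons)
            if ov >= min_overlap_sites:
                dists.append(d)
            else:
                dists.append(None)
        valid = [(d, k) for k, d in enumerate(dists) if d is not None]
        covered = (calls[s] != MISSING).sum() >= min_overlap_sites
        if not valid and not covered:
            unassigned.append(s)
        elif valid and min(valid)[0] <= minor_variant_max_diff:
            d, k = min(valid)
            minor_of[s] = (k, d)
        else:
            major_groups.append([s])          # distant singleton: own haplotype
            major_cons.append(calls[s].copy())

    # name majors by descending individual count, then first appearance
    order = sorted(
        range(len(major_groups)), key=lambda k: (-len(major_groups[k]), k)
    )
    entries: dict[str, np.ndarray] = {}
    majors: list[str] = []
    parent: dict[str, str] = {}
    n_individuals: dict[str, int] = {}
    major_name: dict[int, str] = {}
    for rank, k in enumerate(order, start=1):
        name = f"H{location_code}{rank}"
        major_name[k] = name
        majors.append(name)
        entries[name] = major_cons[k]
        n_individuals[name] = len(major_groups[k])

    rows: list[dict] = []
    for k, g in enumerate(major_groups):
        name = major_name[k]
        for i in g:
            d, ov = _distance(calls[i], entries[name])
            rows.append(
                dict(individual_id=matrix.individuals[i], kind="haplotype",
                     haplotype=name, matched=ov - d, mismatched=d)
            )
    minor_counter = {name: 0 for name in majors}
    for s, (k, d) in sorted(minor_of.items(), key=lambda kv: kv[0]):
        pname = major_name[k]
        minor_counter[pname] += 1
        name = f"{pname}-{minor_counter[pname]}"
        entries[name] = calls[s].copy()
        parent[name] = pname
        n_individuals[name] = 1
        _, ov = _distance(calls[s], entries[pname])
        rows.append(
            dict(individual_id=matrix.individuals[s], kind="minor_variant",
                 haplotype=pname, entry=name, k_diffs=d,
                 matched=ov - d, mismatched=d)
        )
    for s in unassigned:
        rows.append(dict(individual_id=matrix.individuals[s], kind="unassigned"))
    for i in np.flatnonzero(het_mask):
        rows.append(
            dict(individual_id=matrix.individuals[i], kind="het_deferred",
                 het_sites=int((calls[i] == HET).sum()))
        )

    catalog = HaplotypeCatalog(
        entries=entries, majors=majors, parent=parent, n_individuals=n_individuals
    )
    table = pd.DataFrame(rows).reindex(columns=ASSIGNMENT_COLUMNS).astype(object)
    # restore input individual order
    pos = {ind: i for i, ind in enumerate(matrix.individuals)}
    table = table.sort_values(
        "individual_id", key=lambda s: s.map(pos), kind="stable"
    ).reset_index(drop=True)
    return catalog, table


def classify_heterozygotes(
    calls: np.ndarray,
    catalog: HaplotypeCatalog,
    f1_min_het_fraction: float = 0.9,
) -> dict:
    """Classify a het-bearing individual as an F1 between two catalog
    haplotypes, or as contaminated.

    For the pair (h1, h2) explaining the most het calls: the individual is
    F1(h1, h2) when its het calls cover at least ``f1_min_het_fraction`` of
    the sites diagnostic between h1 and h2 (where it has data) and its
    calls at the sites shared by h1 and h2 match that shared consensus.
    Partial heterozygosity is the signature of low quality / partial PCR
    contamination, not of a true cross.
    """
    if len(catalog) < 2:
        return dict(kind="contaminated", het_sites=int((calls == HET).sum()))
    if not (calls == HET).any():
        raise ConfigError("individual has no het call; route to cluster_haplotypes")
    names = catalog.names()
    best: tuple[int, str, str] | None = None
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            c1, c2 = catalog.consensus(names[i]), catalog.consensus(names[j])
            diag = (c1 != MISSING) & (c2 != MISSING) & (c1 != c2)
            explained = int(((calls == HET) & diag).sum())
            if best is None or explained > best[0]:
                best = (explained, names[i], names[j])
    explained, h1, h2 = best
    het_sites = int((calls == HET).sum())
    if explained == 0:
        return dict(kind="contaminated", het_sites=het_sites)
    c1, c2 = catalog.consensus(h1), catalog.consensus(h2)
    diag = (c1 != MISSING) & (c2 != MISSING) & (c1 != c2) & (calls != MISSING)
    n_diag = int(diag.sum())
    het_frac = ((calls == HET) & diag).sum() / n_diag if n_diag else 0.0
    shared = (c1 != MISSING) & (c1 == c2) & (calls != MISSING)
    shared_mismatch = int((calls[shared] != c1[shared]).sum())
    if het_frac >= f1_min_het_fraction and shared_mismatch == 0:
        return dict(
            kind="F1", h1=h1, h2=h2, het_sites=het_sites,
            matched=n_diag, mismatched=shared_mismatch,
        )
    return dict(kind="contaminated", h1=h1, h2=h2, het_sites=het_sites)


def detect_recombinants(
    calls: np.ndarray,
    sites: pd.DataFrame,
    catalog: HaplotypeCatalog,
    min_block_sites: int = 3,
) -> dict | None:
    """Detect a homozygous chromosomal mosaic of two catalog haplotypes.

    The two best-matching haplotypes paint the individual's diagnostic
    sites; maximal runs of at least ``min_block_sites`` consecutive
    diagnostic sites from the non-background haplotype become segments with
    breakpoint intervals between the flanking diagnostic positions. Returns
    a recombinant record, an ``unassigned`` record when the catalog is too
    small, or ``None`` (fall through to minor-variant/unassigned logic)
    when no segment reaches the minimum run length — an isolated discordant
    site is mutation or genotyping error, not a recombination event.
    """
    if len(catalog) < 2:
        return dict(kind="unassigned")
    if (calls == HET).any():
        raise ConfigError("recombinant painting requires a homozygous individual")
    names = catalog.names()
    d_bg, h_bg = min(
        ((_distance(calls, catalog.consensus(n))[0]), n) for n in names
    )
    if d_bg == 0:
        return None  # exact catalog match: nothing to paint
    c_bg = catalog.consensus(h_bg)
    # partner = the haplotype that best explains the background-discordant
    # sites (the overall second-best match may not be the segment donor)
    discord = (calls != MISSING) & (c_bg != MISSING) & (calls != c_bg)
    best_score, h_alt = -1, None
    for n in names:
        if n == h_bg:
            continue
        c = catalog.consensus(n)
        score = int(((c != MISSING) & (calls == c) & discord).sum())
        if score > best_score:
            best_score, h_alt = score, n
    if best_score <= 0:
        return None  # no catalog haplotype explains the discordances
    c_alt = catalog.consensus(h_alt)
    diag = (
        (c_bg != MISSING) & (c_alt != MISSING) & (c_bg != c_alt)
        & (calls != MISSING)
    )
    segments: list[dict] = []
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero((chroms == chrom) & diag)
        if len(idx) == 0:
            continue
        paint = np.where(
            calls[idx] == c_alt[idx], 1, np.where(calls[idx] == c_bg[idx], 0, -1)
        )
        run_start = None
        for k in range(len(idx) + 1):
            is_alt = k < len(idx) and paint[k] == 1
            if is_alt and run_start is None:
                run_start = k
            elif not is_alt and run_start is not None:
                if k - run_start >= min_block_sites:
                    lo = int(pos[idx[run_start - 1]]) if run_start > 0 else None
                    hi = int(pos[idx[k]]) if k < len(idx) else None
                    segments.append(
                        dict(
                            chrom=str(chrom),
                            start_pos=int(pos[idx[run_start]]),
                            end_pos=int(pos[idx[k - 1]]),
                            n_sites=k - run_start,
                            breakpoint_before=lo,
                            breakpoint_after=hi,
                            haplotype=h_alt,
                        )
                    )
                run_start = None
    if segments:
        return dict(kind="recombinant", haplotype=h_bg, h1=h_bg, h2=h_alt,
                    segments=segments, mismatched=d_bg)
    return None


def call_haplotypes(
    matrix: GenotypeMatrix,
    minor_variant_max_diff: int = 2,
    min_overlap: float = 0.5,
    f1_min_het_fraction: float = 0.9,
    min_block_sites: int = 3,
    location_code: str = "L",
) -> tuple[HaplotypeCatalog, pd.DataFrame]:
    """Full classification: cluster, then resolve heterozygotes and
    recombinant-patterned singletons.

    Singleton major haplotypes (groups of one, too distant from every other
    group to be minor variants) are re-examined against the multi-member
    catalog: when their discordances form chromosomal blocks they are
    reported as recombinants and removed from the catalog.
    """
    catalog, table = cluster_haplotypes(
        matrix, minor_variant_max_diff, min_overlap, location_code
    )
    idx_of = {ind: i for i, ind in enumerate(matrix.individuals)}

    # recombinant check for singleton majors, against the rest of the catalog
    multi = [n for n in catalog.majors if catalog.n_individuals[n] >= 2]
    drop: list[str] = []
    if len(multi) >= 2:
        sub = HaplotypeCatalog(
            entries={n: catalog.entries[n] for n in multi},
            majors=multi,
            n_individuals={n: catalog.n_individuals[n] for n in multi},
        )
        for name in catalog.majors:
            if catalog.n_individuals[name] != 1:
                continue
            row = table.index[
                (table["haplotype"] == name) & (table["kind"] == "haplotype")
            ]
            ind = table.loc[row[0], "individual_id"]
            res = detect_recombinants(
                matrix.calls[idx_of[ind]], matrix.sites, sub, min_block_sites
            )
            if res is not None and res["kind"] == "recombinant":
                table.loc[row[0], ["kind", "haplotype", "h1", "h2"]] = (
                    "recombinant", res["haplotype"], res["h1"], res["h2"]
                )
                table.loc[row[0], "segments"] = ";".join(
                    f"{s['chrom']}:{s['start_pos']}-{s['end_pos']}({s['n_sites']})"
                    for s in res["segments"]
                )
                drop.append(name)
    if drop:
        catalog = _drop_and_rename(catalog, drop, table, location_code)

    # resolve deferred heterozygotes
    for r in table.index[table["kind"] == "het_deferred"]:
        ind = table.loc[r, "individual_id"]
        res = classify_heterozygotes(
            matrix.calls[idx_of[ind]], catalog, f1_min_het_fraction
        )
        table.loc[r, "kind"] = res["kind"]
        for col in ("h1", "h2", "het_sites"):
            if col in res:
                table.loc[r, col] = res[col]
    return catalog, table


def _drop_and_rename(
    catalog: HaplotypeCatalog,
    drop: list[str],
    table: pd.DataFrame,
    location_code: str,
) -> HaplotypeCatalog:
    """Remove entries and re-issue names in descending-count order,
    rewriting the assignment table in place."""
    kept_majors = [n for n in catalog.majors if n not in drop]
    order = sorted(
        kept_majors, key=lambda n: (-catalog.n_individuals[n], catalog.majors.index(n))
    )
    rename = {old: f"H{location_code}{i}" for i, old in enumerate(order, start=1)}
    minor_counter = {new: 0 for new in rename.values()}
    entries, majors, parent, n_ind = {}, [], {}, {}
    for old in order:
        new = rename[old]
        majors.append(new)
        entries[new] = catalog.entries[old]
        n_ind[new] = catalog.n_individuals[old]
    for old_minor, old_parent in catalog.parent.items():
        new_parent = rename[old_parent]
        minor_counter[new_parent] += 1
        new = f"{new_parent}-{minor_counter[new_parent]}"
        rename[old_minor] = new
        entries[new] = catalog.entries[old_minor]
        parent[new] = new_parent
        n_ind[new] = catalog.n_individuals[old_minor]
    for col in ("haplotype", "h1", "h2", "entry"):
        table[col] = table[col].map(lambda v: rename.get(v, v))
    return HaplotypeCatalog(
        entries=entries, majors=majors, parent=parent, n_individuals=n_ind
    )
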