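"""Core containers shared across the pipeline.

Genotype calls are stored as a dense ``int8`` matrix (individuals x sites)
using the codes below. A selfing population is expected to be almost
entirely ``HOM_REF``/``HOM_ALT``; heterozygous calls mark rare outcross
progeny (or noise) and are handled specially downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Genotype call codes (match the 0/1/2/NA TSV dialect).
MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

CHROMOSOMES: tuple[str, ...] = ("I", "II", "III", "IV", "V", "X")

#: Controlled vocabulary for sample substrates.
SUBSTRATES: tuple[str, ...] = (
    "fruit", "stem", "leaf_litter", "soil", "grass", "moss",
    "snail", "slug", "isopod", "other",
)

#: Substrates excluded by default from co-occurrence / colonization analyses
#: (non-feeding or vector substrates rather than boom-phase demes).
DEFAULT_SUBSTRATE_EXCLUDES: frozenset[str] = frozenset(
    {"leaf_litter", "soil", "grass", "moss", "snail"}
)

SITE_COLUMNS = ["chrom", "pos", "rad_locus", "ref", "alt"]


class DemeseedError(Exception):
    """Base class for all package errors."""


class ConfigError(DemeseedError):
    """Invalid configuration or parameters."""


class FormatError(DemeseedError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-SNP-sites genotype table.

    Parameters
    ----------
    individuals
        Individual identifiers, one per matrix row.
    sites
        DataFrame with columns ``chrom, pos, rad_locus, ref, alt``; one row
        per matrix column. Positions are 1-based and strictly increasing
        within each chromosome.
    calls
        ``int8`` array of shape ``(n_individuals, n_sites)`` with values in
        ``{MISSING, HOM_REF, HET, HOM_ALT}``.
    """

    individuals: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sites = self.sites.reset_index(drop=True)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ConfigError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ConfigError(f"sites table lacks columns {missing_cols}")
        bad = ~np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if bad.any():
            raise ConfigError("calls contain values outside {-1,0,1,2}")
        self._check_site_order()

    def _check_site_order(self) -> None:
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ConfigError("duplicate (chrom, pos) in sites")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ConfigError("positions not strictly increasing within chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_labels(self) -> list[str]:
        """``chrom:pos`` label per site (TSV column headers)."""
        return [f"{c}:{p}" for c, p in zip(self.sites["chrom"], self.sites["pos"])]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in index],
            sites=self.sites.copy(),
            calls=self.calls[index, :].copy(),
        )

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individuals.index(individual)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class SampleFrame:
    """Per-sample metadata plus the individual -> sample mapping.

    ``samples`` columns: ``sample_id, location, date, substrate, x_m, y_m``
    (and optionally ``transect_m``). ``individuals`` columns:
    ``individual_id, sample_id``.
    """

    samples: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        for col in ("sample_id", "location", "date", "substrate"):
            if col not in self.samples.columns:
                raise ConfigError(f"samples table lacks column {col!r}")
        if self.samples["sample_id"].duplicated().any():
            raise ConfigError("duplicate sample_id")
        for col in ("individual_id", "sample_id"):
            if col not in self.individuals.columns:
                raise ConfigError(f"individuals table lacks column {col!r}")
        if self.individuals["individual_id"].duplicated().any():
            raise ConfigError("an individual maps to more than one sample")
        known = set(self.samples["sample_id"])
        unknown = set(self.individuals["sample_id"]) - known
        if unknown:
            raise ConfigError(f"individuals reference unknown samples: {sorted(unknown)[:5]}")
        if {"x_m", "y_m"} <= set(self.samples.columns):
            xy = self.samples[["x_m", "y_m"]].to_numpy(float)
            if not np.isfinite(xy[~np.isnan(xy)]).all():
                raise ConfigError("non-finite coordinates")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_of(self) -> dict[str, str]:
        """individual_id -> sample_id mapping."""
        return dict(
            zip(self.individuals["individual_id"], self.individuals["sample_id"])
        )

    def coordinates(self) -> np.ndarray:
        """(n_samples, 2) array of x/y metre coordinates."""
        if not {"x_m", "y_m"} <= set(self.samples.columns):
            raise ConfigError("sample table has no x_m/y_m coordinates")
        return self.samples[["x_m", "y_m"]].to_numpy(float)

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean distances between samples on (x, y); falls back to
        absolute transect-position differences when only ``transect_m``
        is available (the two sampling geometries used in the field)."""
        if {"x_m", "y_m"} <= set(self.samples.columns) and not (
            self.samples[["x_m", "y_m"]].isna().any().any()
        ):
            xy = self.coordinates()
            diff = xy[:, None, :] - xy[None, :, :]
            return np.sqrt((diff**2).sum(axis=2))
        if "transect_m" in self.samples.columns:
            t = self.samples["transect_m"].to_numpy(float)
            return np.abs(t[:, None] - t[None, :])
        raise ConfigError("sample table has neither x_m/y_m nor transect_m")
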