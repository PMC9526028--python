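"""Data schemas, delimited-text I/O, and the study filtering/pooling rules.

The analysis consumes three tables in a fixed orientation:

* a site-by-species abundance matrix of completed brood cells (counts),
  with per-site year provenance;
* a species-by-trait table of mixed-type ecological traits with a declared
  kind (continuous or nominal) per trait;
* a per-site covariate table: green-space type plus land-cover proportions
  (impervious / open green / closed green) at one or more buffer scales.

Filtering rules for the clustering analysis (criterion I) and the ordination
analysis (criterion III) differ only in the minimum number of species a site
must hold; both are expressed through :func:`apply_study_filters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

UGS_TYPES = ("community_garden", "home_garden", "public_park", "green_roof")

#: Land-cover fractions carried per buffer scale (water excluded upstream).
COVER_CLASSES = ("impervious", "open_green", "closed_green")

_PROP_TOL = 1e-6


class SchemaError(ValueError):
    """A table violates the schema contract (shape, sign, duplication...)."""


@dataclass
class CommunityMatrix:
    """Site-by-species abundance matrix with year provenance.

    Parameters
    ----------
    site_ids, species_ids : sequences of unique identifiers.
    abundance : (n_sites, n_species) array of non-negative integers.
    years_sampled : mapping from site id to the set of survey years the
        site was sampled in (used by the insufficient-years filter).
    """

    site_ids: list[str]
    species_ids: list[str]
    abundance: np.ndarray
    years_sampled: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        self.abundance = np.asarray(self.abundance)
        if self.abundance.shape != (len(self.site_ids), len(self.species_ids)):
            raise SchemaError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise SchemaError("duplicate site ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise SchemaError("duplicate species ids")
        arr = self.abundance
        if arr.size:
            if np.any(arr < 0):
                i, j = np.argwhere(arr < 0)[0]
                raise SchemaError(
                    f"negative abundance at site {self.site_ids[i]!r}, "
                    f"species {self.species_ids[j]!r}"
                )
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                i, j = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise SchemaError(
                    f"non-integer abundance at site {self.site_ids[i]!r}, "
                    f"species {self.species_ids[j]!r}"
                )
        self.abundance = arr.astype(np.int64)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.site_ids, columns=self.species_ids
        )

    def subset(
        self,
        sites: Sequence[str] | None = None,
        species: Sequence[str] | None = None,
    ) -> "CommunityMatrix":
        sites = list(self.site_ids if sites is None else sites)
        species = list(self.species_ids if species is None else species)
        si = [self.site_ids.index(s) for s in sites]
        sj = [self.species_ids.index(s) for s in species]
        return CommunityMatrix(
            sites,
            species,
            self.abundance[np.ix_(si, sj)] if si and sj else
            np.zeros((len(si), len(sj)), dtype=np.int64),
            {s: self.years_sampled.get(s, frozenset()) for s in sites},
        )


@dataclass
class TraitTable:
    """Species-by-trait table with a per-trait type specification.

    ``variable_spec`` maps each trait column to ``{"kind": "continuous" |
    "nominal", "weight": float}``. In the study configuration there are
    exactly seven traits: body size (continuous, mm intertegular span),
    native status, diet type, diet specialization, trophic rank, nesting
    material, and number of nesting materials.
    """

    traits: pd.DataFrame
    variable_spec: dict[str, dict]

    def __post_init__(self) -> None:
        self.traits = self.traits.copy()
        self.traits.index = self.traits.index.astype(str)
        if self.traits.index.has_duplicates:
            raise SchemaError("duplicate species ids in trait table")
        missing = set(self.traits.columns) - set(self.variable_spec)
        if missing:
            raise SchemaError(f"variable_spec missing traits: {sorted(missing)}")
        for name, spec in self.variable_spec.items():
            if name not in self.traits.columns:
                raise SchemaError(f"variable_spec names unknown trait {name!r}")
            kind = spec.get("kind")
            if kind not in ("continuous", "nominal"):
                raise SchemaError(f"trait {name!r}: unknown kind {kind!r}")
            spec.setdefault("weight", 1.0)
        if "body_size" in self.traits.columns:
            bs = pd.to_numeric(self.traits["body_size"], errors="coerce")
            if (bs.dropna() <= 0).any():
                raise SchemaError("body_size must be positive where present")

    @property
    def species_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def continuous_traits(self) -> list[str]:
        return [t for t in self.trait_names
                if self.variable_spec[t]["kind"] == "continuous"]

    def nominal_traits(self) -> list[str]:
        return [t for t in self.trait_names
                if self.variable_spec[t]["kind"] == "nominal"]

    def subset(self, species: Sequence[str]) -> "TraitTable":
        return TraitTable(self.traits.loc[list(species)], dict(self.variable_spec))


@dataclass
class SiteTable:
    """Per-site green-space type, land-cover proportions, and coordinates.

    ``data`` is indexed by site id with columns ``ugs_type``,
    ``{cover}_{scale}`` for each cover class and buffer scale (proportions
    in [0, 1]; water is excluded from the denominator so the three classes
    sum to ~1), and optional projected ``x`` / ``y`` coordinates in meters.
    """

    data: pd.DataFrame
    scales: tuple[int, ...] = (250, 500)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate site ids in site table")
        if "ugs_type" in self.data.columns:
            bad = set(self.data["ugs_type"].dropna()) - set(UGS_TYPES)
            if bad:
                raise SchemaError(f"unknown green-space types: {sorted(bad)}")
        for scale in self.scales:
            cols = [f"{c}_{scale}" for c in COVER_CLASSES]
            present = [c for c in cols if c in self.data.columns]
            if not present:
                continue
            block = self.data[present].astype(float)
            if ((block < -_PROP_TOL) | (block > 1 + _PROP_TOL)).any().any():
                raise SchemaError(f"cover proportions outside [0,1] at scale {scale}")
            if len(present) == len(cols):
                total = block.sum(axis=1)
                if (total > 1 + 1e-3).any():
                    raise SchemaError(
                        f"cover proportions sum to >1 at scale {scale}"
                    )

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    def covariates(self, scale: int) -> pd.DataFrame:
        cols = [f"{c}_{scale}" for c in COVER_CLASSES]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"site table lacks columns {missing}")
        out = self.data[cols].astype(float).copy()
        out.columns = list(COVER_CLASSES)
        return out

    def coordinates(self) -> pd.DataFrame:
        if not {"x", "y"} <= set(self.data.columns):
            raise SchemaError("site table has no x/y coordinates")
        return self.data[["x", "y"]].astype(float)

    def subset(self, sites: Sequence[str]) -> "SiteTable":
        return SiteTable(self.data.loc[list(sites)], self.scales)


@dataclass
class StudyFilterReport:
    """Record of every site/species removal with its (first-match) reason."""

    n_sites_in: int
    n_sites_out: int
    n_species_in: int
    n_species_out: int
    site_removals: dict[str, str] = field(default_factory=dict)
    species_removals: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites_out != self.n_sites_in - len(self.site_removals):
            raise SchemaError("site removal bookkeeping inconsistent")
        if self.n_species_out != self.n_species_in - len(self.species_removals):
            raise SchemaError("species removal bookkeeping inconsistent")

    def to_dict(self) -> dict:
        return {
            "n_sites_in": self.n_sites_in,
            "n_sites_out": self.n_sites_out,
            "n_species_in": self.n_species_in,
            "n_species_out": self.n_species_out,
            "site_removals": dict(self.site_removals),
            "species_removals": dict(self.species_removals),
        }


# ---------------------------------------------------------------------------
# readers / writers

def read_community(path: str | Path) -> CommunityMatrix:
    """Read a community matrix from CSV.

    First column holds site ids, an optional ``year`` column holds the
    survey year, and every remaining column is a species count. Rows
    sharing a site id (and differing in year) represent yearly records;
    duplicate site-year rows are rejected.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("community table needs a site column plus species")
    site_col = df.columns[0]
    df[site_col] = df[site_col].astype(str)
    has_year = "year" in df.columns[1:]
    species_cols = [c for c in df.columns[1:] if c != "year"]

    for col in species_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise SchemaError(
                f"non-numeric abundance at row {row}, column {col!r}"
            )
        bad = vals[(vals < 0) | (np.mod(vals, 1) != 0)]
        if len(bad):
            raise SchemaError(
                f"invalid abundance {bad.iloc[0]} at row {bad.index[0]}, "
                f"column {col!r}"
            )
        df[col] = vals.astype(np.int64)

    if has_year:
        if df.duplicated(subset=[site_col, "year"]).any():
            dup = df[df.duplicated(subset=[site_col, "year"])].iloc[0]
            raise SchemaError(
                f"duplicate site-year row: {dup[site_col]!r} / {dup['year']}"
            )
        years = {
            site: frozenset(int(y) for y in grp["year"])
            for site, grp in df.groupby(site_col, sort=False)
        }
    else:
        if df[site_col].duplicated().any():
            dup = df[site_col][df[site_col].duplicated()].iloc[0]
            raise SchemaError(f"duplicate site row: {dup!r}")
        years = {site: frozenset() for site in df[site_col]}

    # keep yearly rows distinct; pooling is explicit via pool_years
    site_ids = list(dict.fromkeys(df[site_col]))
    if has_year and df[site_col].duplicated().any():
        # stack yearly rows: one synthetic row id per site-year
        mat = np.zeros((len(df), len(species_cols)), dtype=np.int64)
        mat[:, :] = df[species_cols].to_numpy()
        row_ids = [f"{s}@{y}" for s, y in zip(df[site_col], df["year"])]
        cm = CommunityMatrix(row_ids, species_cols, mat)
        cm.years_sampled = {
            rid: frozenset([int(y)])
            for rid, y in zip(row_ids, df["year"])
        }
        cm._yearly_site_of_row = dict(zip(row_ids, df[site_col]))  # type: ignore[attr-defined]
        return cm
    mat = df.set_index(site_col).loc[site_ids, species_cols].to_numpy()
    return CommunityMatrix(site_ids, species_cols, mat, years)


def pool_years(cm: CommunityMatrix) -> CommunityMatrix:
    """Sum yearly abundance records into one row per site.

    Abundances are summed across years; ``years_sampled`` is preserved so
    the insufficient-years filter can still act. Total abundance per
    species per site is conserved.
    """
    site_of_row = getattr(cm, "_yearly_site_of_row", None)
    if site_of_row is None:
        site_of_row = {rid: rid.split("@")[0] if "@" in rid else rid
                       for rid in cm.site_ids}
    sites = list(dict.fromkeys(site_of_row[r] for r in cm.site_ids))
    pooled = np.zeros((len(sites), cm.n_species), dtype=np.int64)
    years: dict[str, set[int]] = {s: set() for s in sites}
    idx = {s: i for i, s in enumerate(sites)}
    for i, rid in enumerate(cm.site_ids):
        s = site_of_row[rid]
        pooled[idx[s]] += cm.abundance[i]
        years[s] |= set(cm.years_sampled.get(rid, frozenset()))
    return CommunityMatrix(
        sites, list(cm.species_ids), pooled,
        {s: frozenset(v) for s, v in years.items()},
    )


def read_trait_table(
    path: str | Path, variable_spec: Mapping[str, dict] | None = None
) -> TraitTable:
    """Read a species-by-trait CSV (first column species id).

    When ``variable_spec`` is omitted, numeric columns are declared
    continuous and all others nominal.
    """
    df = pd.read_csv(path, index_col=0)
    if variable_spec is None:
        variable_spec = {
            c: {"kind": "continuous" if pd.api.types.is_numeric_dtype(df[c])
                else "nominal", "weight": 1.0}
            for c in df.columns
        }
    return TraitTable(df, {k: dict(v) for k, v in variable_spec.items()})


def read_site_table(path: str | Path, scales: Sequence[int] = (250, 500)) -> SiteTable:
    df = pd.read_csv(path, index_col=0)
    return SiteTable(df, tuple(scales))


def write_filter_report(report: StudyFilterReport, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# study filters

def apply_study_filters(
    cm: CommunityMatrix,
    traits: TraitTable,
    *,
    required_years: int = 3,
    min_species: int = 2,
    species_exclusions: Sequence[str] = (),
) -> tuple[CommunityMatrix, TraitTable, StudyFilterReport]:
    """Apply the study's site/species retention rules to a pooled matrix.

    Species filters run first (missing body size, explicit exclusions),
    then site filters (insufficient survey years, uncolonized, fewer than
    ``min_species`` species present) — so a site reduced to one species by
    a species drop counts as a singleton. Each removed id records the
    first matching reason.
    """
    species_removals: dict[str, str] = {}
    for sp in cm.species_ids:
        if sp in species_exclusions:
            species_removals[sp] = "excluded_by_config"
        elif sp not in traits.species_ids or (
            "body_size" in traits.trait_names
            and pd.isna(traits.traits.loc[sp, "body_size"])
        ):
            species_removals[sp] = "missing_body_size"
    keep_species = [s for s in cm.species_ids if s not in species_removals]
    if not keep_species:
        raise SchemaError("species filters removed every species")

    cm2 = cm.subset(species=keep_species)
    site_removals: dict[str, str] = {}
    for i, site in enumerate(cm2.site_ids):
        row = cm2.abundance[i]
        n_years = len(cm2.years_sampled.get(site, frozenset()))
        if cm2.years_sampled.get(site) and n_years < required_years:
            site_removals[site] = "insufficient_years"
        elif row.sum() == 0:
            site_removals[site] = "uncolonized"
        elif int((row > 0).sum()) < min_species:
            site_removals[site] = "singleton"
    keep_sites = [s for s in cm2.site_ids if s not in site_removals]
    if not keep_sites:
        raise SchemaError("site filters removed every site")

    out_cm = cm2.subset(sites=keep_sites)
    # drop species never observed in the retained sites from the trait table
    out_traits = traits.subset([s for s in keep_species if s in traits.species_ids])
    report = StudyFilterReport(
        n_sites_in=cm.n_sites,
        n_sites_out=out_cm.n_sites,
        n_species_in=cm.n_species,
        n_species_out=len(keep_species),
        site_removals=site_removals,
        species_removals=species_removals,
    )
    return out_cm, out_traits, report


def apply_criterion1_filters(
    cm: CommunityMatrix, traits: TraitTable, config: Mapping | None = None
) -> tuple[CommunityMatrix, TraitTable, StudyFilterReport]:
    """Filters for the clustering analysis: a site needs >= 2 species."""
    config = dict(config or {})
    return apply_study_filters(
        cm,
        traits,
        required_years=config.get("required_years", 3),
        min_species=config.get("min_species", 2),
        species_exclusions=config.get("species_exclusions", ()),
    )


def apply_criterion3_filters(
    cm: CommunityMatrix, traits: TraitTable, config: Mapping | None = None
) -> tuple[CommunityMatrix, TraitTable, StudyFilterReport]:
    """Filters for the ordination analysis: single-species sites retained."""
    config = dict(config or {})
    config["min_species"] = 1
    return apply_criterion1_filters(cm, traits, config)
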