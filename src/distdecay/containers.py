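"""Core data containers and tabular I/O.

Three containers are shared by every stage of the pipeline:

``OccurrenceMatrix``
    Binary site x species incidence. Sites must be non-empty; species
    recorded nowhere are dropped with a warning (zonal subsetting creates
    them routinely).
``SiteTable``
    Per-site metadata: centroid coordinates (decimal degrees, WGS84),
    mean elevation and elevation range (m), area (km^2), and a block of
    named environmental variables.
``PairwiseMatrix``
    A labeled symmetric matrix of pairwise similarities or distances.

The canonical unrolling of a ``PairwiseMatrix`` into a vector of the
n(n-1)/2 unordered pairs is :func:`pair_vector`: pairs (i, j) with i < j
in row-major order, i.e. the condensed order of
:func:`scipy.spatial.distance.squareform`. Every regression and Mantel
statistic in this package consumes that ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8

#: columns every site-metadata table must provide, in canonical order
SITE_REQUIRED_COLUMNS = ("site_id", "lon", "lat", "mean_elev", "elev_range", "area")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dupes}")


@dataclass
class OccurrenceMatrix:
    """Binary site x species incidence matrix.

    Parameters
    ----------
    site_ids, species_ids : sequences of str
        Row and column labels, order preserved.
    incidence : ndarray of shape (n_sites, n_species)
        Entries in {0, 1}; 1 means the species was recorded in the site.
    """

    site_ids: list[str]
    species_ids: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        inc = np.asarray(self.incidence)
        if inc.ndim != 2 or inc.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        _check_unique(self.site_ids, "site")
        _check_unique(self.species_ids, "species")
        bad = ~np.isin(inc, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at site {self.site_ids[i]!r}, "
                f"species {self.species_ids[j]!r}: {inc[i, j]!r}"
            )
        inc = inc.astype(np.int8)
        empty_sites = np.flatnonzero(inc.sum(axis=1) == 0)
        if empty_sites.size:
            names = [self.site_ids[i] for i in empty_sites]
            raise ValidationError(f"sites with no recorded species: {names}")
        absent = np.flatnonzero(inc.sum(axis=0) == 0)
        if absent.size:
            names = [self.species_ids[j] for j in absent]
            logger.warning("dropping %d species recorded in no site: %s", len(names), names)
            keep = np.setdiff1d(np.arange(inc.shape[1]), absent)
            inc = inc[:, keep]
            self.species_ids = [self.species_ids[j] for j in keep]
        self.incidence = inc

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_pairs(self) -> int:
        n = self.n_sites
        return n * (n - 1) // 2

    def richness(self) -> pd.Series:
        """Species count per site."""
        return pd.Series(self.incidence.sum(axis=1), index=self.site_ids, name="richness")

    def subset(self, site_ids) -> "OccurrenceMatrix":
        """Restrict to the given sites (order as given); empty species are dropped."""
        pos = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown site ids: {missing}")
        idx = [pos[s] for s in site_ids]
        return OccurrenceMatrix(list(site_ids), list(self.species_ids), self.incidence[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.site_ids, columns=self.species_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="site_id")


def read_occurrence(path, orientation: str = "sites_by_species") -> OccurrenceMatrix:
    """Read a binary occurrence CSV.

    The file has a header row and a label first column. ``orientation``
    is ``"sites_by_species"`` (rows = sites, the default) or
    ``"species_by_sites"`` (transposed on read). Row/column order is
    preserved from the file.
    """
    df = pd.read_csv(path, index_col=0)
    if orientation == "species_by_sites":
        df = df.T
    elif orientation != "sites_by_species":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: occurrence table contains non-numeric cells")
    return OccurrenceMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


@dataclass
class SiteTable:
    """Per-site metadata.

    ``data`` holds one row per site with the canonical columns
    ``site_id, lon, lat, mean_elev, elev_range, area`` plus one column
    per environmental variable (``env_columns``). Coordinates are
    decimal degrees on WGS84; elevations in metres; area in km^2.
    """

    data: pd.DataFrame
    env_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in SITE_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"site table missing required columns: {missing}")
        df["site_id"] = df["site_id"].astype(str)
        _check_unique(df["site_id"], "site")
        if not self.env_columns:
            self.env_columns = [c for c in df.columns if c not in SITE_REQUIRED_COLUMNS]
        unknown = [c for c in self.env_columns if c not in df.columns]
        if unknown:
            raise ValidationError(f"environmental columns not in table: {unknown}")
        numeric = [c for c in SITE_REQUIRED_COLUMNS[1:]] + list(self.env_columns)
        for c in numeric:
            df[c] = pd.to_numeric(df[c], errors="raise")
        if df[numeric].isna().any().any():
            bad = df[numeric].columns[df[numeric].isna().any()].tolist()
            raise ValidationError(f"missing values in columns: {bad}")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (df["elev_range"] < 0).any():
            raise ValidationError("negative elevation range")
        if (df["area"] <= 0).any():
            raise ValidationError("non-positive area")
        self.data = df

    @property
    def site_ids(self) -> list[str]:
        return self.data["site_id"].tolist()

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def env_matrix(self) -> np.ndarray:
        """Site x variable array of the environmental block."""
        return self.data[self.env_columns].to_numpy(float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ValidationError(f"no column {name!r} in site table")
        return self.data[name].to_numpy(float)

    def subset(self, site_ids) -> "SiteTable":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown site ids: {missing}")
        idx = [pos[s] for s in site_ids]
        return SiteTable(self.data.iloc[idx], list(self.env_columns))

    def align_to(self, occ: OccurrenceMatrix) -> "SiteTable":
        """Reorder to an occurrence matrix's site order (ids must match as sets)."""
        if set(self.site_ids) != set(occ.site_ids):
            only_occ = sorted(set(occ.site_ids) - set(self.site_ids))
            raise ValidationError(f"site ids in occurrence but not metadata: {only_occ}")
        return self.subset(occ.site_ids)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_sites(path, env_columns: list[str] | None = None) -> SiteTable:
    """Read and validate a site-metadata CSV.

    Columns not among the required six are treated as environmental
    variables unless ``env_columns`` names them explicitly.
    """
    df = pd.read_csv(path)
    return SiteTable(df, env_columns or [])


@dataclass
class PairwiseMatrix:
    """Labeled symmetric matrix over site pairs.

    ``kind`` is ``"similarity"`` (values in [0, 1], unit diagonal) or
    ``"distance"`` (non-negative, zero diagonal).
    """

    site_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        _check_unique(self.site_ids, "site")
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} sites")
        if self.kind not in ("similarity", "distance"):
            raise ValidationError(f"kind must be 'similarity' or 'distance', got {self.kind!r}")
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValidationError("matrix is not symmetric within tolerance")
        v = (v + v.T) / 2.0
        if self.kind == "similarity":
            if (v < -SYMMETRY_TOL).any() or (v > 1 + SYMMETRY_TOL).any():
                raise ValidationError("similarity values outside [0, 1]")
            np.fill_diagonal(v, 1.0)
        else:
            if (v < -SYMMETRY_TOL).any():
                raise ValidationError("negative distances")
            np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_pairs(self) -> int:
        n = self.n_sites
        return n * (n - 1) // 2

    def subset(self, site_ids) -> "PairwiseMatrix":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown site ids: {missing}")
        idx = np.array([pos[s] for s in site_ids])
        return PairwiseMatrix(list(site_ids), self.values[np.ix_(idx, idx)], self.kind)

    def permute(self, order: np.ndarray) -> "PairwiseMatrix":
        """Apply a simultaneous row+column permutation (site relabeling)."""
        order = np.asarray(order)
        return PairwiseMatrix(
            [self.site_ids[i] for i in order],
            self.values[np.ix_(order, order)],
            self.kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="site_id")

    @classmethod
    def from_csv(cls, path, kind: str) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValidationError(f"{path}: row and column labels differ")
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)


def pair_index(n: int) -> list[tuple[int, int]]:
    """The (i, j), i < j pairs in canonical (row-major condensed) order."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def pair_vector(m: PairwiseMatrix) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Unroll the off-diagonal upper triangle into the canonical pair vector.

    Returns the length-n(n-1)/2 value vector and the matching (i, j)
    index pairs (i < j, row-major). This ordering is the package-wide
    convention; all matrix regressions consume it.
    """
    n = m.n_sites
    if n < 2:
        raise ValidationError("need at least 2 sites to form pairs")
    iu, ju = np.triu_indices(n, k=1)
    return m.values[iu, ju].copy(), list(zip(iu.tolist(), ju.tolist()))


def condensed(values: np.ndarray) -> np.ndarray:
    """Pair vector of a raw symmetric array (no container overhead)."""
    iu, ju = np.triu_indices(values.shape[0], k=1)
    return values[iu, ju]
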