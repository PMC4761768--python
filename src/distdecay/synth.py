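"""Synthetic landscapes and communities with known ground truth.

Emulates the structure of a mountainous county-level survey — sites on a
jittered grid, elevation from parametric ridges, spatially structured
environmental variables — and populates it with species whose presence
is governed by up to three switchable mechanisms:

* dispersal limitation — each species occupies sites within a range
  radius (~exponentially distributed around ``range_scale_km``) of its
  range centre;
* niche filtering — presence additionally requires the site's
  (standardized) environment to lie within the species' niche breadth of
  its optimum;
* isolation — crossing a ridge inflates the effective distance by a
  multiplicative barrier penalty, and the penalty can grow with
  elevation, so high-elevation assemblages are more local.

Effective distance between a site and a range centre is

    d_eff = d_geo * (1 + barrier_penalty * n_crossings)
                  * (1 + barrier_elev_scale * elev_norm)

with ``n_crossings`` the number of ridge crests crossed by the straight
path and ``elev_norm`` the mean elevation of the two endpoints relative
to the tallest ridge. Crude, but sufficient to create anisotropic and
elevation-dependent turnover with a one-line ground truth.

Per-site richness can be calibrated into a target band: a global
multiplicative radius factor is bisected until mean richness sits at the
band midpoint, then each site's membership list is clamped into the band
by ranking species on how marginally they qualify. All randomness flows
from one integer seed through named substreams, so identical seed +
config give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import OccurrenceMatrix, SiteTable
from .geodesic import geodesic_km

logger = logging.getLogger(__name__)

# substream tags: keep ridge geometry shared between landscape and occurrence
_STREAM_RIDGES = 0
_STREAM_LANDSCAPE = 1
_STREAM_OCCURRENCE = 2


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a 164-county mountain survey.

    ``range_scale_km=None`` disables dispersal limitation entirely;
    ``niche_breadth=None`` disables niche filtering;
    ``target_richness=None`` disables richness calibration/clamping.
    Breadths are in RMS standardized environment units.
    """

    n_sites: int = 164
    n_species: int = 191
    bbox: tuple[float, float, float, float] = (92.0, 106.0, 21.0, 35.0)  # lon0,lon1,lat0,lat1
    n_ridges: int = 4
    ridge_orientation_deg: float = 0.0  # crest-line bearing from north; 0 = south-north
    ridge_amplitude_m: float = 3500.0
    ridge_width_deg: float = 1.0
    base_elev_m: float = 500.0
    n_env: int = 9
    env_spatial_corr: float = 0.7
    range_scale_km: float | None = 400.0
    niche_breadth: float | None = 1.2
    barrier_penalty: float = 0.5
    barrier_elev_scale: float = 0.0
    target_richness: tuple[int, int] | None = (17, 87)

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("need at least 4 sites")
        lon0, lon1, lat0, lat1 = self.bbox
        if lon0 >= lon1 or lat0 >= lat1:
            raise ValueError(f"degenerate bounding box {self.bbox}")
        if self.range_scale_km is not None and self.range_scale_km <= 0:
            raise ValueError("range_scale_km must be positive (or None)")
        if not 0 <= self.env_spatial_corr <= 1:
            raise ValueError("env_spatial_corr must be in [0, 1]")
        if self.target_richness is not None:
            lo, hi = self.target_richness
            if not 1 <= lo <= hi <= self.n_species:
                raise ValueError("target_richness bounds must satisfy 1 <= lo <= hi <= n_species")


@dataclass
class SynthTruth:
    """Ground truth behind a generated occurrence matrix."""

    centers_lon: np.ndarray
    centers_lat: np.ndarray
    radii_km: np.ndarray | None
    optima: np.ndarray | None
    breadths: np.ndarray | None
    ridge_crests: np.ndarray
    radius_multiplier: float
    dispersal_on: bool
    niche_on: bool
    isolation_on: bool
    config: SynthConfig = field(repr=False, default=None)


def _rng(seed: int | None, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, 0 if seed is None else int(seed)])


def _ridge_geometry(cfg: SynthConfig, seed: int | None):
    """Crest positions/widths/amplitudes in the ridge-normal coordinate."""
    rng = _rng(seed, _STREAM_RIDGES)
    lon0, lon1, lat0, lat1 = cfg.bbox
    theta = math.radians(cfg.ridge_orientation_deg)
    # normal coordinate of a point: t = lon*cos(theta) + lat*sin(theta)
    corners_t = [
        lon * math.cos(theta) + lat * math.sin(theta)
        for lon in (lon0, lon1)
        for lat in (lat0, lat1)
    ]
    t_lo, t_hi = min(corners_t), max(corners_t)
    if cfg.n_ridges == 0:
        return theta, np.array([]), np.array([]), np.array([])
    pos = np.linspace(t_lo, t_hi, cfg.n_ridges + 2)[1:-1]
    pos = pos + rng.uniform(-0.15, 0.15, cfg.n_ridges) * (t_hi - t_lo) / (cfg.n_ridges + 1)
    widths = cfg.ridge_width_deg * rng.uniform(0.7, 1.3, cfg.n_ridges)
    amps = cfg.ridge_amplitude_m * rng.uniform(0.6, 1.0, cfg.n_ridges)
    return theta, np.sort(pos), widths, amps


def _normal_coord(theta: float, lon, lat):
    return np.asarray(lon) * math.cos(theta) + np.asarray(lat) * math.sin(theta)


def _elevation(cfg, geometry, lon, lat) -> np.ndarray:
    theta, crests, widths, amps = geometry
    t = _normal_coord(theta, lon, lat)
    elev = np.full_like(np.asarray(t, dtype=float), cfg.base_elev_m)
    for c, w, a in zip(crests, widths, amps):
        elev = elev + a * np.exp(-((t - c) ** 2) / (2 * w**2))
    return elev


def generate_landscape(cfg: SynthConfig, seed: int | None = None) -> SiteTable:
    """Sites on a jittered grid with ridge-driven elevation and environment.

    Environmental variables mix a smooth spatial field (linear trends in
    position and elevation plus a random low-frequency sinusoid) with
    white noise, weighted ``env_spatial_corr`` : ``1 − env_spatial_corr``.
    Deterministic for a given (config, seed).
    """
    rng = _rng(seed, _STREAM_LANDSCAPE)
    geometry = _ridge_geometry(cfg, seed)
    lon0, lon1, lat0, lat1 = cfg.bbox

    # jittered grid: lay an oversized lattice, keep a random subset of cells
    aspect = (lon1 - lon0) / (lat1 - lat0)
    ncol = max(2, math.ceil(math.sqrt(cfg.n_sites * aspect)))
    nrow = max(2, math.ceil(cfg.n_sites / ncol))
    gx = np.linspace(lon0, lon1, ncol + 1)[:-1] + (lon1 - lon0) / (2 * ncol)
    gy = np.linspace(lat0, lat1, nrow + 1)[:-1] + (lat1 - lat0) / (2 * nrow)
    cells = np.array([(x, y) for y in gy for x in gx])
    pick = rng.choice(len(cells), size=cfg.n_sites, replace=False)
    lon = cells[pick, 0] + rng.uniform(-0.4, 0.4, cfg.n_sites) * (lon1 - lon0) / ncol
    lat = cells[pick, 1] + rng.uniform(-0.4, 0.4, cfg.n_sites) * (lat1 - lat0) / nrow
    lon = np.clip(lon, lon0, lon1)
    lat = np.clip(lat, lat0, lat1)

    mean_elev = _elevation(cfg, geometry, lon, lat)
    # local relief: surface spread over a ring of nearby probe points
    probes = []
    for dx, dy in [(0.25, 0), (-0.25, 0), (0, 0.25), (0, -0.25),
                   (0.18, 0.18), (-0.18, 0.18), (0.18, -0.18), (-0.18, -0.18)]:
        probes.append(_elevation(cfg, geometry, lon + dx, lat + dy))
    probes.append(mean_elev)
    probes = np.array(probes)
    elev_range = probes.max(axis=0) - probes.min(axis=0) + rng.uniform(50, 300, cfg.n_sites)

    area = rng.lognormal(mean=math.log(2500), sigma=0.5, size=cfg.n_sites)

    lon_n = (lon - lon.mean()) / max(lon.std(), 1e-9)
    lat_n = (lat - lat.mean()) / max(lat.std(), 1e-9)
    elev_n = (mean_elev - mean_elev.mean()) / max(mean_elev.std(), 1e-9)
    env = {}
    for j in range(cfg.n_env):
        w = rng.normal(size=3)
        freq = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * math.pi, size=2)
        smooth = (
            w[0] * lon_n
            + w[1] * lat_n
            + w[2] * elev_n
            + np.sin(freq[0] * lon_n + phase[0])
            + np.sin(freq[1] * lat_n + phase[1])
        )
        smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-9)
        noise = rng.normal(size=cfg.n_sites)
        env[f"env{j + 1}"] = cfg.env_spatial_corr * smooth + (1 - cfg.env_spatial_corr) * noise

    df = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:03d}" for i in range(cfg.n_sites)],
            "lon": lon,
            "lat": lat,
            "mean_elev": mean_elev,
            "elev_range": elev_range,
            "area": area,
            **env,
        }
    )
    return SiteTable(df)


def _scores(cfg: SynthConfig, sites: SiteTable, truth_parts: dict) -> np.ndarray:
    """Marginality score per (site, species); present when < 1 (at s = 1)."""
    n_sites, n_sp = sites.n_sites, cfg.n_species
    score_disp = np.zeros((n_sites, n_sp))
    if truth_parts["radii"] is not None:
        score_disp = truth_parts["eff_dist"] / truth_parts["radii"][None, :]
    score_niche = np.zeros((n_sites, n_sp))
    if truth_parts["breadths"] is not None:
        score_niche = truth_parts["mismatch"] / truth_parts["breadths"][None, :]
    return np.maximum(score_disp, score_niche)


def generate_occurrence(
    sites: SiteTable, cfg: SynthConfig, seed: int | None = None
) -> tuple[OccurrenceMatrix, SynthTruth]:
    """Populate a landscape with species under the configured mechanisms.

    Returns the occurrence matrix plus the ground truth (range centres,
    radii, niche optima, ridge crests, mechanism switches) needed to
    predict what the analysis pipeline should recover.
    """
    rng = _rng(seed, _STREAM_OCCURRENCE)
    geometry = _ridge_geometry(cfg, seed)
    theta, crests, _, _ = geometry
    lon0, lon1, lat0, lat1 = cfg.bbox
    n_sp = cfg.n_species

    c_lon = rng.uniform(lon0, lon1, n_sp)
    c_lat = rng.uniform(lat0, lat1, n_sp)

    dispersal_on = cfg.range_scale_km is not None
    niche_on = cfg.niche_breadth is not None
    if not dispersal_on and not niche_on:
        raise ValueError("at least one of dispersal or niche mechanisms must be enabled")

    radii = None
    eff_dist = None
    site_lon, site_lat = sites.column("lon"), sites.column("lat")
    if dispersal_on:
        radii = np.maximum(
            rng.exponential(cfg.range_scale_km, n_sp), 0.1 * cfg.range_scale_km
        )
        d_geo = geodesic_km(
            site_lat[:, None], site_lon[:, None], c_lat[None, :], c_lon[None, :]
        )
        t_sites = _normal_coord(theta, site_lon, site_lat)
        t_centers = _normal_coord(theta, c_lon, c_lat)
        crossings = np.zeros_like(d_geo)
        for c in crests:
            crossings += ((t_sites[:, None] - c) * (t_centers[None, :] - c) < 0)
        elev_sites = sites.column("mean_elev")
        elev_centers = _elevation(cfg, geometry, c_lon, c_lat)
        elev_norm = (
            (elev_sites[:, None] + elev_centers[None, :]) / 2.0
        ) / max(cfg.base_elev_m + cfg.ridge_amplitude_m, 1.0)
        eff_dist = (
            d_geo
            * (1 + cfg.barrier_penalty * crossings)
            * (1 + cfg.barrier_elev_scale * elev_norm)
        )

    optima = breadths = mismatch = None
    if niche_on:
        env = sites.env_matrix()
        mu, sd = env.mean(axis=0), np.maximum(env.std(axis=0), 1e-9)
        z = (env - mu) / sd
        anchor = rng.integers(0, sites.n_sites, n_sp)
        optima = z[anchor] + rng.normal(0, 0.3, (n_sp, z.shape[1]))
        breadths = cfg.niche_breadth * rng.uniform(0.75, 1.25, n_sp)
        # RMS distance in standardized environment space
        mismatch = np.sqrt(
            ((z[:, None, :] - optima[None, :, :]) ** 2).mean(axis=2)
        )

    parts = {
        "radii": radii,
        "eff_dist": eff_dist,
        "breadths": breadths,
        "mismatch": mismatch,
    }
    score = _scores(cfg, sites, parts)

    s = 1.0
    if cfg.target_richness is not None and dispersal_on:
        lo, hi = cfg.target_richness
        target_mean = (lo + hi) / 2.0

        def mean_richness(mult: float) -> float:
            ok = np.ones_like(score, dtype=bool)
            ok &= eff_dist <= radii[None, :] * mult
            if mismatch is not None:
                ok &= mismatch <= breadths[None, :]
            return float(ok.sum(axis=1).mean())

        # log-scale bisection on the global radius multiplier (<= 40 steps)
        lo_s, hi_s = -8.0, 8.0
        if mean_richness(2.0**hi_s) < target_mean:
            logger.warning(
                "richness calibration cannot reach the target mean even at "
                "maximal radii; consider widening niche_breadth"
            )
            s = 2.0**hi_s
        else:
            for _ in range(40):
                mid = (lo_s + hi_s) / 2
                if mean_richness(2.0**mid) < target_mean:
                    lo_s = mid
                else:
                    hi_s = mid
            s = 2.0**hi_s
        score = score.copy()
        if radii is not None:
            disp = eff_dist / (radii[None, :] * s)
            niche = (
                mismatch / breadths[None, :] if mismatch is not None else np.zeros_like(disp)
            )
            score = np.maximum(disp, niche)

    presence = score < 1.0

    if cfg.target_richness is not None:
        lo, hi = cfg.target_richness
        order = np.argsort(score, axis=1, kind="stable")
        for i in range(presence.shape[0]):
            k = int(presence[i].sum())
            if k < lo:
                presence[i, order[i, :lo]] = True
            elif k > hi:
                presence[i] = False
                presence[i, order[i, :hi]] = True
    else:
        # no band requested: still forbid empty sites (container invariant)
        for i in np.flatnonzero(presence.sum(axis=1) == 0):
            presence[i, int(np.argmin(score[i]))] = True

    # species observed nowhere get their single least-marginal site
    hi_cap = cfg.target_richness[1] if cfg.target_richness is not None else None
    for k in np.flatnonzero(presence.sum(axis=0) == 0):
        sites_order = np.argsort(score[:, k], kind="stable")
        placed = False
        for i in sites_order:
            if hi_cap is None or presence[i].sum() < hi_cap:
                presence[i, k] = True
                placed = True
                break
        if not placed:  # every site at the cap: drop the site's worst member
            i = sites_order[0]
            worst = max(np.flatnonzero(presence[i]), key=lambda j: score[i, j])
            presence[i, worst] = False
            presence[i, k] = True

    occ = OccurrenceMatrix(
        sites.site_ids,
        [f"sp{k + 1:03d}" for k in range(n_sp)],
        presence.astype(np.int8),
    )
    truth = SynthTruth(
        centers_lon=c_lon,
        centers_lat=c_lat,
        radii_km=None if radii is None else radii * s,
        optima=optima,
        breadths=breadths,
        ridge_crests=np.asarray(crests),
        radius_multiplier=s,
        dispersal_on=dispersal_on,
        niche_on=niche_on,
        isolation_on=cfg.barrier_penalty > 0 or cfg.barrier_elev_scale > 0,
        config=cfg,
    )
    return occ, truth


def generate_dataset(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[SiteTable, OccurrenceMatrix, SynthTruth]:
    """Landscape + occurrence in one call (shared seed, shared ridges)."""
    sites = generate_landscape(cfg, seed)
    occ, truth = generate_occurrence(sites, cfg, seed)
    return sites, occ, truth


def demo_dataset(seed: int | None = 0) -> tuple[SiteTable, OccurrenceMatrix]:
    """The default end-to-end fixture: a 164-site, 191-species survey.

    Sites span 21–35°N x 92–106°E with south–north ridges; per-site
    richness is calibrated into [17, 87]; similarity decays with
    distance. 164 sites give 13,366 site pairs.
    """
    cfg = SynthConfig()
    sites, occ, _ = generate_dataset(cfg, seed)
    return sites, occ


def dispersal_only_config(
    n_sites: int = 45, n_species: int = 120, range_scale_km: float = 250.0
) -> SynthConfig:
    """Mechanism-isolation condition: dispersal limitation only.

    Niche filtering and barriers off; environment spatially unstructured
    so it cannot proxy geography. Turnover responds to geographic
    distance alone; variation partitioning should attribute the signal
    to the pure geographic fraction.
    """
    return SynthConfig(
        n_sites=n_sites,
        n_species=n_species,
        range_scale_km=range_scale_km,
        niche_breadth=None,
        barrier_penalty=0.0,
        barrier_elev_scale=0.0,
        env_spatial_corr=0.0,
        n_env=4,
        target_richness=None,
    )


def niche_only_config(
    n_sites: int = 45, n_species: int = 120, niche_breadth: float = 1.0
) -> SynthConfig:
    """Mechanism-isolation condition: niche filtering only.

    No dispersal limit and a spatially unstructured environment, so
    turnover responds to environmental distance alone; the pure
    environmental fraction should dominate the partition.
    """
    return SynthConfig(
        n_sites=n_sites,
        n_species=n_species,
        range_scale_km=None,
        niche_breadth=niche_breadth,
        barrier_penalty=0.0,
        barrier_elev_scale=0.0,
        env_spatial_corr=0.0,
        n_env=4,
        target_richness=None,
    )


def isolation_gradient_config(
    n_sites: int = 64, n_species: int = 140, range_scale_km: float = 300.0
) -> SynthConfig:
    """Elevation-scaled barrier condition for the isolation gradient.

    Dispersal-limited species on a ridged landscape where the barrier
    cost grows with elevation, so high-elevation assemblages are more
    local and their similarity decays faster per km (smaller halving
    distance in higher zones).
    """
    return SynthConfig(
        n_sites=n_sites,
        n_species=n_species,
        range_scale_km=range_scale_km,
        niche_breadth=None,
        barrier_penalty=0.8,
        barrier_elev_scale=4.0,
        env_spatial_corr=0.0,
        n_env=4,
        target_richness=None,
    )
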