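"""End-to-end orchestration of the turnover analysis.

``run_all`` drives the full study workflow from one configuration:
similarity matrix, the four explanatory distance matrices (geographic,
environmental-PCA, mean-elevation difference, elevation-range
difference) plus area difference, whole-region and per-zone decay fits
with halving distances and permutation p-values, simple and partial
Mantel tests, seven-fraction variation partitioning and incremental R²
for the extra matrices. Every stage's output lands in the output
directory as CSV/JSON, together with a manifest (seed, config hash,
package/library versions, output digests) that makes a rerun
reproducible and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import OccurrenceMatrix, SiteTable, read_occurrence, read_sites
from .decay import FORMS, attach_significance, fit_decay
from .mantel import mantel_partial, mantel_simple
from .similarity import similarity_matrix
from .spatial import env_distance_matrix, env_pca, geo_distance_matrix, scalar_diff_matrix
from .varpart import incremental_r2, partition3
from .zones import ZoneSpec, zone_decay_report

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    occurrence_path: str
    sites_path: str
    out_dir: str
    similarity_index: str = "jaccard"
    pca_variance_target: float = 0.95
    pca_n_components: int | None = None
    forms: tuple[str, ...] = FORMS
    zone_specs: list[dict] = field(default_factory=list)
    n_perm: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm > 0 and self.seed is None:
            raise ValueError("seed is mandatory when permutation tests are requested")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage context
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def _fit_row(fit, region: str) -> dict:
    return {
        "region": region,
        "form": fit.form,
        "n_pairs": fit.n_pairs,
        "s0": fit.s0,
        "a": fit.a,
        "b": fit.b,
        "r2": fit.r2,
        "p_perm": fit.p_perm,
        "halving_distance": fit.halving_distance,
    }


def run_all(
    cfg: RunConfig,
    occ: OccurrenceMatrix | None = None,
    sites: SiteTable | None = None,
) -> dict:
    """Run the full pipeline; returns a summary dict (also written to disk).

    ``occ``/``sites`` may be passed directly (e.g. from the synthetic
    generator); otherwise they are read from the configured paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if occ is None:
        occ = _stage("read_occurrence")(read_occurrence)(cfg.occurrence_path)
    if sites is None:
        sites = _stage("read_sites")(read_sites)(cfg.sites_path)
    sites = _stage("align_sites")(sites.align_to)(occ)

    sim = _stage("similarity")(similarity_matrix)(occ, cfg.similarity_index)
    geo = _stage("geo_distance")(geo_distance_matrix)(sites)
    pca = _stage("env_pca")(env_pca)(
        sites, variance_target=cfg.pca_variance_target, n_components=cfg.pca_n_components
    )
    env = _stage("env_distance")(env_distance_matrix)(pca, sites.site_ids)
    elev = _stage("elev_diff")(scalar_diff_matrix)(sites, "mean_elev")
    erange = _stage("range_diff")(scalar_diff_matrix)(sites, "elev_range")
    earea = _stage("area_diff")(scalar_diff_matrix)(sites, "area")

    for name, m in [
        ("similarity", sim), ("geo", geo), ("env", env),
        ("elev_diff", elev), ("range_diff", erange), ("area_diff", earea),
    ]:
        m.to_csv(out / f"matrix_{name}.csv")

    # whole-region + per-zone decay fits (Table-1-shaped CSV)
    rows = []
    for i, form in enumerate(cfg.forms):
        fit = _stage("decay_fit")(fit_decay)(sim, geo, form)
        if cfg.n_perm > 0:
            fit = _stage("decay_perm")(attach_significance)(
                fit, sim, geo, n_perm=cfg.n_perm, seed=cfg.seed + i
            )
        rows.append(_fit_row(fit, "entire"))
    decay_df = pd.DataFrame(rows)
    zone_frames = []
    for zi, zd in enumerate(cfg.zone_specs):
        spec = ZoneSpec.from_dict(zd)
        rep = _stage(f"zone_decay[{spec.axis}]")(zone_decay_report)(
            occ, sites, spec, forms=cfg.forms, index=cfg.similarity_index,
            n_perm=cfg.n_perm,
            seed=None if cfg.seed is None else cfg.seed + 100 * (zi + 1),
        )
        if len(rep):
            rep = rep.rename(columns={"zone": "region"})
            zone_frames.append(rep)
    if zone_frames:
        decay_df = pd.concat(
            [decay_df, *(f.drop(columns=["axis", "n_sites"]) for f in zone_frames)],
            ignore_index=True,
        )
    decay_df.to_csv(out / "decay_fits.csv", index=False)

    # simple + partial Mantel against the four explanatory matrices (Table-3-shaped)
    explanatory = {"geo": geo, "env": env, "elev_diff": elev, "range_diff": erange}
    mantel_rows = []
    names = list(explanatory)
    for i, name in enumerate(names):
        B = explanatory[name]
        simple = _stage("mantel_simple")(mantel_simple)(
            sim, B, n_perm=cfg.n_perm or 199, seed=(cfg.seed or 0) + 1000 + i
        )
        controls = [explanatory[o] for o in names if o != name]
        partial = _stage("mantel_partial")(mantel_partial)(
            sim, B, controls, n_perm=cfg.n_perm or 199, seed=(cfg.seed or 0) + 2000 + i
        )
        mantel_rows.append(
            {
                "factor": name,
                "r_simple": simple.r,
                "p_simple": simple.p_perm,
                "r_partial": partial.r,
                "p_partial": partial.p_perm,
                "controlled": "+".join(o for o in names if o != name),
            }
        )
    mantel_df = pd.DataFrame(mantel_rows)
    mantel_df.to_csv(out / "mantel_tests.csv", index=False)

    vp = _stage("varpart")(partition3)(sim, geo, env, elev)
    extras = {
        "range_diff": _stage("incremental_r2")(incremental_r2)(sim, [geo, env, elev], erange),
        "area_diff": _stage("incremental_r2")(incremental_r2)(sim, [geo, env, elev], earea),
    }
    vp_payload = {
        "fractions": vp.fractions(),
        "residual": vp.residual,
        "total_explained": vp.total_explained,
        "subset_r2": vp.subset_r2,
        "incremental_r2": extras,
    }
    (out / "varpart.json").write_text(json.dumps(vp_payload, indent=2))

    pca_payload = {
        "explained_fraction": pca.explained_fraction.tolist(),
        "n_retained": pca.n_retained,
        "cumulative_explained": pca.cumulative_explained,
        "variables": pca.variables,
    }
    (out / "pca_summary.json").write_text(json.dumps(pca_payload, indent=2))

    digests = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "config_digest": cfg.digest(),
        "outputs": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "decay": decay_df,
        "mantel": mantel_df,
        "varpart": vp_payload,
        "pca": pca_payload,
        "manifest": manifest,
    }
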