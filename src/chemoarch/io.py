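"""File readers/writers, configuration and the end-to-end pipeline driver.

Everything is plain delimited text: TSV tables with headers for regional
data, dense whitespace-delimited matrices for connectomes and similarity
matrices, JSON for ground truth and pipeline reports. Numeric output is
written with 12 significant digits so a write-then-read round trip
reproduces values to 1e-12.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ParcelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_matrix",
    "save_matrix",
    "save_table",
    "load_geometry",
    "save_geometry",
    "run_pipeline",
]

REPORT_SCHEMA_VERSION = "1.0"
_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end pipeline run."""

    geometry: str
    atlas: str
    out_dir: str
    sc: str | None = None
    fc: str | None = None
    targets: str | None = None
    terms: str | None = None
    labels: str | None = None
    n_perm: int = 1000
    n_nulls: int = 100
    seed: int = 0
    train_frac: float = 0.75
    fdr_q: float = 0.05
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        return cls(**known, extra=raw) if raw else cls(**known)

    def validate(self) -> None:
        for name in ("geometry", "atlas", "sc", "fc", "targets", "terms", "labels"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config path '{name}' does not exist: {path}")
        if self.n_perm < 100:
            logger.warning(
                "n_perm=%d is below 100; significance estimates will be coarse",
                self.n_perm,
            )


def save_matrix(path: str | Path, matrix: np.ndarray) -> None:
    """Write a dense matrix as whitespace-delimited text (12 sig. digits)."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt=_FMT)


def load_matrix(
    path: str | Path, expected: str = "square_symmetric"
) -> tuple[np.ndarray, list[str] | None]:
    """Load a dense matrix or a regions x features table.

    ``expected`` is ``"square_symmetric"`` (whitespace-delimited dense
    matrix, symmetry checked at 1e-8) or ``"regions_by_features"`` (TSV
    with a header row and a leading region-id column). Returns the array
    and the feature labels (None for dense matrices).
    """
    path = Path(path)
    if expected == "square_symmetric":
        try:
            mat = np.loadtxt(path)
        except ValueError as err:
            raise ValueError(f"ragged or non-numeric rows in {path}: {err}") from err
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: expected square matrix, got {mat.shape}")
        if np.any(~np.isfinite(mat)):
            i, j = np.argwhere(~np.isfinite(mat))[0]
            raise ValueError(f"{path}: non-finite value at row {i}, column {j}")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError(f"{path}: matrix asymmetric beyond 1e-8")
        logger.info("loaded %s: square symmetric %s", path.name, mat.shape)
        return mat, None
    if expected == "regions_by_features":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=float)
        if np.any(~np.isfinite(mat)):
            i, j = np.argwhere(~np.isfinite(mat))[0]
            raise ValueError(
                f"{path}: missing/non-finite value at region '{df.index[i]}', "
                f"column '{df.columns[j]}'"
            )
        logger.info("loaded %s: table %s", path.name, mat.shape)
        return mat, list(df.columns)
    raise ValueError(f"unknown expectation '{expected}'")


def save_table(
    path: str | Path,
    values: np.ndarray,
    columns: list[str],
    index: list[str],
    index_name: str = "region_id",
) -> None:
    """Write a labelled regions x features TSV (12 significant digits)."""
    df = pd.DataFrame(np.asarray(values), index=index, columns=columns)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=_FMT)


def save_geometry(path: str | Path, geometry: ParcelGeometry) -> None:
    """Write geometry as TSV: region_id, hemisphere, x, y, z, sx, sy, sz."""
    df = pd.DataFrame(
        {
            "region_id": geometry.region_ids,
            "hemisphere": geometry.hemisphere,
            "x": geometry.centroids[:, 0],
            "y": geometry.centroids[:, 1],
            "z": geometry.centroids[:, 2],
            "sx": geometry.sphere_coords[:, 0],
            "sy": geometry.sphere_coords[:, 1],
            "sz": geometry.sphere_coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def load_geometry(path: str | Path) -> ParcelGeometry:
    """Read geometry written by :func:`save_geometry`."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "hemisphere", "x", "y", "z", "sx", "sy", "sz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"geometry file missing columns: {sorted(missing)}")
    sphere = df[["sx", "sy", "sz"]].to_numpy(float)
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)  # normalize text rounding
    return ParcelGeometry(
        region_ids=[str(r) for r in df["region_id"]],
        centroids=df[["x", "y", "z"]].to_numpy(float),
        sphere_coords=sphere,
        hemisphere=df["hemisphere"].to_numpy(object),
    )


def _save_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis chain on the configured inputs.

    Stages: atlas descriptives (similarity, distance decay, principal
    gradient) -> spin ensemble -> connectome contrasts and
    structure-function coupling (skipped without sc/fc) -> multilinear
    models with dominance and distance CV per target map (skipped without
    targets) -> PLS (skipped without terms). Writes per-stage TSVs and a
    single versioned JSON report; identical config and seed reproduce the
    report byte-identically.
    """
    from . import atlas as atlas_mod
    from . import nulls as nulls_mod
    from . import structfunc as sfc_mod
    from . import multilinear as mlr_mod
    from . import pls as pls_mod

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: start (seed=%d)", name, config.seed)
        return t0

    try:
        t0 = stage("atlas")
        geometry = load_geometry(config.geometry)
        dens, names = load_matrix(config.atlas, "regions_by_features")
        atlas = atlas_mod.assemble_atlas(
            pd.DataFrame(dens, index=geometry.region_ids, columns=names)
        )
        sim = atlas_mod.receptor_similarity(atlas)
        decay = atlas_mod.fit_distance_decay(sim, geometry)
        gradient, varexp = atlas_mod.principal_gradient(atlas)
        save_matrix(out / "receptor_similarity.txt", sim)
        save_table(
            out / "principal_gradient.tsv",
            gradient[:, None],
            ["pc1_score"],
            atlas.region_ids,
        )
        report["stages"]["atlas"] = {
            "n_regions": atlas.n_regions,
            "n_receptors": atlas.n_receptors,
            "decay": {
                "amplitude": decay.amplitude,
                "rate_per_mm": decay.rate,
                "offset": decay.offset,
                "rss": decay.rss,
            },
            "pc1_variance_explained": float(varexp[0]),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }

        t0 = stage("nulls")
        spins = nulls_mod.build_spin_ensemble(geometry, config.n_perm, config.seed)
        report["stages"]["nulls"] = {
            "n_perm": spins.n_perm,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }

        if config.sc is not None:
            t0 = stage("connectome_contrast")
            sc, _ = load_matrix(config.sc, "square_symmetric")
            ensemble = nulls_mod.rewire_preserving_length(
                sc, geometry, n_nulls=config.n_nulls, seed=config.seed
            )
            diff, p_conn = nulls_mod.connected_contrast_test(sim, sc, ensemble)
            block = {"connected_contrast": diff, "p": p_conn}
            if config.labels is not None:
                labels = pd.read_csv(config.labels, sep="\t")["label"].to_numpy()
                ldiff, lp = nulls_mod.label_contrast_test(sim, labels, spins)
                block["label_contrast"] = ldiff
                block["label_p"] = lp
            block["elapsed_s"] = round(time.perf_counter() - t0, 3)
            report["stages"]["connectome_contrast"] = block
        else:
            logger.info("no structural connectome: contrast stage skipped")

        if config.sc is not None and config.fc is not None:
            t0 = stage("structfunc")
            fc, _ = load_matrix(config.fc, "square_symmetric")
            comm = sfc_mod.communicability(sc)
            coupling = sfc_mod.augmented_coupling(comm, fc, sim, spins, q=config.fdr_q)
            save_table(
                out / "coupling.tsv",
                np.column_stack(
                    [
                        coupling.r2_base,
                        coupling.r2_augmented,
                        coupling.delta,
                        coupling.p_spin,
                        coupling.significant.astype(int),
                    ]
                ),
                ["r2_base", "r2_augmented", "delta", "p_spin", "significant"],
                geometry.region_ids,
            )
            report["stages"]["structfunc"] = {
                "mean_r2_base": float(np.nanmean(coupling.r2_base)),
                "mean_delta": float(np.nanmean(coupling.delta)),
                "n_significant": int(coupling.significant.sum()),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
        else:
            logger.info("missing sc/fc: structure-function stage skipped")

        if config.targets is not None:
            t0 = stage("multilinear")
            targets, target_names = load_matrix(config.targets, "regions_by_features")
            ps, sig, p_fdr = mlr_mod.spin_significance_batch(
                atlas.densities, targets, spins, q=config.fdr_q
            )
            per_map = {}
            dom_rows = []
            for j, tname in enumerate(target_names):
                fit = mlr_mod.fit_multilinear(atlas.densities, targets[:, j])
                dom = mlr_mod.dominance(atlas.densities, targets[:, j])
                cv = mlr_mod.distance_cv(
                    atlas.densities, targets[:, j], geometry,
                    train_frac=config.train_frac,
                )
                per_map[tname] = {
                    "r2": fit.r2,
                    "r2_adj": fit.r2_adj,
                    "p_spin": float(ps[j]),
                    "significant": bool(sig[j]),
                    "p_fdr": float(p_fdr[j]),
                    "mean_test_r": cv.mean_test_r,
                }
                dom_rows.append(dom.percent)
            save_table(
                out / "dominance_percent.tsv",
                np.asarray(dom_rows).T,
                list(target_names),
                atlas.receptor_names,
                index_name="receptor",
            )
            report["stages"]["multilinear"] = {
                "models": per_map,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
        else:
            logger.info("no target maps: multilinear stage skipped")

        if config.terms is not None:
            t0 = stage("pls")
            terms, term_names = load_matrix(config.terms, "regions_by_features")
            res = pls_mod.pls_decompose(atlas.densities, terms)
            p_lv = pls_mod.pls_significance(atlas.densities, terms, spins)
            cv = pls_mod.pls_distance_cv(
                atlas.densities, terms, geometry, train_frac=config.train_frac
            )
            save_table(
                out / "pls_scores.tsv",
                np.column_stack([res.x_scores[:, 0], res.y_scores[:, 0]]),
                ["receptor_score_lv1", "term_score_lv1"],
                geometry.region_ids,
            )
            report["stages"]["pls"] = {
                "cov_explained_lv1": float(res.cov_explained[0]),
                "p_spin_lv1": float(p_lv[0]),
                "mean_train_r": float(cv.train_r.mean()),
                "mean_test_r": cv.mean_test_r,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
        else:
            logger.info("no term matrix: PLS stage skipped")
    except Exception as err:
        _save_json(out / "report_partial.json", report)
        raise RuntimeError(
            f"pipeline aborted during a stage: {err}; partial outputs in {out}"
        ) from err

    # timing varies between identical runs; strip it from the persisted report
    persisted = json.loads(json.dumps(report))
    for block in persisted["stages"].values():
        block.pop("elapsed_s", None)
    _save_json(out / "report.json", persisted)
    return report
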