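"""End-to-end workflow: outlines in, phenogram and warp scores out.

Stages, in order: read or simulate specimen outlines; resample each outline
into k arc-length-equidistant semilandmarks; generalized Procrustes
superimposition of all specimens; tangent-space diagnostic; per-genus
consensus shapes; superimposition of the genus means; relative warps and
principal-coordinates ordination of the means; partial Procrustes distance
matrix among the means; UPGMA phenogram with cophenetic correlation.  All
tabular results are written as CSV, the phenogram as Newick, and a JSON
report ties them together with the fully resolved configuration for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from importlib import metadata as _im
from pathlib import Path
from typing import Any

import numpy as np

from . import phenetics, procrustes, semilandmarks, simulate, tps_io, warps

__all__ = ["PipelineReport", "run_full", "DEFAULT_CONFIG"]

log = logging.getLogger("gryllomorph")

#: defaults for every tunable stage parameter; echoed into the report
DEFAULT_CONFIG: dict[str, Any] = {
    "input_tps": None,       # path to a TPS file, or None to simulate
    "labels_csv": None,      # optional labels table for input_tps
    "simulate": None,        # True / dict of StudyDesign overrides
    "seed": 0,
    "k_semilandmarks": 50,
    "closed_outlines": True,
    "y_flip": False,
    "cyclic_align": "off",   # "off" | "ref" (align each to the first specimen)
    "allow_reflection": False,
    "gpa_tol": 1e-10,
    "gpa_max_iter": 100,
    "alpha": 0.0,
    "pcoa_axes": 3,
    "outdir": "gryllomorph_out",
}


@dataclasses.dataclass
class PipelineReport:
    """Machine-readable summary of one full pipeline run."""

    n_specimens: int
    n_genera: int
    n_extant: int
    k_semilandmarks: int
    tangent_test: procrustes.TangentTestResult
    rw_percent_variance: list[float]
    genus_scores: dict[str, list[float]]
    quadrant_by_genus: dict[str, str]
    pcoa_eigenvalues: list[float]
    cophenetic_correlation: float
    distance_matrix_path: str
    newick_path: str
    scores_path: str
    report_path: str
    config_echo: dict[str, Any]
    software_versions: dict[str, str]
    seed: int
    tree: phenetics.UltrametricTree
    distance_matrix: phenetics.DistanceMatrix

    def to_json_dict(self) -> dict[str, Any]:
        tt = self.tangent_test
        return {
            "n_specimens": self.n_specimens,
            "n_genera": self.n_genera,
            "n_extant": self.n_extant,
            "k_semilandmarks": self.k_semilandmarks,
            "tangent_test": {
                "uncentred_correlation": tt.uncentred_correlation,
                "slope_through_origin": tt.slope_through_origin,
                "ols_slope": tt.ols_slope,
                "ols_intercept": tt.ols_intercept,
            },
            "rw_percent_variance": self.rw_percent_variance,
            "genus_scores": self.genus_scores,
            "quadrant_by_genus": self.quadrant_by_genus,
            "pcoa_eigenvalues": self.pcoa_eigenvalues,
            "cophenetic_correlation": self.cophenetic_correlation,
            "distance_matrix_path": self.distance_matrix_path,
            "newick_path": self.newick_path,
            "scores_path": self.scores_path,
            "config_echo": self.config_echo,
            "software_versions": self.software_versions,
            "seed": self.seed,
        }


def _versions() -> dict[str, str]:
    out = {}
    for pkg in ("gryllomorph", "numpy", "scipy", "pandas", "scikit-bio"):
        try:
            out[pkg] = _im.version(pkg)
        except _im.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out


class _Stage:
    """Context manager logging a stage name and wall time to the module logger."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            log.error("stage %s: failed after %.2fs", self.name, dt)
        else:
            log.info("stage %s: done in %.2fs", self.name, dt)
        return False


def _load_records(cfg: dict[str, Any]) -> list[tps_io.SpecimenRecord]:
    if cfg["input_tps"]:
        records = tps_io.read_tps(cfg["input_tps"])
        if cfg["labels_csv"]:
            tps_io.attach_labels(records, tps_io.read_labels_csv(cfg["labels_csv"]))
        return records
    sim = cfg.get("simulate")
    overrides = dict(sim) if isinstance(sim, dict) else {}
    design = simulate.table2_design(seed=int(cfg["seed"]), **overrides)
    return simulate.generate_study(design)


def _resample(records, cfg) -> list[tps_io.Configuration]:
    k = int(cfg["k_semilandmarks"])
    configs = []
    for rec in records:
        if not rec.curves:
            raise ValueError(f"specimen {rec.specimen_id!r} has no outline curve")
        poly = rec.curves[0]
        if cfg["y_flip"]:
            poly = tps_io.Polyline(poly.vertices * np.array([1.0, -1.0]), poly.closed)
        if cfg["closed_outlines"]:
            if not poly.closed:
                poly = tps_io.Polyline(poly.vertices, closed=True)
            poly = semilandmarks.normalize_traversal(poly)
        conf = semilandmarks.resample_equidistant(poly, k)
        conf.specimen_id = rec.specimen_id
        configs.append(conf)
    if cfg["cyclic_align"] == "ref":
        ref = configs[0]
        configs = [configs[0]] + [
            procrustes.cyclic_align(c, ref, cfg["allow_reflection"])[0]
            for c in configs[1:]
        ]
    return configs


def run_full(config: dict[str, Any] | None = None, **kwargs) -> PipelineReport:
    """Execute the complete workflow and write all outputs under ``outdir``."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    cfg.update(kwargs)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage("load"):
        records = _load_records(cfg)
        for rec in records:
            if not rec.genus:
                raise ValueError(f"specimen {rec.specimen_id!r} lacks a genus label")

    with _Stage("resample"):
        configs = _resample(records, cfg)
        tps_io.write_tps(
            [
                tps_io.SpecimenRecord(
                    specimen_id=c.specimen_id,
                    genus=r.genus,
                    species=r.species,
                    status=r.status,
                    landmarks=c,
                )
                for c, r in zip(configs, records)
            ],
            outdir / "resampled.tps",
        )

    with _Stage("gpa"):
        aligned_all = procrustes.gpa(
            configs,
            tol=float(cfg["gpa_tol"]),
            max_iter=int(cfg["gpa_max_iter"]),
            allow_reflection=bool(cfg["allow_reflection"]),
        )

    with _Stage("tangent-test"):
        tt = procrustes.tangent_space_test(aligned_all)

    with _Stage("consensus"):
        groups: dict[str, list[tps_io.Configuration]] = {}
        for rec, conf in zip(records, aligned_all.aligned):
            groups.setdefault(rec.genus, []).append(conf)
        consensuses = warps.genus_consensus(groups)
        genus_aligned = procrustes.gpa(
            list(consensuses.values()),
            tol=float(cfg["gpa_tol"]),
            max_iter=int(cfg["gpa_max_iter"]),
            allow_reflection=bool(cfg["allow_reflection"]),
        )

    with _Stage("relative-warps"):
        rw = warps.relative_warps(genus_aligned, alpha=float(cfg["alpha"]))
        scores_path = outdir / "relative_warp_scores.csv"
        tps_io.write_scores_csv(rw.labels, rw.scores, scores_path)
        quadrants = {
            lab: warps.quadrant_of((row[0], row[1] if len(row) > 1 else 0.0))
            for lab, row in zip(rw.labels, rw.scores)
        }

    with _Stage("distances"):
        dm = phenetics.distance_matrix(
            consensuses, allow_reflection=bool(cfg["allow_reflection"])
        )
        dm_path = outdir / "procrustes_distances.csv"
        tps_io.write_distance_csv(dm, dm_path)

    with _Stage("pcoa"):
        n_axes = min(int(cfg["pcoa_axes"]), len(dm) - 1)
        ord_res = warps.pcoa(dm, n_axes=n_axes)
        tps_io.write_scores_csv(
            ord_res.labels, ord_res.axis_scores, outdir / "pcoa_scores.csv", prefix="Axis"
        )

    with _Stage("upgma"):
        tree = phenetics.upgma(dm)
        nwk_path = outdir / "phenogram.nwk"
        tps_io.write_newick(tree, nwk_path)
        coph = phenetics.cophenetic_correlation(tree, dm)

    report_path = outdir / "report.json"
    report = PipelineReport(
        n_specimens=len(records),
        n_genera=len(consensuses),
        n_extant=sum(1 for r in records if r.status == "extant"),
        k_semilandmarks=int(cfg["k_semilandmarks"]),
        tangent_test=tt,
        rw_percent_variance=[float(p) for p in rw.percent_variance],
        genus_scores={lab: [float(s) for s in row] for lab, row in zip(rw.labels, rw.scores)},
        quadrant_by_genus=quadrants,
        pcoa_eigenvalues=[float(e) for e in ord_res.eigenvalues],
        cophenetic_correlation=coph,
        distance_matrix_path=str(dm_path),
        newick_path=str(nwk_path),
        scores_path=str(scores_path),
        report_path=str(report_path),
        config_echo=cfg,
        software_versions=_versions(),
        seed=int(cfg["seed"]),
        tree=tree,
        distance_matrix=dm,
    )
    report_path.write_text(json.dumps(report.to_json_dict(), indent=2, default=str) + "\n")
    return report
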