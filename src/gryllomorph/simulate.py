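"""Synthetic pronotum-like outline datasets with known genus structure.

Real study material — pronotum outlines digitized from published figures —
is emulated by a parametric family: closed outlines sampled from a truncated
Fourier perturbation of a circle,

    r(theta) = r0 * (1 + sum_{h=1..H} a_h cos(h theta) + b_h sin(h theta)),

with H = 4 harmonics.  Low even harmonics give the rounded-quadrate,
transversely oval silhouettes typical of grylloblattodean pronota; odd and
sine terms introduce the asymmetries of fossil compressions.  Each genus has
a mean coefficient vector; species within a genus add Gaussian coefficient
noise; optional per-vertex jitter emulates digitizing error; and an optional
random similarity transform (rotation, log-uniform scale, translation) adds
the nuisance variation that Procrustes superimposition must remove.

One integer seed drives the whole design; each specimen draws from its own
counter-indexed substream, so records are independent of generation order.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .tps_io import Polyline, SpecimenRecord

__all__ = [
    "GenusSpec",
    "StudyDesign",
    "base_outline",
    "generate_study",
    "table2_design",
    "load_design",
]

N_HARMONICS = 4


@dataclasses.dataclass
class GenusSpec:
    name: str
    status: str  # "extant" | "fossil"
    n_species: int
    mean_coeffs: np.ndarray  # length 2*N_HARMONICS: [a1, b1, ..., a4, b4]

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.status not in ("extant", "fossil"):
            raise ValueError(f"unknown status {self.status!r}")
        c = np.asarray(self.mean_coeffs, dtype=float)
        if c.shape != (2 * N_HARMONICS,):
            raise ValueError(f"mean_coeffs must have length {2 * N_HARMONICS}")
        self.mean_coeffs = c


@dataclasses.dataclass
class StudyDesign:
    """Full specification of a synthetic outline study."""

    genera: list[GenusSpec]
    within_genus_sd: float = 0.005
    landmark_jitter_sd: float = 0.002
    nuisance: bool = True
    k_semilandmarks: int = 50
    n_vertices: int = 400
    r0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_genus_sd < 0 or self.landmark_jitter_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n_vertices < 16:
            raise ValueError("n_vertices must be >= 16")

    @property
    def n_specimens(self) -> int:
        return sum(g.n_species for g in self.genera)


def base_outline(
    coeffs: Sequence[float] | np.ndarray, n_vertices: int, r0: float = 1.0
) -> Polyline:
    """Closed outline sampled at equal angles from the Fourier radius model.

    All-zero coefficients give a circle of radius r0.  Coefficients driving
    the radius nonpositive anywhere on the sampled circle are rejected.
    """
    if n_vertices < 16:
        raise ValueError("n_vertices must be >= 16")
    c = np.asarray(coeffs, dtype=float)
    if c.size % 2 != 0:
        raise ValueError("coefficient vector must hold (a_h, b_h) pairs")
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    r = np.ones(n_vertices)
    for h in range(1, c.size // 2 + 1):
        r += c[2 * h - 2] * np.cos(h * theta) + c[2 * h - 1] * np.sin(h * theta)
    if np.any(r <= 0.0):
        raise ValueError("coefficients drive the radius nonpositive")
    r *= r0
    return Polyline(np.column_stack([r * np.cos(theta), r * np.sin(theta)]), closed=True)


def _substream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_study(design: StudyDesign) -> list[SpecimenRecord]:
    """Draw one synthetic study: one outline record per species.

    Per record: coefficients = genus mean + N(0, within_genus_sd) per
    coefficient; the outline is built by :func:`base_outline`, optionally
    vertex-jittered (N(0, landmark_jitter_sd)) and similarity-transformed
    (rotation U(0, 2pi), scale logU(0.5, 2), translation U(-10, 10)^2) when
    ``nuisance`` is on.  Fully reproducible from ``design.seed``.
    """
    records: list[SpecimenRecord] = []
    counter = 0
    for genus in design.genera:
        for sp in range(genus.n_species):
            rng = _substream(design.seed, counter)
            counter += 1
            coeffs = genus.mean_coeffs + rng.normal(
                0.0, design.within_genus_sd, size=genus.mean_coeffs.shape
            )
            poly = base_outline(coeffs, design.n_vertices, design.r0)
            verts = poly.vertices
            if design.landmark_jitter_sd > 0:
                verts = verts + rng.normal(
                    0.0, design.landmark_jitter_sd, size=verts.shape
                )
            if design.nuisance:
                angle = rng.uniform(0.0, 2.0 * np.pi)
                scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                shift = rng.uniform(-10.0, 10.0, size=2)
                rot = np.array(
                    [[np.cos(angle), np.sin(angle)], [-np.sin(angle), np.cos(angle)]]
                )
                verts = scale * (verts @ rot) + shift
            species = f"sp{sp + 1:02d}"
            records.append(
                SpecimenRecord(
                    specimen_id=f"{genus.name}_{species}",
                    genus=genus.name,
                    species=species,
                    status=genus.status,
                    curves=[Polyline(verts, closed=True)],
                )
            )
    return records


def load_design(source: str | dict, seed: int = 0, **overrides) -> StudyDesign:
    """Build a StudyDesign from a YAML path or an already-parsed mapping."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    genera = [
        GenusSpec(
            name=g["name"],
            status=g["status"],
            n_species=int(g["n_species"]),
            mean_coeffs=np.asarray(g["mean_coeffs"], dtype=float),
        )
        for g in raw.pop("genera")
    ]
    raw.update(overrides)
    return StudyDesign(genera=genera, seed=seed, **raw)


def table2_design(seed: int = 0, **overrides) -> StudyDesign:
    """The default 28-specimen / 13-genus study design shipped with the package."""
    text = resources.files("gryllomorph.data").joinpath("table2.yaml").read_text()
    return load_design(yaml.safe_load(text), seed=seed, **overrides)
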