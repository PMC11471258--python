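"""Seeded generator of paired single-cell / spatial tables with ground truth.

The generator emulates exactly the statistical structure the analysis
assumes and nothing more:

* cluster-conditional marker detection — each cluster *k* has a true
  positivity probability ``p_k``; a positive cell's raw count is
  ``1 + Poisson(detection_lambda)`` (any positive-support law would do,
  since the analysis thresholds counts; the +1 keeps thresholds > 1
  meaningful), a negative cell's count is 0;
* structure-conditional cluster composition — each structure *s* draws
  its ``n_cells`` cell cluster labels i.i.d. from mixing weights
  ``theta[s, .]``;
* section assignment — each spatial cell draws a section id from the
  configured section weights, independently of everything else.

Two independent RNG substreams (single-cell, spatial) are spawned from
the one seed, so resizing one table never perturbs the other. The
closed-form ground truth ``E_true[s] = sum_k n_cells_s * theta[s,k] * p_k``
supports recovery tests without any sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas_model import NT_CLASSES, ValidationError

_THETA_TOL = 1e-9


@dataclass(frozen=True)
class ClusterSpec:
    cluster_id: str
    nt_class: str
    p: float  # true marker-positive probability
    n_sc: int  # single-cell cells simulated for this cluster


@dataclass(frozen=True)
class StructureSpec:
    acronym: str
    n_cells: int
    theta: dict[str, float]  # cluster_id -> mixing weight, sums to 1


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic paired atlas."""

    clusters: tuple[ClusterSpec, ...]
    structures: tuple[StructureSpec, ...]
    sections: tuple[tuple[str, float], ...] = (("1", 1.0),)
    detection_lambda: float = 1.0
    region: str = "OLF"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        object.__setattr__(self, "structures", tuple(self.structures))
        object.__setattr__(
            self, "sections", tuple((str(s), float(w)) for s, w in self.sections)
        )
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("SimSpec.seed is mandatory")
        if self.detection_lambda < 0:
            raise ValidationError("detection_lambda must be >= 0")
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate cluster ids in SimSpec")
        for c in self.clusters:
            if not 0.0 <= c.p <= 1.0:
                raise ValidationError(f"p for {c.cluster_id} outside [0,1]: {c.p}")
            if c.n_sc < 0:
                raise ValidationError(f"n_sc for {c.cluster_id} negative")
            if c.nt_class not in NT_CLASSES:
                raise ValidationError(
                    f"nt_class {c.nt_class!r} for {c.cluster_id} not one of {NT_CLASSES}"
                )
        id_set = set(ids)
        for s in self.structures:
            if s.n_cells < 0:
                raise ValidationError(f"n_cells for {s.acronym} negative")
            unknown = set(s.theta) - id_set
            if unknown:
                raise ValidationError(
                    f"theta for {s.acronym} references unknown cluster(s) {sorted(unknown)}"
                )
            total = sum(s.theta.values())
            if s.theta and abs(total - 1.0) > _THETA_TOL:
                raise ValidationError(
                    f"theta for {s.acronym} sums to {total}, not 1"
                )
            if any(w < 0 for w in s.theta.values()):
                raise ValidationError(f"negative theta weight in {s.acronym}")
        if self.sections:
            wsum = sum(w for _, w in self.sections)
            if wsum <= 0:
                raise ValidationError("section weights must sum to a positive value")

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "clusters": [
                {"cluster_id": c.cluster_id, "nt_class": c.nt_class, "p": c.p, "n_sc": c.n_sc}
                for c in self.clusters
            ],
            "structures": [
                {"acronym": s.acronym, "n_cells": s.n_cells, "theta": dict(s.theta)}
                for s in self.structures
            ],
            "sections": [{"section_id": s, "weight": w} for s, w in self.sections],
            "detection_lambda": self.detection_lambda,
            "region": self.region,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            clusters=tuple(
                ClusterSpec(d["cluster_id"], d["nt_class"], float(d["p"]), int(d["n_sc"]))
                for d in data["clusters"]
            ),
            structures=tuple(
                StructureSpec(d["acronym"], int(d["n_cells"]), dict(d["theta"]))
                for d in data["structures"]
            ),
            sections=tuple(
                (str(d["section_id"]), float(d["weight"])) for d in data["sections"]
            ),
            detection_lambda=float(data.get("detection_lambda", 1.0)),
            region=str(data.get("region", "OLF")),
            seed=int(data["seed"]),
        )


@dataclass
class GroundTruth:
    """Closed-form truth plus realised assignments for oracle checks."""

    p: dict[str, float] = field(default_factory=dict)
    true_expected_pos: dict[str, float] = field(default_factory=dict)
    true_expected_pos_by_class: dict[str, dict[str, float]] = field(default_factory=dict)
    sc_assignments: pd.DataFrame | None = None
    spatial_assignments: pd.DataFrame | None = None


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    sc_ss, sp_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(sc_ss), np.random.default_rng(sp_ss)


def taxonomy_table(spec: SimSpec) -> pd.DataFrame:
    """Taxonomy table for the simulated clusters."""
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in spec.clusters],
            "cluster_label": [f"{c.cluster_id} ({c.nt_class})" for c in spec.clusters],
            "nt_class": [c.nt_class for c in spec.clusters],
        }
    )


def generate_sc(spec: SimSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the single-cell table; reproducible given ``spec.seed``."""
    rng, _ = _streams(spec.seed)
    rows = []
    for c in spec.clusters:
        positive = rng.random(c.n_sc) < c.p
        extra = rng.poisson(spec.detection_lambda, size=c.n_sc)
        counts = np.where(positive, 1 + extra, 0)
        for i in range(c.n_sc):
            rows.append((f"sc_{c.cluster_id}_{i:05d}", spec.region, c.cluster_id, counts[i]))
    sc = pd.DataFrame(rows, columns=["cell_id", "region", "cluster_id", "marker_count"])
    truth = GroundTruth(p={c.cluster_id: c.p for c in spec.clusters})
    truth.sc_assignments = sc[["cell_id", "cluster_id"]].copy()
    return sc, truth


def generate_spatial(spec: SimSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the spatial table (independent substream from the sc one)."""
    _, rng = _streams(spec.seed)
    section_ids = [s for s, _ in spec.sections]
    weights = np.array([w for _, w in spec.sections], dtype=float)
    weights = weights / weights.sum()
    rows = []
    for s in spec.structures:
        if s.n_cells == 0 or not s.theta:
            continue
        cids = list(s.theta.keys())
        theta = np.array([s.theta[k] for k in cids], dtype=float)
        theta = theta / theta.sum()
        draws = rng.choice(len(cids), size=s.n_cells, p=theta)
        sects = rng.choice(len(section_ids), size=s.n_cells, p=weights)
        for i in range(s.n_cells):
            rows.append(
                (f"st_{s.acronym}_{i:05d}", section_ids[sects[i]], cids[draws[i]], s.acronym)
            )
    st = pd.DataFrame(rows, columns=["cell_id", "section_id", "cluster_id", "structure"])
    truth = GroundTruth(p={c.cluster_id: c.p for c in spec.clusters})
    truth.spatial_assignments = st[["cell_id", "cluster_id", "structure"]].copy()
    return st, truth


def ground_truth(spec: SimSpec) -> GroundTruth:
    """Closed-form expected positive counts; no sampling involved."""
    p = {c.cluster_id: c.p for c in spec.clusters}
    nt = {c.cluster_id: c.nt_class for c in spec.clusters}
    truth = GroundTruth(p=p)
    for s in spec.structures:
        total = sum(s.n_cells * w * p[k] for k, w in s.theta.items())
        by_class = {c: 0.0 for c in NT_CLASSES}
        for k, w in s.theta.items():
            by_class[nt[k]] += s.n_cells * w * p[k]
        truth.true_expected_pos[s.acronym] = total
        truth.true_expected_pos_by_class[s.acronym] = by_class
    return truth


def generate_paired(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience: (sc_cells, spatial_cells, taxonomy, full ground truth)."""
    sc, sc_truth = generate_sc(spec)
    st, st_truth = generate_spatial(spec)
    truth = ground_truth(spec)
    truth.sc_assignments = sc_truth.sc_assignments
    truth.spatial_assignments = st_truth.spatial_assignments
    return sc, st, taxonomy_table(spec), truth


# ---------------------------------------------------------------------------
# Reference specs and the deterministic worked example
# ---------------------------------------------------------------------------


def toy_spec(seed: int = 0) -> SimSpec:
    """Small three-cluster / two-structure spec mirroring the worked example.

    The cluster positivity probabilities equal the worked example's
    fractions (0.5, 0.2, 0.0) and the structure mixes match its spatial
    tallies, so the closed-form truth reproduces E[MOB] = 7.0 and
    E[AOB] = 2.0 when the observed fractions equal the true ones.
    """
    return SimSpec(
        clusters=(
            ClusterSpec("K1", "glutamatergic", 0.5, 4),
            ClusterSpec("K2", "GABAergic", 0.2, 5),
            ClusterSpec("K3", "dopaminergic", 0.0, 2),
        ),
        structures=(
            StructureSpec("MOB", 25, {"K1": 0.4, "K2": 0.4, "K3": 0.2}),
            StructureSpec("AOB", 4, {"K1": 1.0}),
        ),
        sections=(("60", 0.5), ("62", 0.5)),
        seed=seed,
    )


def toy_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic hand-checkable fixture: (sc_cells, spatial_cells, taxonomy).

    Single-cell: K1 counts (3,1,0,0), K2 counts (0,0,1,0,0), K3 counts
    (0,0) — so f = (0.5, 0.2, 0.0) at threshold 1. Spatial: MOB holds
    10 K1 + 10 K2 + 5 K3 cells, AOB holds 4 K1 cells — so the imputed
    expectations are E[MOB] = 10*0.5 + 10*0.2 = 7.0 and E[AOB] = 2.0.
    """
    sc_counts = [("K1", c) for c in (3, 1, 0, 0)]
    sc_counts += [("K2", c) for c in (0, 0, 1, 0, 0)]
    sc_counts += [("K3", c) for c in (0, 0)]
    sc = pd.DataFrame(
        {
            "cell_id": [f"c{i:02d}" for i in range(len(sc_counts))],
            "region": "OLF",
            "cluster_id": [k for k, _ in sc_counts],
            "marker_count": [c for _, c in sc_counts],
        }
    )
    spatial_rows = [("MOB", "K1")] * 10 + [("MOB", "K2")] * 10 + [("MOB", "K3")] * 5
    spatial_rows += [("AOB", "K1")] * 4
    st = pd.DataFrame(
        {
            "cell_id": [f"s{i:02d}" for i in range(len(spatial_rows))],
            "section_id": "60",
            "cluster_id": [k for _, k in spatial_rows],
            "structure": [s for s, _ in spatial_rows],
        }
    )
    taxonomy = pd.DataFrame(
        {
            "cluster_id": ["K1", "K2", "K3"],
            "cluster_label": ["K1 glut", "K2 GABA", "K3 dopa"],
            "nt_class": ["glutamatergic", "GABAergic", "dopaminergic"],
        }
    )
    return sc, st, taxonomy


def study_spec(seed: int = 0) -> SimSpec:
    """Study-scale synthetic atlas emulating the olfactory-area analysis.

    Cluster sizes and positivity probabilities are set so the expected
    marker-positive population is 133 cells split 76% glutamatergic /
    20% GABAergic / 2% dopaminergic / 2% unassigned. Structure mixes
    put roughly equal expected glutamatergic and GABAergic positives in
    the MOB (GABAergic granule-type clusters dominate its cell count at
    a tenth of the glutamatergic positivity rate) and make the AOB and
    AON predominantly glutamatergic. Five spatial sections with equal
    assignment weights.
    """
    return SimSpec(
        clusters=(
            # mitral/tufted-like projection neurons: high positivity
            ClusterSpec("GLUT-MT", "glutamatergic", 0.06, 1200),
            # AON-type excitatory neurons
            ClusterSpec("GLUT-AON", "glutamatergic", 0.036, 800),
            # granule-cell interneurons: numerous, low positivity
            ClusterSpec("GABA-GR", "GABAergic", 0.006, 3000),
            # periglomerular interneurons
            ClusterSpec("GABA-PG", "GABAergic", 0.006, 1500),
            # dopaminergic juxtaglomerular cells
            ClusterSpec("DOPA-JG", "dopaminergic", 0.005, 600),
            # low-quality / unresolved cluster
            ClusterSpec("UNK", "unassigned", 0.005, 400),
        ),
        structures=(
            StructureSpec(
                "MOB",
                4000,
                {"GLUT-MT": 0.088, "GABA-GR": 0.60, "GABA-PG": 0.28,
                 "DOPA-JG": 0.028, "UNK": 0.004},
            ),
            StructureSpec(
                "AOB",
                600,
                {"GLUT-MT": 0.55, "GABA-GR": 0.42, "DOPA-JG": 0.02, "UNK": 0.01},
            ),
            StructureSpec(
                "AON",
                1200,
                {"GLUT-AON": 0.70, "GABA-PG": 0.27, "DOPA-JG": 0.02, "UNK": 0.01},
            ),
        ),
        sections=tuple((s, 1.0) for s in ("60", "62", "64", "66", "67")),
        detection_lambda=1.0,
        region="OLF",
        seed=seed,
    )
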