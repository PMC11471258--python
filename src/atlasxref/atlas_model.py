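"""Domain types, table I/O, schema validation and anatomical roll-up.

All tabular data flows through this module as :class:`pandas.DataFrame`
objects with fixed snake_case schemas (see the ``*_COLUMNS`` constants).
Readers validate on the way in; :func:`write_table` guarantees that
string/integer columns round-trip bit-identically through the matching
reader.

Tables
------
taxonomy        cluster_id, cluster_label, nt_class
sc_cells        cell_id, region, cluster_id, marker_count
spatial_cells   cell_id, section_id, cluster_id, structure [, x_um, y_um]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("atlasxref")

#: Recognised neurotransmitter classes; anything else maps to "unassigned".
NT_CLASSES: tuple[str, ...] = (
    "glutamatergic",
    "GABAergic",
    "dopaminergic",
    "unassigned",
)

TAXONOMY_COLUMNS = ("cluster_id", "cluster_label", "nt_class")
SC_COLUMNS = ("cell_id", "region", "cluster_id", "marker_count")
SPATIAL_COLUMNS = ("cell_id", "section_id", "cluster_id", "structure")
SPATIAL_OPTIONAL = ("x_um", "y_um")
PREVALENCE_COLUMNS = (
    "cluster_id",
    "nt_class",
    "n_total",
    "n_pos",
    "fraction",
    "ci_low",
    "ci_high",
)

_STRING_COLUMNS = {
    "cluster_id",
    "cluster_label",
    "nt_class",
    "cell_id",
    "region",
    "section_id",
    "structure",
}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class AtlasXrefError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(AtlasXrefError):
    """A table is missing required columns or has an unparseable column."""


class ValidationError(AtlasXrefError):
    """A table violates an invariant (duplicates, negative counts, ...)."""


class ConsistencyError(ValidationError):
    """Two tables disagree (e.g. a spatial cluster absent from prevalence)."""


class EmptyResultError(AtlasXrefError):
    """A filtering step left no rows, so downstream stages are undefined."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level parameters shared by every pipeline stage.

    Parameters
    ----------
    marker_name
        Gene symbol of the marker being thresholded (e.g. ``"Ghsr"``).
    region
        Dissection-region label the single-cell table is restricted to.
    positivity_threshold
        Minimum raw marker count for a cell to count as positive
        (``tau``); the default 1 realises "non-zero expression".
    sections
        Spatial section ids to retain; empty means all sections.
    structures
        Ordered target anatomical acronyms after roll-up.
    strict
        If True, unknown cluster ids are errors; if False they are
        mapped to the ``unassigned`` class with a logged warning.
    seed
        Seed for simulation only; never used by the analysis stages.
    ci_level
        Two-sided confidence level for the Jeffreys prevalence interval.
    region_restricted_denominator
        If True (default) prevalence denominators count cells within the
        configured region only; if False the whole table is used.
    min_n_pos
        Minimum scRNA-seq positive-cell count for a cluster to be
        carried into the spatial cross-reference.
    """

    marker_name: str = "Ghsr"
    region: str = "OLF"
    positivity_threshold: int = 1
    sections: tuple[str, ...] = ()
    structures: tuple[str, ...] = ("MOB", "AOB", "AON")
    strict: bool = True
    seed: int = 0
    ci_level: float = 0.95
    region_restricted_denominator: bool = True
    min_n_pos: int = 1

    def __post_init__(self) -> None:
        if self.positivity_threshold < 1:
            raise ValidationError(
                f"positivity_threshold must be >= 1, got {self.positivity_threshold}"
            )
        if not self.structures:
            raise ValidationError("structures must be non-empty")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level must be in (0, 1), got {self.ci_level}")
        object.__setattr__(self, "sections", tuple(str(s) for s in self.sections))
        object.__setattr__(self, "structures", tuple(self.structures))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self


# ---------------------------------------------------------------------------
# Structure roll-up
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureMap:
    """Many-to-one map from raw structure acronyms onto target acronyms.

    The atlas annotates cells at layer/substructure resolution (e.g.
    ``MOB-gl``, ``AONd``); analysis happens at the level of a configured
    target set (e.g. MOB, AOB, AON). A raw acronym that resolves to no
    target is excluded. The map is idempotent: every target maps to
    itself.
    """

    targets: tuple[str, ...]
    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        target_set = set(self.targets)
        for raw, tgt in self.mapping.items():
            if tgt not in target_set:
                raise ValidationError(
                    f"StructureMap maps {raw!r} to {tgt!r}, not in target set"
                )

    def apply(self, acronym: str) -> str | None:
        """Roll ``acronym`` up to its target, or None if excluded."""
        if acronym in self.mapping:
            return self.mapping[acronym]
        if acronym in self.targets:
            return acronym
        # prefix rule: longest target that is an ontology-style prefix
        best = None
        for tgt in self.targets:
            if acronym.startswith(tgt) and (best is None or len(tgt) > len(best)):
                best = tgt
        return best

    @classmethod
    def from_prefix(cls, targets: Sequence[str]) -> "StructureMap":
        """Default map using acronym prefixes only (no explicit table)."""
        return cls(targets=tuple(targets))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    dtypes = {c: str for c in required if c in _STRING_COLUMNS}
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes)
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read and validate a cluster taxonomy table.

    Unrecognised neurotransmitter-class labels are mapped to
    ``unassigned`` with a logged warning; duplicate cluster ids are an
    error.
    """
    df = _read_tsv(path, TAXONOMY_COLUMNS)
    dup = df["cluster_id"][df["cluster_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"duplicate cluster_id in taxonomy: {sorted(dup.unique())}"
        )
    unknown = ~df["nt_class"].isin(NT_CLASSES)
    if unknown.any():
        bad = sorted(df.loc[unknown, "nt_class"].unique())
        logger.warning(
            "taxonomy: %d cluster(s) with unrecognised nt_class %s mapped to "
            "'unassigned'",
            int(unknown.sum()),
            bad,
        )
        df = df.copy()
        df.loc[unknown, "nt_class"] = "unassigned"
    return df.loc[:, list(TAXONOMY_COLUMNS)].reset_index(drop=True)


def validate_taxonomy_membership(
    df: pd.DataFrame, taxonomy: pd.DataFrame, strict: bool, what: str
) -> pd.DataFrame:
    """Check every cluster_id in ``df`` against the taxonomy.

    Strict mode raises; lenient mode keeps the rows (their class resolves
    to ``unassigned`` at join time) and logs.
    """
    known = set(taxonomy["cluster_id"])
    mask = ~df["cluster_id"].isin(known)
    if mask.any():
        bad = sorted(df.loc[mask, "cluster_id"].unique())
        if strict:
            raise ValidationError(
                f"{what}: cluster id(s) absent from taxonomy: {bad}"
            )
        logger.warning(
            "%s: %d row(s) with unknown cluster id(s) %s treated as 'unassigned'",
            what,
            int(mask.sum()),
            bad,
        )
    return df


def read_sc_cells(
    path: str | Path, taxonomy: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Read the single-cell table and restrict it to the configured region.

    The returned frame carries the pre-filter row count in
    ``df.attrs["n_input"]`` so conservation can be checked downstream.
    """
    df = _read_tsv(path, SC_COLUMNS)
    counts = pd.to_numeric(df["marker_count"], errors="coerce")
    if counts.isna().any() or (counts != counts.round()).any():
        raise ValidationError(f"{path}: marker_count must be integral")
    if (counts < 0).any():
        raise ValidationError(f"{path}: marker_count must be non-negative")
    df = df.assign(marker_count=counts.astype(int))
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate cell_id {sorted(dup.unique())[:5]}")
    n_input = len(df)
    if config.region_restricted_denominator:
        df = df[df["region"] == config.region]
    if df.empty:
        raise EmptyResultError(f"no cells in region {config.region!r}")
    validate_taxonomy_membership(df, taxonomy, config.strict, "sc_cells")
    logger.info(
        "sc_cells: %d/%d rows retained in region %s", len(df), n_input, config.region
    )
    out = df.loc[:, list(SC_COLUMNS)].reset_index(drop=True)
    out.attrs["n_input"] = n_input
    return out


def read_spatial_cells(
    path: str | Path,
    structure_map: StructureMap,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Read the spatial cell table, roll structures up and filter sections.

    Rows whose rolled-up structure falls outside the target set, or whose
    section is not configured, are excluded; the counts are recorded in
    ``df.attrs`` (``n_input``, ``n_excluded_structure``,
    ``n_excluded_section``) and logged.
    """
    df = _read_tsv(path, SPATIAL_COLUMNS)
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate cell_id {sorted(dup.unique())[:5]}")
    n_input = len(df)

    rolled = df["structure"].map(structure_map.apply)
    keep_structure = rolled.notna() & (rolled != "")
    n_excluded_structure = int((~keep_structure).sum())
    df = df[keep_structure].assign(structure=rolled[keep_structure])

    n_excluded_section = 0
    if config.sections:
        in_section = df["section_id"].isin(config.sections)
        n_excluded_section = int((~in_section).sum())
        df = df[in_section]

    if df.empty:
        raise EmptyResultError("no spatial cells in target structures/sections")

    logger.info(
        "spatial_cells: %d/%d rows retained (%d excluded by structure, %d by section)",
        len(df),
        n_input,
        n_excluded_structure,
        n_excluded_section,
    )
    cols = list(SPATIAL_COLUMNS) + [c for c in SPATIAL_OPTIONAL if c in df.columns]
    out = df.loc[:, cols].reset_index(drop=True)
    out.attrs["n_input"] = n_input
    out.attrs["n_excluded_structure"] = n_excluded_structure
    out.attrs["n_excluded_section"] = n_excluded_section
    return out


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with a stable column order and header.

    Integer and string columns round-trip bit-identically through the
    matching reader; floats are serialised with 12 significant digits.
    """
    path = Path(path)
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    except OSError as exc:
        raise AtlasXrefError(f"cannot write {path}: {exc}") from exc


def read_prevalence(path: str | Path) -> pd.DataFrame:
    """Read a prevalence table previously written by :func:`write_table`."""
    df = _read_tsv(path, PREVALENCE_COLUMNS)
    df = df.astype({"n_total": int, "n_pos": int})
    return df.loc[:, list(PREVALENCE_COLUMNS)]


# ---------------------------------------------------------------------------
# Optional adapter: Allen-style h5ad -> TSV schema
# ---------------------------------------------------------------------------


def sc_cells_from_h5ad(
    h5ad_path: str | Path,
    marker_name: str,
    region_column: str = "region_of_interest_acronym",
    cluster_column: str = "cluster_alias",
) -> pd.DataFrame:
    """Extract the sc_cells schema from an h5ad single-cell container.

    Expects raw counts in ``X`` (or the ``counts`` layer when present),
    gene symbols in ``var_names`` and per-cell region/cluster labels in
    ``obs``. The atlas release to use is whatever file the caller pins;
    no downloading happens here.
    """
    import anndata as ad  # deferred: only the adapter needs it
    import numpy as np

    adata = ad.read_h5ad(h5ad_path)
    if marker_name not in adata.var_names:
        raise SchemaError(f"marker {marker_name!r} not found in {h5ad_path}")
    for col in (region_column, cluster_column):
        if col not in adata.obs.columns:
            raise SchemaError(f"obs column {col!r} not found in {h5ad_path}")
    matrix = adata.layers["counts"] if "counts" in adata.layers else adata.X
    j = adata.var_names.get_loc(marker_name)
    col = matrix[:, j]
    counts = np.asarray(col.todense() if hasattr(col, "todense") else col).ravel()
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValidationError(f"{h5ad_path}: marker counts must be raw non-negative integers")
    return pd.DataFrame(
        {
            "cell_id": adata.obs_names.astype(str),
            "region": adata.obs[region_column].astype(str).to_numpy(),
            "cluster_id": adata.obs[cluster_column].astype(str).to_numpy(),
            "marker_count": counts.astype(int),
        }
    )


def spatial_cells_from_frame(
    df: pd.DataFrame,
    column_map: Mapping[str, str],
) -> pd.DataFrame:
    """Rename an atlas metadata frame onto the spatial_cells schema.

    ``column_map`` maps our schema names to the source frame's columns,
    e.g. ``{"cell_id": "cell_label", "section_id": "brain_section_label",
    "cluster_id": "cluster_alias", "structure": "parcellation_substructure"}``.
    """
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"source frame missing column(s) {missing}")
    out = pd.DataFrame({ours: df[src].astype(str) for ours, src in column_map.items()})
    required = [c for c in SPATIAL_COLUMNS if c not in out.columns]
    if required:
        raise SchemaError(f"column_map must cover {list(SPATIAL_COLUMNS)}; missing {required}")
    return out


def conservation_check(retained: int, excluded: Iterable[int], n_input: int) -> None:
    """Assert retained + excluded == input for a filtering reader."""
    total = retained + sum(excluded)
    if total != n_input:
        raise ConsistencyError(
            f"row conservation violated: {retained} retained + excluded "
            f"{list(excluded)} != {n_input} input rows"
        )
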