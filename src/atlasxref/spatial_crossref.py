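"""Stage 2: spatial cross-reference and expected-count imputation.

The spatial cells carry a cluster label and an anatomical structure but
no marker measurement. Each retained spatial cell of cluster *k* is
assigned its cluster's scRNA-seq positive fraction f_k as the
probability of being marker-positive, so the expected number of
positive cells in structure *s* is

    E[s] = sum_k n[s, k] * f_k

with the per-class split E[s, c] summing f_k over the clusters of class
*c*. Only "relevant" clusters — those with at least ``min_n_pos``
positive cells in the single-cell data — enter the tabulation; spatial
rows of other clusters are counted in provenance, never imputed at f=0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_model import (
    NT_CLASSES,
    ConsistencyError,
    EmptyResultError,
    ValidationError,
    logger,
)

STRUCTURE_REPORT_COLUMNS = ("structure", "n_cells", "expected_positive")
CLASS_REPORT_COLUMNS = ("structure", "nt_class", "expected", "pct")


def select_relevant_clusters(prev: pd.DataFrame, min_n_pos: int = 1) -> set[str]:
    """Clusters carried into the spatial cross-reference.

    Relevance means prior marker detection in the single-cell data:
    ``n_pos >= min_n_pos`` (equivalently ``fraction > 0`` at the
    default).
    """
    if prev.empty:
        raise EmptyResultError("prevalence table is empty")
    if min_n_pos < 1:
        raise ValidationError(f"min_n_pos must be >= 1, got {min_n_pos}")
    relevant = set(prev.loc[prev["n_pos"] >= min_n_pos, "cluster_id"])
    if not relevant:
        raise EmptyResultError("no relevant clusters (no cluster has n_pos >= 1)")
    return relevant


def check_spatial_clusters(st: pd.DataFrame, prev: pd.DataFrame, strict: bool) -> None:
    """Reject (strict) or warn about (lenient) spatial clusters never seen
    in the single-cell prevalence table.

    A cluster that is known but has no positives is legitimately
    non-relevant; a cluster absent from prevalence altogether means the
    two tables disagree, and imputing f=0 for it silently is forbidden.
    """
    unknown = sorted(set(st["cluster_id"]) - set(prev["cluster_id"]))
    if not unknown:
        return
    if strict:
        raise ConsistencyError(
            f"spatial cluster(s) absent from the prevalence table: {unknown[:10]}"
        )
    logger.warning(
        "spatial table: %d cluster(s) absent from prevalence excluded: %s",
        len(unknown),
        unknown[:10],
    )


def tabulate_structure_clusters(
    st: pd.DataFrame, relevant: set[str]
) -> pd.DataFrame:
    """Cross-tabulate retained spatial cells: structures x relevant clusters.

    Returns a structure-by-cluster integer count matrix (structures as
    index). Rows of non-relevant clusters are excluded and counted in
    ``attrs["n_irrelevant"]``; structures left without any relevant cell
    drop out of the table and are listed in ``attrs["structures_dropped"]``.
    """
    if st.empty:
        raise EmptyResultError("no retained spatial rows to tabulate")
    in_relevant = st["cluster_id"].isin(relevant)
    n_irrelevant = int((~in_relevant).sum())
    kept = st[in_relevant]
    if kept.empty:
        raise EmptyResultError("no spatial cells belong to relevant clusters")
    counts = (
        kept.groupby(["structure", "cluster_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    dropped = sorted(set(st["structure"]) - set(counts.index))
    if n_irrelevant:
        logger.info(
            "spatial tabulation: %d row(s) of non-relevant clusters excluded",
            n_irrelevant,
        )
    counts.attrs["n_irrelevant"] = n_irrelevant
    counts.attrs["structures_dropped"] = dropped
    return counts


@dataclass
class ImputationReport:
    """Expected marker-positive counts per structure and class.

    Attributes
    ----------
    per_structure
        Columns (structure, n_cells, expected_positive).
    by_class
        Columns (structure, nt_class, expected, pct); ``pct`` is NaN for
        a structure with zero expected positives.
    provenance
        Run metadata: marker, tau, sections, cluster count, excluded-row
        counters.
    """

    per_structure: pd.DataFrame
    by_class: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        structures = []
        for _, row in self.per_structure.iterrows():
            s = row["structure"]
            cls_rows = self.by_class[self.by_class["structure"] == s]
            structures.append(
                {
                    "acronym": s,
                    "n_cells": int(row["n_cells"]),
                    "expected_positive": float(row["expected_positive"]),
                    "by_class": {
                        r["nt_class"]: {
                            "expected": float(r["expected"]),
                            "pct": None if pd.isna(r["pct"]) else float(r["pct"]),
                        }
                        for _, r in cls_rows.iterrows()
                    },
                }
            )
        return {**self.provenance, "structures": structures}


def impute_expected_counts(
    counts: pd.DataFrame,
    prev: pd.DataFrame,
    taxonomy: pd.DataFrame,
    provenance: dict | None = None,
) -> ImputationReport:
    """Impute expected marker-positive counts from the count matrix.

    Every cluster column of ``counts`` must have a prevalence row;
    silently assuming f=0 for an unknown cluster is forbidden.
    """
    prev_idx = prev.set_index("cluster_id")
    missing = [k for k in counts.columns if k not in prev_idx.index]
    if missing:
        raise ConsistencyError(
            f"cluster(s) in spatial counts missing from prevalence: {missing}"
        )
    f = prev_idx.loc[list(counts.columns), "fraction"].to_numpy(dtype=float)
    nt = (
        taxonomy.set_index("cluster_id")["nt_class"]
        .reindex(counts.columns)
        .fillna("unassigned")
    )

    mat = counts.to_numpy(dtype=float)
    expected_total = mat @ f
    n_cells = mat.sum(axis=1).astype(int)

    per_structure = pd.DataFrame(
        {
            "structure": counts.index,
            "n_cells": n_cells,
            "expected_positive": expected_total,
        }
    ).reset_index(drop=True)

    rows = []
    for c in NT_CLASSES:
        mask = (nt == c).to_numpy()
        e_c = mat[:, mask] @ f[mask] if mask.any() else np.zeros(len(counts))
        for s, tot, e in zip(counts.index, expected_total, e_c):
            pct = 100.0 * e / tot if tot > 0 else np.nan
            rows.append({"structure": s, "nt_class": c, "expected": e, "pct": pct})
    by_class = (
        pd.DataFrame(rows, columns=list(CLASS_REPORT_COLUMNS))
        .sort_values(["structure", "nt_class"], key=_class_order)
        .reset_index(drop=True)
    )
    return ImputationReport(
        per_structure=per_structure,
        by_class=by_class,
        provenance=dict(provenance or {}),
    )


def _class_order(col: pd.Series) -> pd.Series:
    if col.name == "nt_class":
        order = {c: i for i, c in enumerate(NT_CLASSES)}
        return col.map(order)
    return col
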