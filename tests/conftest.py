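"""Shared fixtures: the hand-checkable toy atlas and brute-force oracles.

The oracles are deliberately naive per-cell Python loops, independent of
the vectorised implementation they check.
"""

from __future__ import annotations

import pandas as pd
import pytest

import atlasxref as ax


@pytest.fixture()
def toy():
    """(sc_cells, spatial_cells, taxonomy) with hand-derived expectations."""
    return ax.toy_tables()


@pytest.fixture()
def config():
    return ax.AnalysisConfig()


@pytest.fixture()
def toy_files(toy, tmp_path):
    """The toy tables written to TSV files."""
    sc, st, tax = toy
    paths = {
        "sc": tmp_path / "sc_cells.tsv",
        "spatial": tmp_path / "spatial_cells.tsv",
        "taxonomy": tmp_path / "taxonomy.tsv",
    }
    ax.write_table(sc, paths["sc"])
    ax.write_table(st, paths["spatial"])
    ax.write_table(tax, paths["taxonomy"])
    return paths


# ---------------------------------------------------------------------------
# Brute-force oracles (naive per-cell loops)
# ---------------------------------------------------------------------------


def brute_prevalence(sc: pd.DataFrame, tau: int) -> dict[str, tuple[int, int]]:
    """cluster_id -> (n_total, n_pos) by looping over individual cells."""
    out: dict[str, list[int]] = {}
    for _, row in sc.iterrows():
        k = row["cluster_id"]
        if k not in out:
            out[k] = [0, 0]
        out[k][0] += 1
        if row["marker_count"] >= tau:
            out[k][1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def brute_composition(sc: pd.DataFrame, taxonomy: pd.DataFrame, tau: int) -> dict[str, int]:
    """nt_class -> positive-cell count by looping over individual cells."""
    cls = dict(zip(taxonomy["cluster_id"], taxonomy["nt_class"]))
    out = {c: 0 for c in ax.NT_CLASSES}
    for _, row in sc.iterrows():
        if row["marker_count"] >= tau:
            out[cls.get(row["cluster_id"], "unassigned")] += 1
    return out


def brute_expected(
    st: pd.DataFrame, fractions: dict[str, float], taxonomy: pd.DataFrame
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Sum f_cluster(i) over individual spatial cells i.

    Returns (structure -> E[s], (structure, nt_class) -> E[s, c]).
    Cells of clusters without a fraction (non-relevant) contribute
    nothing and are skipped, mirroring the relevance filter.
    """
    cls = dict(zip(taxonomy["cluster_id"], taxonomy["nt_class"]))
    e_total: dict[str, float] = {}
    e_class: dict[tuple[str, str], float] = {}
    for _, row in st.iterrows():
        k = row["cluster_id"]
        if k not in fractions:
            continue
        s = row["structure"]
        f = fractions[k]
        e_total[s] = e_total.get(s, 0.0) + f
        key = (s, cls.get(k, "unassigned"))
        e_class[key] = e_class.get(key, 0.0) + f
    return e_total, e_class
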