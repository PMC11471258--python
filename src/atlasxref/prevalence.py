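"""Stage 1: marker-positive prevalence per cluster and class composition.

Given the region-restricted single-cell table, a cell is marker-positive
when its raw marker count is at least the positivity threshold ``tau``
(default 1, i.e. any non-zero expression). For each cluster *k* present
in the region we report

    f_k = n_pos_k / n_total_k

with an equal-tailed Jeffreys binomial interval from
Beta(n_pos + 1/2, n_total - n_pos + 1/2) quantiles. The interval is an
uncertainty annotation on top of the point estimate the cross-reference
consumes; only f_k feeds the imputation.

The composition of the positive population is counted over *cells*, not
clusters: each positive cell contributes one count to its cluster's
neurotransmitter class.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .atlas_model import (
    NT_CLASSES,
    PREVALENCE_COLUMNS,
    AnalysisConfig,
    ConsistencyError,
    EmptyResultError,
)

COMPOSITION_COLUMNS = ("nt_class", "n_pos", "pct")


def filter_marker_positive(sc: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Rows of ``sc`` with ``marker_count >= tau``, order preserved."""
    tau = config.positivity_threshold
    out = sc[sc["marker_count"] >= tau].reset_index(drop=True)
    if out.empty:
        raise EmptyResultError(
            f"no marker-positive cells at threshold {tau} "
            f"(marker {config.marker_name!r})"
        )
    return out


def jeffreys_interval(n_pos, n_total, level: float = 0.95):
    """Equal-tailed Jeffreys interval for a binomial proportion.

    Quantiles of Beta(n_pos + 1/2, n_total - n_pos + 1/2), with the
    usual boundary modification: the lower limit is 0 when n_pos = 0 and
    the upper limit is 1 when n_pos = n_total, so the interval always
    contains the point estimate. Vectorised over ``n_pos``/``n_total``.
    """
    alpha = 1.0 - level
    x = pd.Series(n_pos, dtype=float)
    n = pd.Series(n_total, dtype=float)
    a = x + 0.5
    b = n - x + 0.5
    low = stats.beta.ppf(alpha / 2.0, a, b)
    high = stats.beta.ppf(1.0 - alpha / 2.0, a, b)
    low = pd.Series(low).where(x > 0, 0.0).to_numpy()
    high = pd.Series(high).where(x < n, 1.0).to_numpy()
    return low, high


def _class_map(taxonomy: pd.DataFrame) -> pd.Series:
    return taxonomy.set_index("cluster_id")["nt_class"]


def cluster_prevalence(
    sc: pd.DataFrame,
    positives: pd.DataFrame,
    taxonomy: pd.DataFrame,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-cluster marker-positive counts and fractions.

    One row per cluster with at least one cell in ``sc``; ``positives``
    must be a subset of ``sc`` (cell-id wise).
    """
    stray = set(positives["cell_id"]) - set(sc["cell_id"])
    if stray:
        raise ConsistencyError(
            f"positives contain cell(s) absent from the source table: "
            f"{sorted(stray)[:5]}"
        )
    n_total = sc.groupby("cluster_id", sort=True).size()
    n_pos = positives.groupby("cluster_id", sort=True).size()
    n_pos = n_pos.reindex(n_total.index, fill_value=0)

    classes = _class_map(taxonomy)
    nt = n_total.index.to_series().map(classes).fillna("unassigned")

    fraction = n_pos / n_total
    ci_low, ci_high = jeffreys_interval(n_pos.to_numpy(), n_total.to_numpy(), ci_level)
    prev = pd.DataFrame(
        {
            "cluster_id": n_total.index,
            "nt_class": nt.to_numpy(),
            "n_total": n_total.to_numpy(),
            "n_pos": n_pos.to_numpy(),
            "fraction": fraction.to_numpy(),
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    ).reset_index(drop=True)
    return prev.loc[:, list(PREVALENCE_COLUMNS)]


def class_composition(positives: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Neurotransmitter-class breakdown of the marker-positive cells.

    Counts are cell-level. All four classes are always present, zeros
    included; percentages are exact (display rounding is the caller's
    concern). ``df.attrs["n_pos_total"]`` carries N_pos.
    """
    if positives.empty:
        raise EmptyResultError("no marker-positive cells; composition undefined")
    classes = _class_map(taxonomy)
    per_cell = positives["cluster_id"].map(classes).fillna("unassigned")
    counts = per_cell.value_counts().reindex(list(NT_CLASSES), fill_value=0)
    n_pos_total = int(counts.sum())
    comp = pd.DataFrame(
        {
            "nt_class": counts.index,
            "n_pos": counts.to_numpy(),
            "pct": 100.0 * counts.to_numpy() / n_pos_total,
        }
    ).reset_index(drop=True)
    comp.attrs["n_pos_total"] = n_pos_total
    return comp
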