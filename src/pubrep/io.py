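"""TSV readers and writers for abundance and probability tables.

Formats:

* abundance TSV — header ``clone_id<TAB>count_1<TAB>...<TAB>count_M``,
  one row per clone, integer counts;
* probability TSV — ``clone_id<TAB>p_1<TAB>...<TAB>p_M``;
* AIRR-style rearrangement TSV — one row per rearrangement; rows are
  collapsed on the clonotype column (default ``junction_aa``), summing
  ``duplicate_count`` (defaulting to 1 when the column is absent).

Clone labels are free strings; they are mapped to the shared integer
index by a deterministic sorted-label dictionary at load time so the
same label set always yields the same index assignment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyRepertoireError, InvalidInputError
from .repertoire import CloneAbundance, CloneProbabilities, Cohort


def read_abundance_tsv(
    path: str | Path,
    sample_sizes: list[int] | None = None,
) -> tuple[Cohort, list[str]]:
    """Read an abundance table; returns the cohort and the clone labels."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise EmptyRepertoireError(f"empty repertoire table: {path}")
    labels, df = _sorted_by_label(df)
    counts = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise InvalidInputError("count columns must be numeric")
    if np.any(counts != np.floor(counts)):
        raise InvalidInputError("abundance counts must be integers")
    members = tuple(
        CloneAbundance(counts[:, j].astype(np.int64))
        for j in range(counts.shape[1])
    )
    cohort = Cohort(
        members=members,
        sample_sizes=None if sample_sizes is None else tuple(sample_sizes),
    )
    return cohort, labels


def read_probability_tsv(
    path: str | Path,
    population_sizes: list[int],
    sample_sizes: list[int] | None = None,
) -> tuple[Cohort, list[str]]:
    """Read a probability table; one population size per member required."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise EmptyRepertoireError(f"empty probability table: {path}")
    labels, df = _sorted_by_label(df)
    probs = df.iloc[:, 1:].to_numpy(dtype=float)
    members = tuple(
        CloneProbabilities(probs[:, j]) for j in range(probs.shape[1])
    )
    cohort = Cohort(
        members=members,
        population_sizes=tuple(population_sizes),
        sample_sizes=None if sample_sizes is None else tuple(sample_sizes),
    )
    return cohort, labels


def _sorted_by_label(df: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    label_col = df.columns[0]
    df = df.copy()
    df[label_col] = df[label_col].astype(str)
    if df[label_col].duplicated().any():
        raise InvalidInputError("duplicate clone labels in table")
    df = df.sort_values(label_col, kind="mergesort").reset_index(drop=True)
    return df[label_col].tolist(), df


def write_abundance_tsv(
    path: str | Path,
    cohort: Cohort,
    labels: list[str] | None = None,
) -> None:
    cohort.require_n_representation()
    if labels is None:
        width = len(str(cohort.num_clones))
        labels = [f"clone_{i:0{width}d}" for i in range(1, cohort.num_clones + 1)]
    data = {"clone_id": labels}
    for j, member in enumerate(cohort.members, start=1):
        data[f"count_{j}"] = member.counts
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_airr_tsv(
    path: str | Path,
    clonotype_column: str = "junction_aa",
    count_column: str = "duplicate_count",
) -> tuple[CloneAbundance, list[str]]:
    """Collapse an AIRR-style rearrangement table to clone abundances."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise EmptyRepertoireError(f"empty rearrangement table: {path}")
    if clonotype_column not in df.columns:
        raise InvalidInputError(
            f"column {clonotype_column!r} not found in {path}"
        )
    if count_column in df.columns:
        weights = df[count_column].fillna(1).astype(np.int64)
    else:
        weights = pd.Series(np.ones(len(df), dtype=np.int64))
    grouped = (
        pd.DataFrame(
            {"label": df[clonotype_column].astype(str), "n": weights.values}
        )
        .groupby("label", sort=True)["n"]
        .sum()
    )
    return CloneAbundance(grouped.to_numpy()), grouped.index.tolist()
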