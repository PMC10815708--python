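"""Cross-database expression summarization for candidate genes.

Heterogeneous expression datasets (RNA-seq TPM, RNA-seq RPKM, microarray
intensities) are made comparable by normalizing each dataset to a common
0-100 scale — 100 being the maximum value observed anywhere in that dataset
— then merged by gene symbol (through an ortholog map for cross-species
datasets) and log-scaled as log10(v + 1) for display.  The pseudocount
keeps exact zeros (non-expressed genes) at 0 and the map strictly monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("svprior")

MISSING = float("nan")  # explicit missing marker, distinct from 0


@dataclass
class ExpressionDataset:
    """A gene x tissue matrix of nonnegative expression values.

    ``matrix`` is a DataFrame indexed by gene symbol with one column per
    tissue label; ``unit`` is a free label (TPM, RPKM, intensity, ...).
    """

    name: str
    unit: str
    matrix: pd.DataFrame

    def __post_init__(self):
        if self.matrix.columns.duplicated().any():
            raise ValueError(f"{self.name}: duplicate tissue labels")
        if (self.matrix.to_numpy(dtype=float) < 0).any():
            raise ValueError(f"{self.name}: negative expression values")

    @classmethod
    def from_tsv(cls, path, name: str, unit: str = "") -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(name=name, unit=unit, matrix=df.astype(float))


def normalize_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    """Rescale so the dataset-wide maximum (over all genes and tissues)
    maps to exactly 100: v -> 100 * v / max(ds).

    Idempotent and invariant under multiplication of the whole dataset by
    any positive constant.  An all-zero dataset has no defined scale and is
    returned unchanged with a warning.
    """
    values = ds.matrix.to_numpy(dtype=float)
    peak = np.nanmax(values) if values.size else 0.0
    if not peak > 0:
        logger.warning("%s: all-zero dataset, normalization skipped", ds.name)
        return ExpressionDataset(name=ds.name, unit="normalized 0-100", matrix=ds.matrix.copy())
    return ExpressionDataset(
        name=ds.name,
        unit="normalized 0-100",
        matrix=ds.matrix * (100.0 / peak),
    )


def merge_by_gene(
    datasets: Sequence[ExpressionDataset],
    ortholog_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Outer-join normalized datasets on gene symbol.

    Columns are labelled ``dataset:tissue``; a gene absent from a dataset
    carries NaN (explicitly distinct from an observed 0) in that dataset's
    columns.  ``ortholog_map`` maps each dataset's native symbols (e.g.
    mouse ``Erbb3``) onto the common namespace (human ``ERBB3``); symbols
    without an entry pass through unchanged.
    """
    frames: List[pd.DataFrame] = []
    for ds in datasets:
        m = ds.matrix.copy()
        if ortholog_map:
            m.index = [ortholog_map.get(g, g) for g in m.index]
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()][0]
            raise ValueError(f"{ds.name}: duplicate gene row {dup!r}")
        m.columns = [f"{ds.name}:{t}" for t in m.columns]
        frames.append(m)
    merged = pd.concat(frames, axis=1, join="outer")
    return merged.sort_index()


def log_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Display transform v -> log10(v + 1); missing stays missing.

    Strictly monotone on [0, 100], 0 maps to 0, 100 maps to log10(101).
    """
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("log_scale requires nonnegative input")
    return pd.DataFrame(
        np.log10(values + 1.0), index=matrix.index, columns=matrix.columns
    )


def expression_summary(
    datasets: Sequence[ExpressionDataset],
    ortholog_map: Optional[Dict[str, str]] = None,
    genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Full normalize -> merge -> log chain; optionally restricted to a gene
    set (e.g. the candidate genes)."""
    merged = merge_by_gene([normalize_dataset(ds) for ds in datasets], ortholog_map)
    if genes is not None:
        keep = [g for g in merged.index if g in set(genes)]
        merged = merged.loc[keep]
    return log_scale(merged)


def read_ortholog_map(path) -> Dict[str, str]:
    """TSV with columns human_symbol, mouse_symbol -> {mouse: human}."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.mouse_symbol): str(r.human_symbol)
        for r in df.itertuples(index=False)
    }


def plot_heatmap(display_matrix: pd.DataFrame, path) -> None:
    """Optional rendering of the display matrix as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * display_matrix.shape[1]),
                 max(2.5, 0.4 * display_matrix.shape[0])),
    )
    data = np.ma.masked_invalid(display_matrix.to_numpy(dtype=float))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(display_matrix.shape[1]))
    ax.set_xticklabels(display_matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(display_matrix.shape[0]))
    ax.set_yticklabels(display_matrix.index, fontsize=7, style="italic")
    fig.colorbar(im, ax=ax, label="log10(normalized expression + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
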