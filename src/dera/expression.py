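"""Expression preprocessing and the ternary gene-activity indicator.

Expression matrices are plain pandas DataFrames with genes (or probes) as the
row index and sample IDs as columns, on the log2 scale after preprocessing.
The indicator matrix discretizes each tumor sample against the mean of a
reference (control) sample set: a gene is called over-expressed (+1) or
under-expressed (-1) when its log2 fold change versus the reference mean
reaches the cutoff ``log2(K)`` (K = 2 by default, i.e. a two-fold change),
and unchanged (0) otherwise.

Missing values are permitted (NaN); a missing tumor measurement yields a
missing fold change and an indicator of 0 — a gene with no measurement never
supports a regulation.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_probe_map",
    "read_phenotype",
    "filter_probes",
    "ProbeFilterReport",
    "preprocess",
    "fold_change",
    "indicator",
    "write_indicator",
]

#: Reserved phenotype-group token marking control samples.
REFERENCE_LABEL = "REFERENCE"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated expression matrix.

    First column holds gene (or probe) IDs, the header row holds sample IDs.
    Returns a float DataFrame indexed by gene with samples as columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row IDs in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path}")
    return df.astype(float)


def read_probe_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV ``probe<TAB>gene`` into probe -> gene-set.

    Multi-mapping probes appear as repeated probe rows; a probe mapping to no
    gene appears with an empty gene field. ``#`` comments are allowed.
    """
    mapping: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}, line {lineno}: expected 2 tab-separated fields"
            )
        probe, gene = fields[0].strip(), fields[1].strip()
        mapping.setdefault(probe, set())
        if gene:
            mapping[probe].add(gene)
    return {p: frozenset(g) for p, g in mapping.items()}


def read_phenotype(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``sample_id<TAB>group`` into a Series.

    The reserved group token ``REFERENCE`` marks control samples.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "group"],
        dtype=str, comment="#",
    )
    if (df.iloc[0] == ["sample_id", "group"]).all():  # tolerate a header row
        df = df.iloc[1:]
    s = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    if s.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in phenotype table {path}")
    return s


@dataclass(frozen=True)
class ProbeFilterReport:
    """Counts from probe filtering: probes dropped for multi-gene or no-gene
    mapping, and probes merged into an existing gene row."""

    dropped_multi: int
    dropped_none: int
    collapsed: int


def filter_probes(
    raw: pd.DataFrame,
    probe_map: Mapping[str, frozenset[str]],
    collapse: str = "mean",
) -> tuple[pd.DataFrame, ProbeFilterReport]:
    """Map a probe-level matrix to gene level.

    Probes mapping to zero or to multiple genes are dropped; the rest are
    relabelled by their unique gene. When several retained probes map to the
    same gene their rows are collapsed to one (``collapse`` ∈ {"mean",
    "median", "max"}).
    """
    if collapse not in ("mean", "median", "max"):
        raise ValueError(f"unknown collapse method {collapse!r}")
    missing = [p for p in raw.index if p not in probe_map]
    if missing:
        raise KeyError(f"probe(s) absent from probe map: {missing[:5]}")

    dropped_multi = dropped_none = 0
    keep: list[str] = []
    genes: list[str] = []
    for probe in raw.index:
        targets = probe_map[probe]
        if len(targets) == 0:
            dropped_none += 1
        elif len(targets) > 1:
            dropped_multi += 1
        else:
            keep.append(probe)
            genes.append(next(iter(targets)))

    kept = raw.loc[keep].copy()
    kept.index = pd.Index(genes, name="gene")
    n_collapsed = len(kept) - kept.index.nunique()
    grouped = kept.groupby(level=0, sort=False)
    out = getattr(grouped, collapse)()
    report = ProbeFilterReport(dropped_multi, dropped_none, n_collapsed)
    logger.info(
        "filter_probes: dropped %d multi-gene, %d unmapped; collapsed %d probe(s)",
        dropped_multi, dropped_none, n_collapsed,
    )
    return out, report


def preprocess(
    expr: pd.DataFrame, log2: bool = True, mean_center: bool = True
) -> pd.DataFrame:
    """Log2-transform and/or mean-center an expression matrix.

    Order is log2 first, then centering. Mean-centering subtracts each gene's
    row mean, computed over all columns passed in (tumors and references
    jointly) and over observed entries only when values are missing. Centering
    cannot change downstream indicators — fold changes subtract the reference
    mean and thus cancel any per-gene constant — but it matches the usual
    array-preprocessing convention for visualisation and export.
    """
    out = expr.astype(float)
    if log2:
        bad = (out <= 0) & out.notna()
        if bad.to_numpy().any():
            gene = bad.any(axis=1).idxmax()
            sample = bad.loc[gene].idxmax()
            raise ValueError(
                f"non-positive value at gene {gene!r}, sample {sample!r}: "
                f"{out.loc[gene, sample]} cannot be log2 transformed"
            )
        out = np.log2(out)
    if mean_center:
        out = out.sub(out.mean(axis=1, skipna=True), axis=0)
    return out


def fold_change(
    expr: pd.DataFrame,
    tumor_ids: Iterable[str],
    reference_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-sample log2 fold change of each gene versus the reference mean.

    Entry (i, j) is ``expr[i, j] - mean_k expr[i, k]`` over reference samples
    k: over-expression in the tumor gives a positive value. ``expr`` must be
    on the log2 scale. Tumor and reference IDs must be disjoint subsets of the
    columns, and the reference set non-empty.
    """
    tumor_ids = list(tumor_ids)
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference sample set is empty")
    unknown = [s for s in (*tumor_ids, *reference_ids) if s not in expr.columns]
    if unknown:
        raise KeyError(f"unknown sample ID(s): {unknown[:5]}")
    overlap = set(tumor_ids) & set(reference_ids)
    if overlap:
        raise ValueError(f"tumor and reference sets overlap: {sorted(overlap)[:5]}")
    ref_mean = expr[reference_ids].mean(axis=1, skipna=True)
    return expr[tumor_ids].sub(ref_mean, axis=0)


def indicator(fc: pd.DataFrame, K: float = 2.0) -> pd.DataFrame:
    """Ternary gene-activity indicator from a log2 fold-change matrix.

    +1 where ``fc >= log2(K)``, -1 where ``fc <= -log2(K)``, else 0; the
    boundary is inclusive ("at least a K-fold difference"). Missing fold
    changes map to 0. K must exceed 1, otherwise every gene would be called.
    """
    if not K > 1:
        raise ValueError(f"fold-change cutoff K must be > 1, got {K}")
    thr = math.log2(K)
    vals = fc.to_numpy(dtype=float)
    out = np.zeros(vals.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[vals >= thr] = 1
        out[vals <= -thr] = -1
    return pd.DataFrame(out, index=fc.index, columns=fc.columns)


def write_indicator(ind: pd.DataFrame, path: str | Path) -> None:
    """Write a genes × tumors indicator matrix of {-1, 0, 1} as TSV."""
    ind.to_csv(path, sep="\t", index_label="gene")
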