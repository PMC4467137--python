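"""Reading and writing expression matrices, labels and gene lists.

Expression matrices are plain :class:`pandas.DataFrame` objects oriented
features x samples, with log2-scale values, unique string feature identifiers
as the index and unique sample identifiers as the columns.  Probe-level
matrices are collapsed to gene level by keeping, per gene, the probe with the
largest inter-quartile range across samples.

Supported on-disk formats: TSV/CSV (header row = sample IDs), GCT 1.2
(read-only; version and dimension lines skipped, ``Description`` column
dropped), one-symbol-per-line or two-column (gene, class) signature lists,
and single-line space-separated CLS-style label files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "collapse_probes",
    "read_gene_list",
    "read_labels",
    "write_labels",
    "read_cls",
    "write_cls",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what} identifier(s): {', '.join(dups)}")


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check uniqueness of IDs and absence of missing / non-numeric cells."""
    _check_unique(list(m.index.astype(str)), "feature")
    _check_unique(list(m.columns.astype(str)), "sample")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = m.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {m.index[r]!r}, sample {m.columns[c]!r}"
        )
    nan = np.argwhere(~np.isfinite(values))
    if nan.size:
        r, c = nan[0]
        raise ValueError(
            f"missing/non-finite value at feature {m.index[r]!r}, "
            f"sample {m.columns[c]!r}"
        )
    return m


def read_matrix(
    path: str | Path,
    orientation: str = "features_by_samples",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited expression matrix, returning features x samples.

    Parameters
    ----------
    path:
        TSV/CSV file with a header row, or a GCT 1.2 file.
    orientation:
        ``features_by_samples`` (default) or ``samples_by_features``; the
        returned frame is always features x samples.
    """
    path = Path(path)
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        m = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if m.columns[0].lower() == "description":
            m = m.drop(columns=m.columns[0])
    else:
        delim = _sep_for(path, sep)
        _check_ragged(path, delim)
        m = pd.read_csv(path, sep=delim, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if orientation == "samples_by_features":
        m = m.T
    try:
        m = m.astype(float)
    except (TypeError, ValueError):
        pass  # validate_matrix reports the offending cell
    return validate_matrix(m)


def _check_ragged(path: Path, delim: str) -> None:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        width = len(header)
        _check_unique(header[1:], "header")  # pandas would silently mangle dups
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) not in (width, width + 1):
                # index column may or may not have a header cell
                raise ValueError(
                    f"ragged row at line {lineno} of {path}: "
                    f"{len(row)} fields, expected {width} or {width + 1}"
                )


def write_matrix(m: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    m.to_csv(path, sep=_sep_for(path, sep))


def iqr(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Inter-quartile range with linear-interpolation (type-7) quartiles."""
    q75, q25 = np.percentile(values, [75, 25], axis=axis)
    return q75 - q25


def collapse_probes(m: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For each gene the probe with the largest IQR across samples is retained;
    IQR ties are broken toward the lexicographically smaller probe id.  Output
    rows are gene symbols in sorted order.
    """
    unmapped = sorted(set(m.index) - set(probe_map))
    if unmapped:
        raise ValueError(f"probe(s) absent from map: {', '.join(unmapped)}")
    probe_iqr = pd.Series(iqr(m.to_numpy(), axis=1), index=m.index)
    best: dict[str, str] = {}
    for probe in sorted(m.index):  # sorted -> first max is the smallest id
        gene = probe_map[probe]
        if gene not in best or probe_iqr[probe] > probe_iqr[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    out = m.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return out


def read_gene_list(path: str | Path, sep: str = "\t") -> list[str] | dict[str, str]:
    """Read a signature gene list.

    One symbol per line returns a list; two columns (gene, class) return a
    gene -> class dict.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(line.split(sep))
    if all(len(r) == 1 for r in rows):
        return [r[0] for r in rows]
    if all(len(r) == 2 for r in rows):
        return {r[0]: r[1] for r in rows}
    raise ValueError(f"{path}: expected one or two columns throughout")


def read_labels(path: str | Path, sep: str = "\t") -> pd.Series:
    """Read a two-column (sample, label) table into a Series."""
    df = pd.read_csv(path, sep=sep, index_col=0, header=None, dtype=str)
    return df.iloc[:, 0].rename("label")


def write_labels(labels: pd.Series, path: str | Path, sep: str = "\t") -> None:
    labels.to_csv(path, sep=sep, header=False)


def read_cls(path: str | Path) -> list[str]:
    """Read a CLS-like label file: a single line of space-separated labels."""
    with open(path) as fh:
        line = fh.readline().strip()
    return line.split() if line else []


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(str(x) for x in labels) + "\n")
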