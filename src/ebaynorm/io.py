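"""Reading and writing count tables, labels, trees, and result tables.

Counts travel as UTF-8 tab-separated text with a header row of taxa names and
a first column of sample ids (or the transpose, via ``taxa_are_rows``). Every
table the package writes starts with a ``#`` provenance line recording the
producing method, its options, and the seed, so any output can be re-derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import PhyloTree


def read_counts(path, taxa_are_rows: bool = False) -> pd.DataFrame:
    """Read a TSV count table into a samples x taxa integer DataFrame.

    Cells must be nonnegative integers; the offending row/column is named
    otherwise. Duplicate taxa names are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if taxa_are_rows:
        df = df.T
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    # pandas silently renames duplicate header fields, so check the raw header
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
    names = list(df.index) if taxa_are_rows else header
    dups = [n for i, n in enumerate(names) if n in names[:i]]
    if dups:
        raise ValueError(f"{path}: duplicate taxa names {sorted(set(dups))}")
    values = df.to_numpy()
    bad = ~np.isfinite(values) | (values < 0) | (values != np.round(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{path}: cell ({df.index[i]!r}, {df.columns[j]!r}) = "
                         f"{values[i, j]!r} is not a nonnegative integer")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path, provenance: str = "") -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t")


def read_labels(path) -> pd.Series:
    """Read a two-column TSV (sample id, group) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.iloc[:, 0]


def read_tree(path, taxa: list[str] | None = None) -> PhyloTree:
    """Read a rooted Newick tree; leaf labels must equal the taxa names.

    A mismatch is reported as the symmetric difference of the two label sets.
    """
    return PhyloTree.from_newick(str(path), taxa=taxa)


def write_table(df: pd.DataFrame, path, provenance: str = "") -> None:
    """Write a result table as TSV with a provenance comment line."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)
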