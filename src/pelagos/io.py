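"""Reading, writing, normalisation and prefiltering of OTU tables.

File conventions: tab-separated UTF-8 text, ``#`` comment lines ignored.  OTU
tables are written with OTUs as rows and samples as columns (the common
amplicon-pipeline orientation); orientation on read is auto-detected from the
header keyword ``sample_id`` or can be forced.  Trees are newick.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable

__all__ = [
    "load_otu_table",
    "write_otu_table",
    "load_metadata",
    "write_metadata",
    "rarefy_table",
    "filter_for_network",
    "read_newick",
    "write_newick",
    "validate_tree_tips",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def load_otu_table(path, taxonomy_path=None, orientation: str = "auto") -> OtuTable:
    """Load an OTU count table from TSV.

    Parameters
    ----------
    path : str or Path
        TSV file; first column holds row ids.
    taxonomy_path : str or Path, optional
        Two-column TSV mapping OTU id to lineage string.
    orientation : {"auto", "otus_as_rows", "samples_as_rows"}
        ``auto`` treats the table as OTUs-as-rows unless the id header is
        ``sample_id``.
    """
    raw = _read_tsv(path)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate column ids {dups}")
    try:
        numeric = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count ({exc})") from exc
    if not np.allclose(numeric.to_numpy(), np.round(numeric.to_numpy())):
        bad = numeric.index[
            ~np.isclose(numeric, np.round(numeric)).all(axis=1)
        ].tolist()
        raise FormatError(f"{path}: non-integer counts in rows {bad}")

    if orientation == "auto":
        orientation = (
            "samples_as_rows"
            if (raw.index.name or "").lower() in {"sample_id", "sample", "samples"}
            else "otus_as_rows"
        )
    if orientation == "otus_as_rows":
        numeric = numeric.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    taxonomy = None
    if taxonomy_path is not None:
        tax = _read_tsv(taxonomy_path)
        taxonomy = tax.iloc[:, 0].to_dict()
    return OtuTable(numeric.astype(np.int64), taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    """Write OTUs-as-rows TSV that round-trips through :func:`load_otu_table`."""
    out = table.counts.T
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def load_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    md.index = md.index.astype(str)
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def rarefy_table(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draw per sample; deterministic for a given
    seed.  Raises if any sample holds fewer than ``depth`` reads, naming the
    failing samples.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    short = totals.index[totals < depth].tolist()
    if short:
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: {short}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns),
        taxonomy=table.taxonomy,
    )


def filter_for_network(
    table: OtuTable,
    min_prevalence: float = 0.30,
    min_mean_relabund: float = 0.0001,
    mode: str = "and",
) -> OtuTable:
    """Prevalence/abundance prefilter applied before correlation inference.

    An OTU is retained when it occurs in at least ``min_prevalence`` of
    samples AND has mean relative abundance at least ``min_mean_relabund``
    (``mode="and"``, the default).  ``mode="or"`` retains OTUs passing either
    rule (i.e. removes only those failing both).
    """
    if table.n_samples == 0 or table.n_otus == 0:
        raise ValueError("empty table")
    prevalence = (table.counts > 0).mean(axis=0)
    mean_ra = table.relative_abundance().mean(axis=0)
    pass_prev = prevalence >= min_prevalence
    pass_ab = mean_ra >= min_mean_relabund
    if mode == "and":
        keep = pass_prev & pass_ab
    elif mode == "or":
        keep = pass_prev | pass_ab
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        warnings.warn("prevalence/abundance filter removed every OTU")
    return OtuTable(
        table.counts.loc[:, keep.index[keep]].copy(), taxonomy=table.taxonomy
    )


def read_newick(source) -> TreeNode:
    """Read a rooted tree from a newick file or string.

    Branch lengths missing in the source default to 0 with a warning.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        tree = TreeNode.read(str(source), format="newick")
    else:
        tree = TreeNode.read(_io.StringIO(str(source)), format="newick")
    missing = [n for n in tree.traverse(include_self=False) if n.length is None]
    if missing:
        warnings.warn(f"{len(missing)} branches had no length; defaulting to 0")
        for n in missing:
            n.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def validate_tree_tips(tree: TreeNode, table: OtuTable) -> None:
    """Raise if any OTU in the table is not a tip of the tree."""
    tips = {t.name for t in tree.tips()}
    absent = [o for o in table.otu_ids if o not in tips]
    if absent:
        raise ValueError(f"OTUs absent from the tree: {absent}")
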