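"""Reading, validation, and serialization of OTU tables, trees, metadata, and results.

All tabular artifacts are tab-separated UTF-8 with ``.`` decimals; trees are
newick; networks are written as GraphML plus an edge-list TSV; summaries as
JSON.  Everything in memory is labeled — samples × OTUs is the canonical
orientation for count tables, and every square matrix carries sample (or OTU)
identifiers on both axes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import skbio


class IdentifierError(ValueError):
    """Duplicate, unknown, or mismatched sample/OTU identifiers."""


class ValidationError(ValueError):
    """A table or matrix violates a structural invariant."""


class CoverageError(ValueError):
    """OTUs required by an operation are missing from the tree."""


#: Environmental factors measured per sample in a typical hydrographic cast.
ENV_FACTORS = (
    "depth",
    "temperature",
    "salinity",
    "NO3_N",
    "NO2_N",
    "NH4_N",
    "SiO3_Si",
    "PO4_P",
    "dissolved_oxygen",
    "chlorophyll_a",
    "POC",
)


@dataclasses.dataclass(frozen=True)
class OtuTable:
    """Integer OTU count matrix, rows = samples, columns = OTUs.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts indexed by sample id, columns OTU ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise IdentifierError("duplicate sample ids in OTU table")
        if df.columns.has_duplicates:
            raise IdentifierError("duplicate OTU ids in OTU table")
        values = df.to_numpy()
        if values.size == 0:
            raise ValidationError("empty OTU table")
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric counts in OTU table")
        if np.any(values < 0):
            raise ValidationError("negative counts in OTU table")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("non-integer counts in OTU table")
        if np.any(values.sum(axis=1) == 0):
            empty = df.index[values.sum(axis=1) == 0].tolist()
            raise ValidationError(f"samples with zero total counts: {empty}")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean occurrence matrix (count > 0)."""
        return self.counts > 0

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, keep])

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.counts.index]
        if missing:
            raise IdentifierError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[ids])


@dataclasses.dataclass(frozen=True)
class PhyloTree:
    """Rooted phylogeny over OTU labels with non-negative branch lengths."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(tips) != len(set(tips)):
            raise IdentifierError("duplicate leaf labels in tree")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def check_coverage(self, otu_ids: Iterable[str]) -> None:
        """Raise :class:`CoverageError` if any OTU id is not a leaf."""
        tips = set(self.tip_names)
        missing = sorted(set(otu_ids) - tips)
        if missing:
            shown = missing[:10]
            raise CoverageError(
                f"{len(missing)} OTUs absent from tree, e.g. {shown}"
            )

    def prune_to(self, otu_ids: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to the given leaves (shears extra tips)."""
        self.check_coverage(otu_ids)
        return PhyloTree(self.tree.shear(list(otu_ids)))

    def patristic_matrix(self, otu_ids: Iterable[str] | None = None) -> pd.DataFrame:
        """Symmetric matrix of tip-to-tip path lengths, labeled by OTU id."""
        dm = self.tree.tip_tip_distances()
        df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
        if otu_ids is not None:
            ids = list(otu_ids)
            self.check_coverage(ids)
            df = df.loc[ids, ids]
        return df

    def write(self, path: str | Path) -> None:
        self.tree.write(str(path), format="newick")


@dataclasses.dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata: site, depth layer, depth (m), environmental factors.

    ``meta`` must contain columns ``site``, ``layer``, ``depth``; any further
    numeric columns are treated as environmental factors (units per factor —
    °C, psu, µmol/L, mg/m³...).  Missing environmental values are permitted;
    only stages that need them drop the affected samples.
    """

    meta: pd.DataFrame

    REQUIRED = ("site", "layer", "depth")

    def __post_init__(self) -> None:
        if self.meta.index.has_duplicates:
            raise IdentifierError("duplicate sample ids in metadata")
        for col in self.REQUIRED:
            if col not in self.meta.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if (self.meta["depth"] <= 0).any():
            raise ValidationError("depths must be positive (meters below surface)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def env(self) -> pd.DataFrame:
        """Environmental-factor columns (everything beyond site/layer; depth kept)."""
        cols = [
            c
            for c in self.meta.columns
            if c not in ("site", "layer") and pd.api.types.is_numeric_dtype(self.meta[c])
        ]
        return self.meta[cols]

    def check_alignment(self, table: OtuTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.meta.index]
        if missing:
            raise IdentifierError(f"samples absent from metadata: {missing}")

    def aligned_to(self, table: OtuTable) -> "SampleFrame":
        self.check_alignment(table)
        return SampleFrame(self.meta.loc[table.sample_ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "SampleFrame":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.meta.index]
        if missing:
            raise IdentifierError(f"unknown sample ids: {missing}")
        return SampleFrame(self.meta.loc[ids])


@dataclasses.dataclass
class ResultBundle:
    """Named collection of labeled matrices, tables, graphs, and run metadata."""

    matrices: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    graphs: dict[str, nx.Graph] = dataclasses.field(default_factory=dict)
    summaries: dict[str, dict] = dataclasses.field(default_factory=dict)
    metadata: dict = dataclasses.field(default_factory=dict)

    def add_matrix(self, name: str, df: pd.DataFrame) -> None:
        self.matrices[name] = df

    def add_table(self, name: str, df: pd.DataFrame) -> None:
        self.tables[name] = df

    def add_graph(self, name: str, g: nx.Graph) -> None:
        self.graphs[name] = g

    def add_summary(self, name: str, payload: dict) -> None:
        self.summaries[name] = payload


# ---------------------------------------------------------------------------
# readers


def read_otu_table(
    path: str | Path,
    orientation: str = "rows-are-samples",
) -> OtuTable:
    """Read a tab-separated count table into canonical samples × OTUs form.

    Parameters
    ----------
    orientation : {"rows-are-samples", "rows-are-otus", "auto"}
        Layout of the file.  ``auto`` guesses: the axis with fewer entries is
        taken to be samples (OTU counts almost always exceed sample counts).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "auto":
        orientation = (
            "rows-are-samples" if df.shape[0] <= df.shape[1] else "rows-are-otus"
        )
    if orientation == "rows-are-otus":
        df = df.T
    elif orientation != "rows-are-samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return OtuTable(df)


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted newick tree; internal/bootstrap labels are kept but unused."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    return PhyloTree(tree)


def read_sample_frame(path: str | Path) -> SampleFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return SampleFrame(meta)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# result serialization

_FLOAT_FMT = "%.17g"  # full float64 round-trip fidelity


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(bundle: ResultBundle, out_dir: str | Path) -> pd.DataFrame:
    """Write every artifact in *bundle* under *out_dir*; return the manifest.

    Matrices and tables become labeled TSV, graphs GraphML plus an edge-list
    TSV, summaries JSON.  The manifest (also written, as ``manifest.tsv``)
    lists every file with its SHA-256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, df in bundle.matrices.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        written.append(p)
    for name, df in bundle.tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        written.append(p)
    for name, g in bundle.graphs.items():
        p = out / f"{name}.graphml"
        nx.write_graphml(g, p)
        written.append(p)
        p2 = out / f"{name}_edges.tsv"
        rows = [
            {"source": u, "target": v, **{k: data[k] for k in sorted(data)}}
            for u, v, data in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "phi", "weight"]).to_csv(
            p2, sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written.append(p2)
    for name, payload in bundle.summaries.items():
        p = out / f"{name}.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
        written.append(p)
    if bundle.metadata:
        p = out / "run_metadata.json"
        p.write_text(
            json.dumps(bundle.metadata, indent=2, sort_keys=True, default=_jsonify)
        )
        written.append(p)

    manifest = pd.DataFrame(
        {
            "file": [p.name for p in written],
            "sha256": [_sha256(p) for p in written],
        }
    ).sort_values("file", ignore_index=True)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read back a labeled square matrix TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
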