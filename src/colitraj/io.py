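"""Readers, writers and core containers for every external format the pipeline touches.

All tabular formats are tab-separated text with ``#`` comment lines allowed.
Feature and sample identifiers are case-sensitive strings; on load, rows and
columns are canonicalized by sorted id so that input ordering can never change
a downstream numerical result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("colitraj")

DEFAULT_DAYS = (5, 12, 17, 36)

GROUP_DISEASE = "disease"
GROUP_CONTROL = "control"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with per-sample library sizes.

    ``library_sizes`` defaults to column sums but may be supplied explicitly,
    e.g. to keep blood VDJ normalization consistent with the full library.
    """

    counts: pd.DataFrame  # features x samples, integer dtype
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise FormatError(
                    f"non-integer count at feature {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            c = c.round().astype(np.int64)
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at feature {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}"
            )
        # canonical order
        c = c.sort_index(axis=0).sort_index(axis=1)
        object.__setattr__(self, "counts", c)
        if self.library_sizes is None:
            lib = c.sum(axis=0)
        else:
            lib = self.library_sizes.reindex(c.columns)
            if lib.isna().any():
                missing = lib.index[lib.isna()].tolist()
                raise FormatError(f"library sizes missing for samples: {missing[:5]}")
        lib = lib.astype(np.int64)
        if (lib <= 0).any():
            raise FormatError("library sizes must be positive")
        object.__setattr__(self, "library_sizes", lib)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            self.counts[sample_ids], self.library_sizes.loc[sample_ids]
        )


@dataclass
class ExonAnnotation:
    """Maps exon counting-bin ids to genes with a 1-based bin index."""

    table: pd.DataFrame  # columns exon_id, gene_id, bin_index

    def __post_init__(self) -> None:
        t = self.table
        required = {"exon_id", "gene_id", "bin_index"}
        if not required.issubset(t.columns):
            raise FormatError(f"exon annotation requires columns {sorted(required)}")
        if t["exon_id"].duplicated().any():
            raise FormatError("exon_id must map to exactly one gene")
        if (t["bin_index"].astype(int) < 1).any():
            raise FormatError("bin_index must be >= 1")
        t = t.sort_values("exon_id").reset_index(drop=True)
        object.__setattr__(self, "table", t)

    def gene_of(self) -> pd.Series:
        """exon_id -> gene_id mapping as a Series."""
        return self.table.set_index("exon_id")["gene_id"]


@dataclass
class Signature:
    """A labeled gene set with optional per-gene direction/weight.

    Labels follow the pipeline convention ``fixed-day-<d>``, ``cluster-<X>``,
    ``splice-day-<d>`` or ``all-day-average``.
    """

    label: str
    genes: list[str]
    direction: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"signature {self.label!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Network:
    """Undirected, deduplicated gene network."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# counts and metadata
# ---------------------------------------------------------------------------


def read_counts(path, kind: str = "gene", library_sizes: pd.Series | None = None) -> CountMatrix:
    """Read a count TSV (first column feature id, header row of sample ids).

    ``kind`` is ``gene`` or ``exon``; exon matrices are expected to be paired
    with an :class:`ExonAnnotation` loaded via :func:`read_exon_annotation`.
    """
    if kind not in ("gene", "exon"):
        raise ValueError(f"kind must be 'gene' or 'exon', got {kind!r}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    cm = CountMatrix(df, library_sizes=library_sizes)
    logger.info("read_counts(%s): %d features x %d samples", kind, *cm.shape)
    return cm


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_exon_annotation(path) -> ExonAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"exon_id": str, "gene_id": str})
    return ExonAnnotation(df)


def write_exon_annotation(ann: ExonAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


META_COLUMNS = ["sample_id", "group", "day", "cohort", "tissue"]


def validate_sample_meta(df: pd.DataFrame, allowed_days=DEFAULT_DAYS) -> pd.DataFrame:
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"sample metadata missing columns: {sorted(missing)}")
    df = df[META_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    df["group"] = df["group"].astype(str).str.lower()
    bad_groups = set(df["group"]) - {GROUP_DISEASE, GROUP_CONTROL}
    if bad_groups:
        raise FormatError(f"unknown group labels: {sorted(bad_groups)}")
    df["day"] = df["day"].astype(int)
    allowed = set(int(d) for d in allowed_days)
    bad_days = set(df["day"]) - allowed
    if bad_days:
        raise FormatError(
            f"days {sorted(bad_days)} outside allowed set {sorted(allowed)}"
        )
    return df.sort_values("sample_id").reset_index(drop=True)


def read_sample_meta(path, allowed_days=DEFAULT_DAYS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = validate_sample_meta(df, allowed_days)
    logger.info("read_sample_meta: %d samples, days %s", len(meta), sorted(meta["day"].unique()))
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: member set}``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = set(fields[2:]) - {""}
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(collection: dict[str, set[str]], path, description: str = "colitraj") -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def signature_to_gmt(signatures: list[Signature], path) -> None:
    write_gmt({s.label: set(s.genes) for s in signatures}, path)


# ---------------------------------------------------------------------------
# networks / ortholog maps / clone tables
# ---------------------------------------------------------------------------


def read_network(path, dialect: str = "sif") -> Network:
    """Load an edge list as an undirected graph.

    SIF lines are ``node relation node [node ...]``; TSV lines are two-column.
    Direction in the source file is discarded, parallel edges are merged, and
    self-loops are dropped with a warning.
    """
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"dialect must be 'sif' or 'tsv', got {dialect!r}")
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if dialect == "sif":
                if len(fields) == 1:
                    g.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise FormatError(f"{path}: malformed SIF line {lineno}")
                a, targets = fields[0], fields[2:]
            else:
                if len(fields) < 2:
                    raise FormatError(f"{path}: malformed edge line {lineno}")
                a, targets = fields[0], [fields[1]]
            for b in targets:
                if a == b:
                    n_self += 1
                    continue
                g.add_edge(a, b)
    if n_self:
        logger.warning("read_network: dropped %d self-loop(s)", n_self)
    return Network(g)


def read_ortholog_map(path) -> dict[str, set[str]]:
    """Two-column TSV (source gene, target gene) -> one-to-many mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["src", "dst"], dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: ortholog map rows must have two fields")
    out: dict[str, set[str]] = {}
    for src, dst in df.itertuples(index=False):
        out.setdefault(src, set()).add(dst)
    return out


def read_clone_table(path) -> pd.DataFrame:
    """VDJ clone abundances: columns sample_id, clone_id, reads."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "clone_id", "reads"}
    if not required.issubset(df.columns):
        raise FormatError(f"clone table requires columns {sorted(required)}")
    df = df[["sample_id", "clone_id", "reads"]].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["reads"] = df["reads"].astype(int)
    if (df["reads"] < 0).any():
        raise FormatError("clone read counts must be non-negative")
    return df.sort_values(["sample_id", "clone_id"]).reset_index(drop=True)


def read_histology(path) -> pd.Series:
    """Per-sample histopathology scores (columns sample_id, histo_score)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample_id", "histo_score"}.issubset(df.columns):
        raise FormatError("histology table requires columns sample_id, histo_score")
    s = df.set_index(df["sample_id"].astype(str))["histo_score"].astype(float)
    if (s < 0).any():
        raise FormatError("histology scores must be >= 0")
    return s.sort_index()


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
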