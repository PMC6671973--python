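"""Readers, writers and validated in-memory representations for every file
format the pipeline touches.

Tab-separated text throughout: expression matrices (with an optional parallel
detection-flag file), probe annotations, sample designs and result tables.
Gene sets use the GMT dialect; networks export to SIF and GraphML
(Cytoscape-loadable).

Conventions
-----------
* Genomic coordinates are 1-based inclusive. A BED export, if ever added,
  must convert to 0-based half-open.
* Detection flags use the Agilent vocabulary ``P`` (present), ``A`` (absent)
  and ``M`` (marginal). A missing flag file means all-present.
* Gene identity is the symbol string, case-sensitive; no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_FLAGS = frozenset({"P", "A", "M"})
VALID_SCALES = ("raw", "log2", "normalized")
VALID_TRANSCRIPT_TYPES = frozenset({"mRNA", "lncRNA"})
VALID_STRANDS = frozenset({"+", "-", "."})
VALID_CONDITIONS = ("control", "treated")


class FormatError(ValueError):
    """Malformed input file or inconsistent in-memory structure."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with per-cell detection flags.

    Parameters
    ----------
    probe_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Float array of shape ``(len(probe_ids), len(sample_ids))``.
    flags
        Character array of the same shape with cells in ``{P, A, M}``,
        or ``None`` meaning all-present.
    scale_tag
        One of ``raw``, ``log2``, ``normalized``; transitions only move
        forward along that sequence.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    flags: np.ndarray | None = None
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype="<U1")
            if self.flags.shape != self.values.shape:
                raise FormatError(
                    f"flags shape {self.flags.shape} does not match values shape "
                    f"{self.values.shape}"
                )
            bad = ~np.isin(self.flags, list(VALID_FLAGS))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"invalid flag {self.flags[i, j]!r} at probe "
                    f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
        if self.scale_tag not in VALID_SCALES:
            raise FormatError(f"unknown scale_tag {self.scale_tag!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_lookup[probe_id]
        except AttributeError:
            self._probe_lookup = {p: i for i, p in enumerate(self.probe_ids)}
            return self._probe_lookup[probe_id]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def effective_flags(self) -> np.ndarray:
        """Flags array, materializing the all-present default."""
        if self.flags is None:
            return np.full(self.values.shape, "P", dtype="<U1")
        return self.flags

    def subset_probes(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        """Row-subset preserving probe order; `keep` is ids or a bool mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            mask = keep
        else:
            wanted = set(str(k) for k in keep)
            mask = np.array([p in wanted for p in self.probe_ids])
        idx = np.flatnonzero(mask)
        return ExpressionMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx].copy(),
            flags=None if self.flags is None else self.flags[idx].copy(),
            scale_tag=self.scale_tag,
        )

    def with_values(self, values: np.ndarray, scale_tag: str) -> "ExpressionMatrix":
        order = {s: i for i, s in enumerate(VALID_SCALES)}
        if order[scale_tag] < order[self.scale_tag]:
            raise FormatError(
                f"scale transition {self.scale_tag} -> {scale_tag} moves backwards"
            )
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            flags=None if self.flags is None else self.flags.copy(),
            scale_tag=scale_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def read_expression_matrix(path: str | Path, flag_path: str | Path | None = None,
                           scale_tag: str = "raw") -> ExpressionMatrix:
    """Read a tab-separated matrix (first column probe ids, header sample ids)
    plus an optional parallel flag file of identical shape."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # astype parses with round-trip precision (pd.to_numeric does not)
            values[:, j] = df[col].astype(np.float64).to_numpy()
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric cell at probe {row!r}, sample {col!r}"
            ) from None
    flags = None
    if flag_path is not None:
        fdf = pd.read_csv(flag_path, sep="\t", index_col=0, dtype=str)
        if list(fdf.index) != list(df.index) or list(fdf.columns) != list(df.columns):
            raise FormatError(
                f"{flag_path}: flag file dimensions/ids do not match {path}"
            )
        flags = fdf.to_numpy(dtype="<U1")
        bad = ~np.isin(flags, list(VALID_FLAGS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"{flag_path}: invalid flag {flags[i, j]!r} at probe "
                f"{fdf.index[i]!r}, sample {fdf.columns[j]!r}"
            )
    return ExpressionMatrix(
        probe_ids=list(df.index),
        sample_ids=list(df.columns),
        values=values,
        flags=flags,
        scale_tag=scale_tag,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            flag_path: str | Path | None = None) -> None:
    """Write values (full ``repr`` precision, lossless round-trip) and,
    optionally, the flags."""
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.17g")  # lossless round-trip
    if flag_path is not None:
        fdf = pd.DataFrame(matrix.effective_flags(), index=matrix.probe_ids,
                           columns=matrix.sample_ids)
        fdf.index.name = "probe_id"
        fdf.to_csv(flag_path, sep="\t")


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Paired two-condition design: each patient contributes exactly one
    control and one treated sample."""

    frame: pd.DataFrame  # columns: sample_id, patient_id, condition

    def __post_init__(self) -> None:
        required = ["sample_id", "patient_id", "condition"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise FormatError(f"design missing columns {missing}")
        self.frame = self.frame[required].astype(str).reset_index(drop=True)
        if self.frame["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in design")
        bad = ~self.frame["condition"].isin(VALID_CONDITIONS)
        if bad.any():
            raise FormatError(
                f"unknown condition {self.frame.loc[bad, 'condition'].iloc[0]!r}"
            )
        counts = self.frame.groupby(["patient_id", "condition"]).size()
        if (counts != 1).any():
            pat, cond = counts[counts != 1].index[0]
            raise FormatError(
                f"patient {pat!r} has {counts[(pat, cond)]} samples in "
                f"condition {cond!r}; paired design requires exactly one"
            )
        per_patient = self.frame.groupby("patient_id")["condition"].nunique()
        if (per_patient != 2).any():
            pat = per_patient[per_patient != 2].index[0]
            raise FormatError(f"patient {pat!r} is missing one condition")

    @property
    def patients(self) -> list[str]:
        return sorted(self.frame["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def samples_for(self, condition: str) -> dict[str, str]:
        """patient_id -> sample_id for one condition."""
        sub = self.frame[self.frame["condition"] == condition]
        return dict(zip(sub["patient_id"], sub["sample_id"]))

    def condition_of(self, sample_id: str) -> str:
        sub = self.frame[self.frame["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(sample_id)
        return sub["condition"].iloc[0]

    def check_matrix(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.frame["sample_id"]) - set(matrix.sample_ids)
        if missing:
            raise FormatError(
                f"design samples absent from matrix: {sorted(missing)}"
            )


def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "probe_id", "transcript_type", "gene_symbol",
    "chromosome", "start", "end", "strand",
]


@dataclass
class ProbeAnnotation:
    """Probe -> transcript type / gene symbol / genomic interval records.

    Coordinates are 1-based inclusive on a single assembly.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"annotation missing columns {missing}")
        df = self.frame[ANNOTATION_COLUMNS].copy().reset_index(drop=True)
        for col in ("probe_id", "transcript_type", "gene_symbol", "chromosome",
                    "strand"):
            df[col] = df[col].astype(str)
        df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
        df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r} in annotation")
        bad = ~df["transcript_type"].isin(VALID_TRANSCRIPT_TYPES)
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"probe {row['probe_id']!r}: unknown transcript_type "
                f"{row['transcript_type']!r}"
            )
        bad = ~df["strand"].isin(VALID_STRANDS)
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"probe {row['probe_id']!r}: unknown strand {row['strand']!r}"
            )
        if (df["chromosome"].str.len() == 0).any():
            raise FormatError("empty chromosome label")
        bad = df["start"] > df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"probe {row['probe_id']!r}: start {row['start']} > end {row['end']}"
            )
        self.frame = df
        self._by_probe = df.set_index("probe_id", drop=False)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_probe.index

    def record(self, probe_id: str) -> pd.Series:
        return self._by_probe.loc[probe_id]

    def probes_of_type(self, transcript_type: str) -> list[str]:
        sub = self.frame[self.frame["transcript_type"] == transcript_type]
        return list(sub["probe_id"])

    def symbol_of(self, probe_id: str) -> str:
        return str(self._by_probe.at[probe_id, "gene_symbol"])

    def span_length(self, probe_id: str) -> int:
        rec = self.record(probe_id)
        return int(rec["end"] - rec["start"] + 1)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]  # deduplicated, original order preserved


@dataclass
class GeneSetCollection:
    """Ordered named gene sets; ``kind_tag`` distinguishes functional
    collections from TF target collections."""

    sets: list[GeneSet] = field(default_factory=list)
    kind_tag: str = "function"

    def __post_init__(self) -> None:
        if self.kind_tag not in ("function", "tf_targets"):
            raise FormatError(f"unknown kind_tag {self.kind_tag!r}")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise FormatError("duplicate set names in collection")
        for s in self.sets:
            seen: dict[str, None] = {}
            for m in s.members:
                seen.setdefault(m, None)
            s.members = list(seen)
            if not s.members:
                raise FormatError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def members_of(self, name: str) -> list[str]:
        for s in self.sets:
            if s.name == name:
                return list(s.members)
        raise KeyError(name)


def read_gmt(path: str | Path, kind_tag: str = "function") -> GeneSetCollection:
    """Read the standard GMT dialect: name TAB description TAB members..."""
    sets: list[GeneSet] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3"
                )
            members = [m for m in fields[2:] if m]
            sets.append(GeneSet(name=fields[0], description=fields[1],
                                members=members))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets=sets, kind_tag=kind_tag)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

VALID_NODE_TYPES = frozenset({"lncRNA", "TF", "gene"})


@dataclass
class NetworkGraph:
    """Typed, scored graph for export: nodes ``(id, node_type)``, edges
    ``(source, target, relation, score)``."""

    nodes: list[tuple[str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n for n, _ in self.nodes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate node ids in graph")
        for _, t in self.nodes:
            if t not in VALID_NODE_TYPES:
                raise FormatError(f"unknown node_type {t!r}")
        idset = set(ids)
        seen = set()
        for s, t, rel, _score in self.edges:
            if s == t:
                raise FormatError(f"self-edge on node {s!r}")
            if s not in idset or t not in idset:
                raise FormatError(f"edge ({s!r}, {t!r}) references unknown node")
            key = (s, t, rel)
            if key in seen:
                raise FormatError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_type(self, node_id: str) -> str:
        for n, t in self.nodes:
            if n == node_id:
                return t
        raise KeyError(node_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n, t in self.nodes:
            g.add_node(n, node_type=t)
        for s, t, rel, score in self.edges:
            g.add_edge(s, t, relation=rel, score=float(score))
        return g


def write_network(graph: NetworkGraph, path: str | Path, format: str = "SIF") -> None:
    """Export to SIF (edge list only) or GraphML (node types + edge scores)."""
    path = Path(path)
    if format == "SIF":
        with open(path, "w") as fh:
            for s, t, rel, _score in graph.edges:
                fh.write(f"{s}\t{rel}\t{t}\n")
    elif format == "GraphML":
        nx.write_graphml(graph.to_networkx(), path, named_key_ids=True)
    else:
        raise FormatError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> NetworkGraph:
    g = nx.read_graphml(path)
    nodes = [(str(n), str(d.get("node_type", "gene"))) for n, d in g.nodes(data=True)]
    edges = [
        (str(s), str(t), str(d.get("relation", "")), float(d.get("score", 0.0)))
        for s, t, d in g.edges(data=True)
    ]
    return NetworkGraph(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated result table with the frame's documented column order."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
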