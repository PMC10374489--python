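"""Shared data model and readers/writers for every pipeline step.

Canonical on-disk formats are plain TSV: expression matrices (genes x
samples), two-column sample annotations, edge lists, labeled square distance
matrices, drug libraries and Pareto fronts.  GraphML is supported read-only
for networks.  All writers accept a list of comment lines (written with a
leading ``#``) so each output can carry its resolved run configuration; all
readers skip ``#`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("dream.dataio")

CONDITION_LABELS = ("disease", "control")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with a two-condition design.

    Values are assumed to be already normalized (log scale for sequencing or
    array data); no normalization is applied here.  ``condition`` holds one
    label per sample, drawn from ``{"disease", "control"}``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.condition) != len(self.sample_ids):
            raise ValueError("one condition label per sample required")
        labels = set(self.condition)
        if labels != set(CONDITION_LABELS):
            raise ValueError(
                f"condition labels must be exactly {set(CONDITION_LABELS)}, got {labels}"
            )
        for lab in CONDITION_LABELS:
            if self.condition.count(lab) < 2:
                raise ValueError(f"need at least 2 samples in condition {lab!r}")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condition_mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.condition], dtype=bool)

    def condition_values(self, label: str) -> np.ndarray:
        """Sub-matrix (genes x samples) restricted to one condition."""
        return self.values[:, self.condition_mask(label)]

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Dataset restricted to ``genes``, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionDataset(
            list(genes), list(self.sample_ids), self.values[rows], list(self.condition)
        )


class GeneNetwork:
    """Undirected gene network with edge weights in [0, 1].

    Self-loops are dropped on construction (with a logged count); duplicate
    edges keep the maximum weight.  Unweighted edges get weight 1.0.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
        rescale: bool = False,
    ) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        raw: list[tuple[str, str, float]] = []
        for e in edges:
            a, b = str(e[0]), str(e[1])
            w = float(e[2]) if len(e) > 2 else 1.0
            if a == b:
                n_loops += 1
                continue
            raw.append((a, b, w))
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        if raw:
            weights = np.array([w for _, _, w in raw])
            if weights.min() < 0 or weights.max() > 1:
                if not rescale:
                    raise ValueError(
                        f"edge weights outside [0, 1] (range "
                        f"[{weights.min():g}, {weights.max():g}]); "
                        "pass rescale=True to min-max rescale"
                    )
                lo, hi = weights.min(), weights.max()
                span = hi - lo if hi > lo else 1.0
                raw = [(a, b, (w - lo) / span) for (a, b, _), w in zip(raw, weights)]
        for a, b, w in raw:
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (a, b, weight) with a < b, sorted lexicographically."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, float(data.get("weight", 1.0))))
        return sorted(out)

    def weight(self, a: str, b: str) -> float:
        return float(self.graph[a][b].get("weight", 1.0))

    def adjacency(self, nodelist: Sequence[str] | None = None) -> np.ndarray:
        """Weighted adjacency over ``nodelist``; absent nodes become isolated."""
        nodelist = list(nodelist) if nodelist is not None else self.nodes
        g = self.graph
        missing = [n for n in nodelist if n not in g]
        if missing:
            g = g.copy()
            g.add_nodes_from(missing)
        return nx.to_numpy_array(g, nodelist=nodelist, weight="weight")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()


@dataclass
class DrugRecord:
    """A drug: identifier, optional SMILES, target genes, optional MOA network.

    The perturbational network (inferred from post-treatment expression
    profiles) represents the drug's mechanism of action and feeds the HIM
    distance; targets feed the disease-network topology metrics.
    """

    drug_id: str
    smiles: str | None = None
    targets: set[str] = field(default_factory=set)
    perturbational_network: GeneNetwork | None = None


class DistanceMatrix:
    """Symmetric labeled matrix of pairwise drug distances or similarities.

    Labels are stored in canonical (lexicographic) order so that equal
    matrices have equal representations regardless of input order.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.shape != (len(labels), len(labels)):
            raise ValueError("values must be square and match labels")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        if not np.allclose(values, values.T, atol=1e-9, rtol=0.0):
            raise ValueError("matrix is not symmetric")
        order = np.argsort(np.array(labels, dtype=object))
        self.labels: list[str] = [labels[i] for i in order]
        self.values: np.ndarray = values[np.ix_(order, order)]
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self._index[lab] for lab in labels]
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)


class FrontEntry(NamedTuple):
    """One Pareto-front row as written to / read from disk."""

    subset: tuple[str, ...]
    objectives: tuple[float, ...]
    rank: int
    crowding: float


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _write_header(fh, header_lines: Sequence[str] | None) -> None:
    for line in header_lines or ():
        fh.write(f"# {line}\n")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, annotation_path: str | Path) -> ExpressionDataset:
    """Load an expression matrix plus its sample-condition annotation.

    The matrix file has a header row of sample ids and gene symbols in the
    first column.  The annotation is a two-column table mapping sample id to
    condition ("disease" / "control").  Rows with missing values are dropped;
    duplicate gene symbols collapse to the highest-variance row (both with
    logged counts).
    """
    path, annotation_path = Path(path), Path(annotation_path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#", float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    ann = pd.read_csv(annotation_path, sep=_sep_for(annotation_path), comment="#")
    if ann.shape[1] < 2:
        raise ValueError("annotation needs (sample, condition) columns")
    ann_map = dict(zip(ann.iloc[:, 0].astype(str), ann.iloc[:, 1].astype(str)))

    matrix_samples = list(df.columns)
    missing_in_ann = [s for s in matrix_samples if s not in ann_map]
    missing_in_mat = [s for s in ann_map if s not in set(matrix_samples)]
    if missing_in_ann or missing_in_mat:
        raise ValueError(
            "sample ids do not match between matrix and annotation: "
            f"absent from annotation {missing_in_ann}; absent from matrix {missing_in_mat}"
        )

    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.warning("dropped %d gene row(s) with missing values", n_na)
        df = df.dropna(axis=0)

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene row(s), keeping max variance", n_dup)
        variances = df.var(axis=1, ddof=1)
        df = df.assign(_var=variances.values)
        df = df.sort_values("_var", ascending=False)
        df = df[~df.index.duplicated(keep="first")].drop(columns="_var")
        df = df.sort_index()

    condition = [ann_map[s] for s in df.columns]
    return ExpressionDataset(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        condition=condition,
    )


def write_expression(
    ds: ExpressionDataset,
    path: str | Path,
    annotation_path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    path, annotation_path = Path(path), Path(annotation_path)
    with open(path, "w") as fh:
        _write_header(fh, header_lines)
        fh.write("gene\t" + "\t".join(ds.sample_ids) + "\n")
        for g, row in zip(ds.gene_ids, ds.values):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    with open(annotation_path, "w") as fh:
        _write_header(fh, header_lines)
        fh.write("sample\tcondition\n")
        for s, c in zip(ds.sample_ids, ds.condition):
            fh.write(f"{s}\t{c}\n")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def read_network(path: str | Path, rescale: bool = False) -> GeneNetwork:
    """Read a network from an edge-list TSV or a GraphML file.

    Edge lists have 2 or 3 columns (node_a, node_b[, weight]); a header row is
    detected when the third field is not numeric.  Weights outside [0, 1] are
    a hard error unless ``rescale`` is set (min-max rescale then).
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        edges = [
            (str(a), str(b), float(d.get("weight", 1.0))) for a, b, d in g.edges(data=True)
        ]
        return GeneNetwork.from_edges(edges, nodes=[str(n) for n in g.nodes], rescale=rescale)

    edges = []
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if first:
                first = False
                if len(parts) >= 3:
                    try:
                        float(parts[2])
                    except ValueError:
                        continue  # header row
                elif parts[:2] == ["node_a", "node_b"]:
                    continue
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append(tuple(parts[:2]) if len(parts) == 2 else (parts[0], parts[1], float(parts[2])))
    return GeneNetwork.from_edges(edges, rescale=rescale)


def write_network(
    net: GeneNetwork, path: str | Path, header_lines: Sequence[str] | None = None
) -> None:
    with open(Path(path), "w") as fh:
        _write_header(fh, header_lines)
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{_fmt(w)}\n")


# ---------------------------------------------------------------------------
# Drug libraries
# ---------------------------------------------------------------------------


def read_drug_library(
    path: str | Path, network_dir: str | Path | None = None
) -> list[DrugRecord]:
    """Read a drug-library TSV: drug_id, smiles, targets[, network].

    Targets are semicolon-separated gene symbols.  A SMILES that does not
    parse keeps the record with ``smiles=None`` and logs a warning; a
    duplicate drug_id is a hard error.  When a ``network`` column names a
    file, the edge list is loaded relative to ``network_dir`` (default: the
    library's own directory).
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    base = Path(network_dir) if network_dir is not None else path.parent
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("drug_id", "smiles", "targets"):
        if required not in cols:
            raise ValueError(f"drug library missing column {required!r}")
    drugs: list[DrugRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        drug_id = str(row[cols["drug_id"]]).strip()
        if drug_id in seen:
            raise ValueError(f"duplicate drug_id {drug_id!r}")
        seen.add(drug_id)
        smiles = row[cols["smiles"]]
        smiles = None if pd.isna(smiles) or not str(smiles).strip() else str(smiles).strip()
        if smiles is not None and Chem.MolFromSmiles(smiles) is None:
            logger.warning("drug %s: unparseable SMILES %r, kept without structure", drug_id, smiles)
            smiles = None
        raw_targets = row[cols["targets"]]
        targets = (
            set()
            if pd.isna(raw_targets)
            else {t.strip() for t in str(raw_targets).split(";") if t.strip()}
        )
        net = None
        if "network" in cols and not pd.isna(row[cols["network"]]):
            net = read_network(base / str(row[cols["network"]]).strip())
        drugs.append(DrugRecord(drug_id, smiles, targets, net))
    return drugs


def write_drug_library(
    drugs: Sequence[DrugRecord],
    path: str | Path,
    network_dir: str | Path | None = None,
    header_lines: Sequence[str] | None = None,
) -> None:
    """Write a drug library; perturbational networks go to ``network_dir``."""
    path = Path(path)
    base = Path(network_dir) if network_dir is not None else path.parent
    with open(path, "w") as fh:
        _write_header(fh, header_lines)
        fh.write("drug_id\tsmiles\ttargets\tnetwork\n")
        for d in drugs:
            net_name = ""
            if d.perturbational_network is not None:
                net_name = f"{d.drug_id}_network.tsv"
                write_network(d.perturbational_network, base / net_name, header_lines)
            fh.write(
                f"{d.drug_id}\t{d.smiles or ''}\t{';'.join(sorted(d.targets))}\t{net_name}\n"
            )


# ---------------------------------------------------------------------------
# Matrices and Pareto fronts
# ---------------------------------------------------------------------------


def write_matrix(
    m: DistanceMatrix, path: str | Path, header_lines: Sequence[str] | None = None
) -> None:
    """Write a labeled symmetric matrix as TSV (lexicographic label order)."""
    with open(Path(path), "w") as fh:
        _write_header(fh, header_lines)
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for lab, row in zip(m.labels, m.values):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, comment="#", float_precision="round_trip")
    return DistanceMatrix([str(x) for x in df.index], df.to_numpy(dtype=float))


def write_front(
    solutions: Sequence, path: str | Path, header_lines: Sequence[str] | None = None
) -> None:
    """Write Pareto solutions: subset, five objectives, rank, crowding."""
    with open(Path(path), "w") as fh:
        _write_header(fh, header_lines)
        fh.write(
            "size\tdrugs\tf1_size\tf2_moa\tf3_structure\tf4_coverage\t"
            "f5_target_dist\trank\tcrowding\n"
        )
        for s in solutions:
            subset = tuple(s.subset)
            obj = tuple(s.objectives)
            fh.write(
                f"{len(subset)}\t{';'.join(subset)}\t"
                + "\t".join(_fmt(v) for v in obj)
                + f"\t{int(s.rank)}\t{_fmt(s.crowding)}\n"
            )


def read_front(path: str | Path) -> list[FrontEntry]:
    df = pd.read_csv(Path(path), sep="\t", comment="#", float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        out.append(
            FrontEntry(
                subset=tuple(str(row["drugs"]).split(";")),
                objectives=tuple(
                    float(row[c])
                    for c in ("f1_size", "f2_moa", "f3_structure", "f4_coverage", "f5_target_dist")
                ),
                rank=int(row["rank"]),
                crowding=float(row["crowding"]),
            )
        )
    return out
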