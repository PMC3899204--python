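"""Reading and writing networks, gene tables, scores and curves.

Formats
-------
Edge lists are tab-separated with two columns per line (``#`` starts a
comment); SIF lines are ``source<TAB>relation<TAB>target [target ...]``
(whitespace-separated also accepted, as Cytoscape writes it). Gene tables
are TSV with a header of ``family``, ``gene`` and ``role`` columns, where
role is ``disease`` or ``candidate``. Identifiers are opaque, case-sensitive
strings; no symbol mapping is performed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .catalog import IsomerCatalog
from .network import InteractionNetwork
from .scoring import DiseaseFamily, ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "write_network",
    "merge_networks",
    "largest_component",
    "read_gene_table",
    "write_gene_table",
    "families_from_table",
    "read_weights",
    "write_weights",
    "write_scores",
    "write_curve",
    "write_catalog",
]

_ROLES = {"disease", "candidate"}


class FormatError(ValueError):
    """Malformed input file."""


def _iter_data_lines(path: Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line


def read_network(path: str | Path, fmt: str | None = None) -> InteractionNetwork:
    """Read an undirected simple network from a TSV edge list or SIF file.

    ``fmt`` is ``"tsv"`` or ``"sif"``; by default it is inferred from the
    file extension (``.sif`` means SIF, anything else a 2-column edge list).
    Self-loops and duplicate edges are dropped with a logged count.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {fmt!r}")
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if fmt == "tsv":
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}")
            edges.append((fields[0], fields[1]))
        else:  # sif
            if len(fields) == 1:
                nodes.append(fields[0])  # isolated node, legal SIF
            elif len(fields) >= 3:
                src = fields[0]
                edges.extend((src, tgt) for tgt in fields[2:])
            else:
                raise FormatError(
                    f"{path}:{lineno}: SIF line needs 1 or >=3 columns, "
                    f"got {len(fields)}")
    if not edges and not nodes:
        raise FormatError(f"{path}: no edges found")
    return InteractionNetwork(edges, nodes)


def write_network(path: str | Path, net: InteractionNetwork) -> None:
    """Write a network as a sorted 2-column TSV edge list."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}\t{v}\n")
        isolated = sorted(g for g in net.nodes if net.degree(g) == 0)
        for g in isolated:
            logger.warning("isolated node %r cannot be represented in an "
                           "edge list and was dropped on write", g)


def merge_networks(nets: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of node and edge sets of one or more networks."""
    if not nets:
        raise ValueError("need at least one network to merge")
    g = nx.Graph()
    for net in nets:
        g.update(net.graph)
    return InteractionNetwork.from_networkx(g)


def largest_component(net: InteractionNetwork) -> InteractionNetwork:
    """Subgraph induced on the largest connected component.

    Ties in size are broken by the component containing the
    lexicographically smallest node identifier.
    """
    if len(net) == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(net.graph),
                   key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    return InteractionNetwork.from_networkx(net.graph.subgraph(keep))


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a disease/candidate gene table (TSV: family, gene, role).

    Duplicate rows are dropped with a warning; an unknown role token or a
    missing column is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("family", "gene", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df[["family", "gene", "role"]]
    if df["gene"].isna().any() or (df["gene"] == "").any():
        raise FormatError(f"{path}: empty gene identifier")
    bad = set(df["role"]) - _ROLES
    if bad:
        raise FormatError(
            f"{path}: unknown role token(s) {sorted(bad)}; "
            f"expected one of {sorted(_ROLES)}")
    n_before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < n_before:
        logger.warning("%s: dropped %d duplicate row(s)",
                       path, n_before - len(df))
    return df


def write_gene_table(path: str | Path,
                     families: Iterable[DiseaseFamily]) -> None:
    rows = []
    for fam in families:
        rows += [(fam.family_id, g, "disease")
                 for g in sorted(fam.known_genes)]
        rows += [(fam.family_id, g, "candidate")
                 for g in sorted(fam.candidates - fam.known_genes)]
    pd.DataFrame(rows, columns=["family", "gene", "role"]).to_csv(
        path, sep="\t", index=False)


def families_from_table(df: pd.DataFrame,
                        net: InteractionNetwork | None = None
                        ) -> list[DiseaseFamily]:
    """Group a gene table into disease families.

    The candidate set of a family includes its disease genes (they trivially
    lie in the disease loci). If a network is given, genes absent from it
    are reported in the log but retained; downstream operations skip them.
    """
    families = []
    for fam_id, grp in df.groupby("family", sort=True):
        disease = frozenset(grp.loc[grp["role"] == "disease", "gene"])
        candidate = frozenset(grp.loc[grp["role"] == "candidate", "gene"])
        families.append(DiseaseFamily(str(fam_id), disease,
                                      candidate | disease))
        if net is not None:
            missing = sorted((disease | candidate) - net.nodes)
            if missing:
                logger.info("family %r: %d gene(s) not in the network: %s",
                            fam_id, len(missing), ", ".join(missing[:10]))
    return families


def read_weights(path: str | Path) -> pd.Series:
    """Read an isomer-weight TSV (columns: isomer, weight) into a Series
    indexed I1..I28 order."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"weight": float})
    for col in ("isomer", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    s = pd.Series(df["weight"].values, index=df["isomer"].astype(str).values)
    return s


def write_weights(path: str | Path, weights, isomers: Sequence[int]) -> None:
    pd.DataFrame({
        "isomer": [f"I{k}" for k in isomers],
        "weight": list(weights),
    }).to_csv(path, sep="\t", index=False)


def write_feature_matrix(path: str | Path, fm) -> None:
    """Write a regression design as TSV with isomer-named columns."""
    df = pd.DataFrame(fm.X, columns=[f"I{k}" for k in fm.isomers])
    df.insert(0, "family", [r[0] for r in fm.rows])
    df.insert(1, "gene", [r[1] for r in fm.rows])
    df["label"] = fm.labels.astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_scores(path: str | Path, table: ScoreTable) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_curve(path: str | Path, curve) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def write_catalog(path: str | Path, catalog: IsomerCatalog) -> None:
    """Serialize the isomer catalog as a documented TSV."""
    pd.DataFrame(catalog.to_table()).to_csv(path, sep="\t", index=False)
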