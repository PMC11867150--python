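"""Readers and writers for on-disk formats.

Formats handled:

* FASTA alignments (via Biopython) paired with an abundance TSV
  (``sequence_id <tab> count``);
* histories as a newick topology (internal nodes named) plus a FASTA mapping
  node names to sequences;
* the ancestral-sequence tables of a PHYLIP ``dnapars`` outfile;
* mutability model CSVs (``fivemer,rate,A,C,G,T``);
* a JSON schema for history DAGs (label table, node table with clades as
  sorted label-index lists, edge list), optionally gzip-compressed.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from pathlib import Path
from typing import Mapping, Optional

import dendropy
from Bio import SeqIO

from .sdag import Clade, History, HistoryNode, HistorySDAG, history_from_tree

logger = logging.getLogger("phylodag")


# ---------------------------------------------------------------------------
# FASTA + abundances


def read_fasta(path) -> dict[str, str]:
    """id -> uppercased sequence; rejects duplicate ids."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("uppercasing sequence %s", rec.id)
            seq = seq.upper()
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n{seq}\n")


def read_abundances(path) -> dict[str, int]:
    """sequence_id -> count from a two-column TSV."""
    out: dict[str, int] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            name, count = fields
            if name in out:
                raise ValueError(f"duplicate id {name!r} in abundance file")
            out[name] = int(count)
    return out


def read_alignment_with_abundances(
    fasta_path, tsv_path=None
) -> tuple[dict[str, str], dict[str, int]]:
    """Deduplicated genotypes with summed counts.

    Returns (id -> sequence for one representative id per distinct sequence,
    sequence -> summed abundance).  A missing TSV assigns every record a
    count of 1.
    """
    records = read_fasta(fasta_path)
    lengths = {len(s) for s in records.values()}
    if len(lengths) > 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    for name, seq in records.items():
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"record {name!r} has non-ACGT characters {sorted(bad)}")
    if tsv_path is None:
        counts = {name: 1 for name in records}
    else:
        counts = read_abundances(tsv_path)
        unknown = set(counts) - set(records)
        if unknown:
            raise ValueError(f"abundance ids missing from FASTA: {sorted(unknown)[:3]}")
        for name in set(records) - set(counts):
            counts[name] = 1

    genotypes: dict[str, str] = {}
    abundances: dict[str, int] = {}
    for name, seq in records.items():
        if seq not in abundances:
            genotypes[name] = seq
            abundances[seq] = 0
        abundances[seq] += counts[name]
    return genotypes, abundances


# ---------------------------------------------------------------------------
# Histories as newick + FASTA


def read_history(newick_path, fasta_path) -> History:
    """Parse a named-node newick plus a FASTA of node sequences."""
    sequences = read_fasta(fasta_path)
    tree = dendropy.Tree.get(
        path=str(newick_path),
        schema="newick",
        suppress_internal_node_taxa=False,
    )

    def name_of(node) -> str:
        label = node.taxon.label if node.taxon else node.label
        if not label:
            raise ValueError("newick node without a name")
        return label.replace(" ", "_")

    def convert(node):
        name = name_of(node)
        if name not in sequences:
            raise ValueError(f"node name {name!r} missing from FASTA")
        if node.is_leaf():
            return sequences[name]
        return (sequences[name], [convert(c) for c in node.child_nodes()])

    return history_from_tree(convert(tree.seed_node))


def history_names(history: History, leaf_ids: Optional[Mapping[str, str]] = None):
    """Stable node -> name assignment for serialization."""
    names = {}
    leaf_counter = ancestor_counter = 0
    for node in history.nodes():
        if node.is_leaf():
            if leaf_ids and node.label in leaf_ids:
                names[node] = leaf_ids[node.label]
            else:
                leaf_counter += 1
                names[node] = f"seq{leaf_counter}"
        else:
            ancestor_counter += 1
            names[node] = f"anc{ancestor_counter}"
    return names


def write_history(
    history: History,
    newick_path,
    fasta_path,
    leaf_ids: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a history as named-node newick plus node-sequence FASTA.

    ``leaf_ids`` optionally maps leaf sequences to preferred names.
    """
    names = history_names(history, leaf_ids)

    def newick(node: HistoryNode) -> str:
        if node.is_leaf():
            return names[node]
        kids = ",".join(newick(c) for c in history.down[node].values())
        return f"({kids}){names[node]}"

    with open(newick_path, "w") as handle:
        handle.write(newick(history.root) + ";\n")
    write_fasta(fasta_path, {names[n]: n.label for n in history.nodes()})


# ---------------------------------------------------------------------------
# dnapars outfile


_STEPS_RE = re.compile(r"requires a total of")
_SEQ_CHARS = re.compile(r"^[ACGTURYSWKMBDHVN?.\- ]+$")


def parse_dnapars_outfile(path) -> list[History]:
    """Parse the ancestral-sequence tables of a dnapars ``outfile``.

    Each tree section (delimited by the ``requires a total of ... steps``
    lines) contains one or more ``From To Any Steps? State at upper node``
    tables whose rows give the tree's edges and chunks of each node's
    sequence; ``.`` means "same base as the parent node".  Returns one
    :class:`History` per tree, with node labels taken from the assembled
    sequences (ancestral ambiguity codes preserved).
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty dnapars outfile: {path}")
    sections = []
    current: Optional[list] = None
    for line in text.splitlines():
        if _STEPS_RE.search(line):
            if current is not None:
                sections.append(current)
            current = []
        elif current is not None:
            current.append(line)
    if current is not None:
        sections.append(current)
    if not sections:
        raise ValueError(f"no tree sections found in dnapars outfile {path}")

    histories = []
    for section in sections:
        histories.append(_parse_dnapars_section(section))
    return histories


def _parse_dnapars_section(lines: list) -> History:
    edges: list[tuple[Optional[str], str]] = []
    chunks: dict[str, list[str]] = {}
    seen_edges = set()
    for raw in lines:
        line = raw.rstrip()
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) >= 4 and tokens[2].lower() in ("yes", "no", "maybe"):
            parent, child = tokens[0], tokens[1]
            seq = "".join(tokens[3:])
        elif len(tokens) >= 2 and all(_SEQ_CHARS.match(t) for t in tokens[1:]):
            parent, child = None, tokens[0]
            seq = "".join(tokens[1:])
        else:
            continue  # header / prose line
        if not _SEQ_CHARS.match(seq):
            continue
        key = (parent, child)
        if key not in seen_edges:
            seen_edges.add(key)
            edges.append(key)
        chunks.setdefault(child, []).append(seq)

    if not edges:
        raise ValueError("malformed dnapars section: no sequence table rows")
    sequences = {node: "".join(parts) for node, parts in chunks.items()}
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent sequence lengths in dnapars section: {lengths}")

    children: dict[str, list[str]] = {}
    root = None
    parent_of: dict[str, str] = {}
    for parent, child in edges:
        if parent is None:
            if root is not None and root != child:
                raise ValueError("multiple roots in dnapars section")
            root = child
        else:
            children.setdefault(parent, []).append(child)
            parent_of[child] = parent
    if root is None:
        raise ValueError("dnapars section has no root row")

    # resolve "." inheritance top-down
    resolved: dict[str, str] = {}

    def resolve(node: str) -> str:
        if node in resolved:
            return resolved[node]
        seq = sequences[node]
        if node in parent_of:
            parent_seq = resolve(parent_of[node])
            seq = "".join(
                p if ch == "." else ch for ch, p in zip(seq, parent_seq)
            )
        if "." in seq:
            raise ValueError(f"unresolvable '.' in root sequence of node {node}")
        resolved[node] = seq
        return seq

    for node in sequences:
        resolve(node)

    def convert(node: str):
        kids = children.get(node)
        if not kids:
            return resolved[node]
        return (resolved[node], [convert(k) for k in kids])

    return history_from_tree(convert(root))


# ---------------------------------------------------------------------------
# DAG JSON serialization

DAG_SCHEMA_VERSION = 1


def dag_to_json(dag: HistorySDAG) -> dict:
    """Serialize to the documented JSON schema (version 1)."""
    labels = sorted({v.label for v in dag.children})
    label_index = {lab: i for i, lab in enumerate(labels)}

    def clade_ids(clade: Clade) -> list:
        return sorted(label_index[lab] for lab in clade)

    nodes = sorted(
        dag.children,
        key=lambda v: (label_index[v.label], sorted(map(tuple, map(sorted, v.clades)))),
    )
    node_index = {v: i for i, v in enumerate(nodes)}
    node_table = [
        {
            "label": label_index[v.label],
            "clades": sorted(clade_ids(c) for c in v.clades),
        }
        for v in nodes
    ]
    edge_list = sorted(
        (node_index[p], node_index[c])
        for p, clades in dag.children.items()
        for kids in clades.values()
        for c in kids
    )
    return {
        "version": DAG_SCHEMA_VERSION,
        "labels": labels,
        "nodes": node_table,
        "edges": edge_list,
        "ua_children": sorted(node_index[c] for c in dag.ua_children),
    }


def dag_from_json(data: dict) -> HistorySDAG:
    if data.get("version") != DAG_SCHEMA_VERSION:
        raise ValueError(f"unsupported DAG schema version {data.get('version')!r}")
    labels = data["labels"]
    nodes = [
        HistoryNode(
            labels[entry["label"]],
            frozenset(frozenset(labels[i] for i in clade) for clade in entry["clades"]),
        )
        for entry in data["nodes"]
    ]
    dag = HistorySDAG()
    for v in nodes:
        dag._ensure_node(v)
    for p, c in data["edges"]:
        dag.add_edge(nodes[p], nodes[c])
    for c in data["ua_children"]:
        dag.ua_children.add(nodes[c])
    return dag


def write_dag(dag: HistorySDAG, path) -> None:
    path = Path(path)
    payload = json.dumps(dag_to_json(dag), separators=(",", ":"))
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as handle:
            handle.write(payload)
    else:
        path.write_text(payload)


def read_dag(path) -> HistorySDAG:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            data = json.load(handle)
    else:
        data = json.loads(path.read_text())
    return dag_from_json(data)
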