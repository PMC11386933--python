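"""Readers and writers for every external format the pipeline touches.

Count matrices and the two-column sample→group file are plain TSV; gene sets
use the GMT dialect (term TAB description TAB member...); sequences travel as
FASTA via Biopython; networks export as Cytoscape SIF or an annotated TSV.
The three differential-expression tables printed by the source study are
packaged as TSV fixtures and exposed through :func:`load_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

RNA_CLASSES = ("circRNA", "miRNA", "mRNA")
GROUPS = ("control", "treated")


@dataclass
class CountMatrix:
    """Integer counts for one RNA class across samples with group labels."""

    feature_ids: list[str]
    rna_class: str
    sample_ids: list[str]
    group_of: dict[str, str]
    counts: np.ndarray  # features x samples, non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(f"unknown rna_class {self.rna_class!r}")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"count grid {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids in count matrix")
        if np.any(self.counts < 0):
            raise FormatError("negative counts in matrix")
        for s in self.sample_ids:
            if s not in self.group_of:
                raise FormatError(f"sample {s!r} missing from group assignment")
            if self.group_of[s] not in GROUPS:
                raise FormatError(f"sample {s!r} has unknown group {self.group_of[s]!r}")
        for g in GROUPS:
            if sum(1 for s in self.sample_ids if self.group_of[s] == g) < 2:
                raise FormatError(f"fewer than 2 samples in group {g!r}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group]
        return self.counts[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets over an identifier universe."""

    sets: list[tuple[str, str, list[str]]]  # (term id, name, members)
    universe: list[str] = field(default_factory=list)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping emptied sets."""
        uni = list(dict.fromkeys(universe))
        uset = set(uni)
        kept = []
        for term, name, members in self.sets:
            inter = [m for m in members if m in uset]
            if inter:
                kept.append((term, name, inter))
        return GeneSetCollection(sets=kept, universe=uni)

    def as_dict(self) -> dict[str, list[str]]:
        return {term: members for term, _, members in self.sets}


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: str | Path, group_path: str | Path, rna_class: str) -> CountMatrix:
    """Parse a features x samples TSV plus a two-column sample→group TSV.

    Raises :class:`FormatError` with a line number on ragged rows, negative
    or non-integer counts, or samples missing from the group file.
    """
    path, group_path = Path(path), Path(group_path)
    group_of: dict[str, str] = {}
    for lineno, line in enumerate(group_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{group_path}:{lineno}: expected 2 columns, got {len(parts)}")
        if parts[0] == "sample" and parts[1] == "group":
            continue  # optional header
        group_of[parts[0]] = parts[1]

    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}:1: empty file")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}:1: header has no sample columns")
    for s in sample_ids:
        if s not in group_of:
            raise FormatError(f"{path}:1: sample {s!r} missing from group file")

    feature_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        feature_ids.append(parts[0])
        row = []
        for col, cell in enumerate(parts[1:], start=2):
            try:
                value = int(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: column {col}: non-integer count {cell!r}"
                ) from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: column {col}: negative count {value}")
            row.append(value)
        rows.append(row)
    counts = np.array(rows, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    return CountMatrix(
        feature_ids=feature_ids,
        rna_class=rna_class,
        sample_ids=sample_ids,
        group_of={s: group_of[s] for s in sample_ids},
        counts=counts,
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path, group_path: str | Path) -> None:
    path, group_path = Path(path), Path(group_path)
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")
    with open(group_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.group_of[s]}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a line are deduplicated."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(parts)}")
        term, name, members = parts[0], parts[1], list(dict.fromkeys(parts[2:]))
        sets.append((term, name, members))
    universe = list(dict.fromkeys(m for _, _, ms in sets for m in ms))
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, name, members in collection.sets:
            fh.write("\t".join([term, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# packaged fixture tables

_FIXTURE_FILES = {
    "circ_table": "circ_table.tsv",
    "mirna_table": "mirna_table.tsv",
    "mrna_table": "mrna_table.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged differential-expression tables.

    ``circ_table`` / ``mirna_table`` / ``mrna_table`` each hold exactly 30
    rows with columns id, log2fc, pvalue, regulation (plus circbase_id or
    symbol where the printed table has one). Missing text cells ("-") parse
    to None. Rows are keyed by position: the circRNA table legitimately
    repeats a parent-gene id for two distinct circRNAs.
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    ref = resources.files("cernet.data").joinpath(_FIXTURE_FILES[name])
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"id": str})
    for col in ("circbase_id", "symbol"):
        if col in df.columns:
            df[col] = df[col].where(df[col] != "-", other=pd.NA)
    # transcription sanity: printed Regulation always matches the FC sign
    assert ((df["log2fc"] > 0) == (df["regulation"] == "UP")).all()
    return df


# ---------------------------------------------------------------------------
# network export

_EDGE_KINDS = ("circ_mir", "mir_mrna")


def write_network(network, path: str | Path, dialect: str = "tsv") -> None:
    """Write a ceRNA network as SIF (source TAB interaction TAB target) or
    as an annotated TSV with the supporting correlation statistics."""
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges = sorted(network.edges(data=True), key=lambda e: (e[2].get("etype", ""), e[0], e[1]))
    with open(path, "w") as fh:
        if dialect == "sif":
            for u, v, data in edges:
                fh.write(f"{u}\t{data.get('etype', 'edge')}\t{v}\n")
        else:
            fh.write("source\tinteraction\ttarget\tscc\tpcc\tpvalue\n")
            for u, v, data in edges:
                fh.write(
                    "\t".join(
                        [
                            u,
                            data.get("etype", "edge"),
                            v,
                            _fmt(data.get("scc")),
                            _fmt(data.get("pcc")),
                            _fmt(data.get("pvalue")),
                        ]
                    )
                    + "\n"
                )


def read_network_tsv(path: str | Path):
    """Read an annotated TSV network back into a networkx graph."""
    import networkx as nx

    net = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        u, etype, v, scc, pcc, p = parts
        net.add_edge(
            u,
            v,
            etype=etype,
            scc=_parse_opt(scc),
            pcc=_parse_opt(pcc),
            pvalue=_parse_opt(p),
        )
    return net


def _fmt(x) -> str:
    return "" if x is None else f"{x:.10g}"


def _parse_opt(cell: str):
    return None if cell == "" else float(cell)


# ---------------------------------------------------------------------------
# JSON helpers (truth / config round-trips)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
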