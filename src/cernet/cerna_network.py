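"""Three-filter ceRNA network construction and focal sub-network extraction.

Working over differentially expressed features only, with expression taken
as log2(normalized + 0.5) across all samples pooled:

1. circRNA–miRNA and mRNA–miRNA pairs are kept when they are predicted
   target pairs AND their Spearman correlation is below −scc_threshold
   (default 0.7) — the negative coexpression a sponge implies;
2. circRNA–mRNA pairs are kept when their Pearson correlation exceeds
   pcc_threshold (default 0.9, strict) and the two share at least one
   miRNA among the retained sponge pairs;
3. each surviving circRNA–mRNA pair is tested for sharing more miRNA
   regulators than chance with a hypergeometric upper-tail test over the
   miRNA universe (DE miRNAs with at least one predicted target); pairs
   need p < 0.05.

A triplet (circRNA, miRNA, mRNA) is accepted when all three filters hold;
the network is the union of accepted triplets' circ–miR and miR–mRNA edges,
each edge carrying its supporting statistics and triplet provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import PSEUDOCOUNT, normalize
from .enrichment import hypergeometric_p
from .errors import DomainError
from .io_formats import CountMatrix


@dataclass
class SpongeTestResult:
    circ_id: str
    mrna_id: str
    K: int  # miRNA universe size
    k1: int  # miRNAs targeting the circRNA
    k2: int  # miRNAs targeting the mRNA
    s: int  # shared
    pvalue: float


def spearman(x, y) -> float:
    """Spearman rank correlation; NaN sentinel when a rank variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("spearman needs equal-length vectors of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pearson(x, y) -> float:
    """Pearson product-moment correlation; NaN sentinel on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("pearson needs equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def expression_table(matrices: Iterable[CountMatrix], method: str = "cpm") -> dict[str, np.ndarray]:
    """Per-feature log2(normalized + 0.5) vectors across pooled samples."""
    table: dict[str, np.ndarray] = {}
    for matrix in matrices:
        log_norm = np.log2(normalize(matrix, method=method) + PSEUDOCOUNT)
        for i, fid in enumerate(matrix.feature_ids):
            table[fid] = log_norm[i]
    return table


def _pair_set(targets: pd.DataFrame) -> set[tuple[str, str]]:
    if targets.empty:
        return set()
    return set(zip(targets["mirna_id"], targets["target_id"]))


def select_sponge_pairs(
    de_circ: Iterable[str],
    de_mrna: Iterable[str],
    de_mir: Iterable[str],
    expression: Mapping[str, np.ndarray],
    targets: pd.DataFrame,
    scc_threshold: float = 0.7,
) -> pd.DataFrame:
    """Filter (1): anti-correlated predicted target pairs, both RNA kinds."""
    pairs = _pair_set(targets)
    rows = []
    for kind, a_ids in (("circ_mir", list(de_circ)), ("mrna_mir", list(de_mrna))):
        for a in a_ids:
            if a not in expression:
                raise DomainError(f"feature {a!r} missing from expression matrix")
            for m in de_mir:
                if (m, a) not in pairs:
                    continue
                if m not in expression:
                    raise DomainError(f"feature {m!r} missing from expression matrix")
                scc = spearman(expression[a], expression[m])
                if np.isnan(scc):
                    continue  # undefined correlation: drop the pair
                if scc < -scc_threshold:
                    rows.append(
                        {"a_id": a, "b_id": m, "kind": kind, "scc": scc,
                         "n_samples": len(expression[a])}
                    )
    return pd.DataFrame(rows, columns=["a_id", "b_id", "kind", "scc", "n_samples"])


def select_coexpressed(
    de_circ: Iterable[str],
    de_mrna: Iterable[str],
    expression: Mapping[str, np.ndarray],
    sponge_pairs: pd.DataFrame,
    pcc_threshold: float = 0.9,
) -> pd.DataFrame:
    """Filter (2): positively coexpressed circ–mRNA pairs sharing a miRNA."""
    circ_partners: dict[str, set[str]] = {}
    mrna_partners: dict[str, set[str]] = {}
    for _, row in sponge_pairs.iterrows():
        d = circ_partners if row["kind"] == "circ_mir" else mrna_partners
        d.setdefault(row["a_id"], set()).add(row["b_id"])
    rows = []
    for c in de_circ:
        mirs_c = circ_partners.get(c, set())
        if not mirs_c:
            continue
        for g in de_mrna:
            shared = mirs_c & mrna_partners.get(g, set())
            if not shared:
                continue
            if c not in expression or g not in expression:
                raise DomainError("feature missing from expression matrix")
            pcc = pearson(expression[c], expression[g])
            if np.isnan(pcc):
                continue
            if pcc > pcc_threshold:  # strict inequality per protocol
                rows.append(
                    {"a_id": c, "b_id": g, "kind": "circ_mrna", "pcc": pcc,
                     "shared_mirnas": ",".join(sorted(shared)),
                     "n_samples": len(expression[c])}
                )
    return pd.DataFrame(
        rows, columns=["a_id", "b_id", "kind", "pcc", "shared_mirnas", "n_samples"]
    )


def sponge_test(
    circ_id: str,
    mrna_id: str,
    mirna_universe: Iterable[str],
    targets: pd.DataFrame,
) -> SpongeTestResult:
    """Filter (3): hypergeometric test on the shared-regulator count."""
    universe = list(dict.fromkeys(mirna_universe))
    K = len(universe)
    if K < 1:
        raise DomainError("mirna universe must satisfy K >= 1")
    pairs = _pair_set(targets)
    uset = set(universe)
    mirs_circ = {m for (m, t) in pairs if t == circ_id and m in uset}
    mirs_mrna = {m for (m, t) in pairs if t == mrna_id and m in uset}
    k1, k2 = len(mirs_circ), len(mirs_mrna)
    s = len(mirs_circ & mirs_mrna)
    p = hypergeometric_p(N=K, n=k2, M=k1, m=s)
    return SpongeTestResult(circ_id=circ_id, mrna_id=mrna_id, K=K, k1=k1, k2=k2, s=s, pvalue=p)


def build_network(
    sponge_pairs: pd.DataFrame,
    coexpressed_pairs: pd.DataFrame,
    targets: pd.DataFrame,
    mirna_universe: Iterable[str],
    alpha: float = 0.05,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Assemble accepted triplets and their edge-union network."""
    universe = list(dict.fromkeys(mirna_universe))
    scc_of: dict[tuple[str, str], float] = {}
    circ_mirs: dict[str, set[str]] = {}
    mrna_mirs: dict[str, set[str]] = {}
    for _, row in sponge_pairs.iterrows():
        scc_of[(row["a_id"], row["b_id"])] = row["scc"]
        d = circ_mirs if row["kind"] == "circ_mir" else mrna_mirs
        d.setdefault(row["a_id"], set()).add(row["b_id"])

    triplet_rows = []
    sponge_cache: dict[tuple[str, str], SpongeTestResult] = {}
    for _, row in coexpressed_pairs.iterrows():
        c, g, pcc = row["a_id"], row["b_id"], row["pcc"]
        key = (c, g)
        if key not in sponge_cache:
            sponge_cache[key] = sponge_test(c, g, universe, targets)
        res = sponge_cache[key]
        if not res.pvalue < alpha:
            continue
        for m in sorted(circ_mirs.get(c, set()) & mrna_mirs.get(g, set())):
            triplet_rows.append(
                {
                    "circ_id": c,
                    "mirna_id": m,
                    "mrna_id": g,
                    "scc_circ_mir": scc_of[(c, m)],
                    "scc_mrna_mir": scc_of[(g, m)],
                    "pcc_circ_mrna": pcc,
                    "sponge_p": res.pvalue,
                }
            )
    triplets = pd.DataFrame(
        triplet_rows,
        columns=[
            "circ_id", "mirna_id", "mrna_id",
            "scc_circ_mir", "scc_mrna_mir", "pcc_circ_mrna", "sponge_p",
        ],
    )

    net = nx.Graph()
    for _, t in triplets.iterrows():
        trip = (t["circ_id"], t["mirna_id"], t["mrna_id"])
        net.add_node(t["circ_id"], kind="circRNA")
        net.add_node(t["mirna_id"], kind="miRNA")
        net.add_node(t["mrna_id"], kind="mRNA")
        for u, v, etype, scc in (
            (t["circ_id"], t["mirna_id"], "circ_mir", t["scc_circ_mir"]),
            (t["mirna_id"], t["mrna_id"], "mir_mrna", t["scc_mrna_mir"]),
        ):
            if net.has_edge(u, v):
                net[u][v]["triplets"].append(trip)
            else:
                net.add_edge(
                    u, v, etype=etype, scc=scc,
                    pcc=t["pcc_circ_mrna"], pvalue=t["sponge_p"], triplets=[trip],
                )
    return net, triplets


def extract_subnetwork(network: nx.Graph, focal_mrna_id: str) -> nx.Graph:
    """Induced sub-network of all triplets containing the focal mRNA.

    An absent focal id yields an empty network, not an error.
    """
    sub = nx.Graph()
    for u, v, data in network.edges(data=True):
        keep = [t for t in data.get("triplets", []) if t[2] == focal_mrna_id]
        if keep:
            for node in (u, v):
                sub.add_node(node, **network.nodes[node])
            sub.add_edge(u, v, **{**data, "triplets": keep})
    return sub
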