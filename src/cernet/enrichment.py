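"""Over-representation analysis via the hypergeometric upper tail.

For a universe of N annotated features, n of which are differentially
expressed, a term with M members and m DE members is scored with

    p = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)
      = P(X >= m),  X ~ Hypergeometric(N, M, n),

evaluated in log-space for stability, followed by BH-FDR across tested
terms. The same tail probability drives the ceRNA shared-sponge test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust
from .errors import DomainError
from .io_formats import GeneSetCollection


@dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    N: int
    n: int
    M: int
    m: int
    pvalue: float
    fdr: float
    overlap: tuple[str, ...] = ()


def _log_comb(a: int, b: np.ndarray | int) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


def hypergeometric_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail P(X >= m) for X ~ Hypergeometric(N, M, n).

    Impossible binomial terms contribute zero. Raises :class:`DomainError`
    naming the violated inequality for inconsistent arguments.
    """
    for label, ok in (
        ("N >= 0", N >= 0),
        ("0 <= M <= N", 0 <= M <= N),
        ("0 <= n <= N", 0 <= n <= N),
        ("0 <= m <= min(n, M)", 0 <= m <= min(n, M)),
    ):
        if not ok:
            raise DomainError(f"hypergeometric arguments violate {label}")
    if m == 0:
        return 1.0
    # sum the tail i = m .. min(n, M) directly (shorter and better conditioned
    # than 1 - CDF when the tail is tiny)
    i = np.arange(m, min(n, M) + 1)
    log_terms = _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich(
    de_ids,
    universe_ids,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    include_empty: bool = False,
) -> pd.DataFrame:
    """Hypergeometric ORA of *de_ids* against every set, BH-FDR corrected.

    Terms with no DE overlap are excluded from testing by default (they
    cannot be enriched and would inflate the BH denominator).
    """
    universe = list(dict.fromkeys(universe_ids))
    if not universe:
        raise DomainError("empty universe")
    uset = set(universe)
    de = [d for d in dict.fromkeys(de_ids)]
    if not de:
        raise DomainError("empty DE listing")
    if not set(de) <= uset:
        raise DomainError("de_ids must be a subset of universe_ids")
    restricted = sets.restrict(universe)
    de_set = set(de)
    N, n = len(universe), len(de)

    rows = []
    for term, name, members in restricted.sets:
        overlap = sorted(set(members) & de_set)
        M, m = len(set(members)), len(overlap)
        if m == 0 and not include_empty:
            continue
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "pvalue": hypergeometric_p(N, n, M, m),
                "overlap": ",".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "N", "n", "M", "m", "pvalue", "overlap"]
    )
    if len(df):
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
        df["significant"] = df["fdr"] < alpha
        df = df.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
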