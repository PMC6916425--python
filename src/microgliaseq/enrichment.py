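"""Hypergeometric overlap statistics and category enrichment.

The overlap between two gene lists drawn from a common universe is scored
with the upper tail of the hypergeometric distribution: with a universe of
N genes, a first list of K, a second of n and an observed overlap of k, the
p-value is P(X >= k) for X ~ Hypergeom(N, K, n), summed in log space for
numerical stability.  Fold enrichment is the observed overlap over its
expectation under independence, ``k * N / (K * n)``.  Category enrichment
runs the same test per annotation term, keeps only terms with at least
``min_size`` query genes (a reporting filter, not a statistical one) and
adjusts across the tested terms by Benjamini-Hochberg.

Only enrichment (the upper tail) is tested, never depletion.  The universe
is an explicit argument everywhere: fold enrichments are meaningless
without stating which N they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust
from .io import GeneSetCollection, get_logger

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "fold_enrichment",
    "overlap_enrichment",
    "category_enrichment",
]

log = get_logger("enrichment")


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate(N: int, K: int, n: int, k: int) -> None:
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValueError(f"list sizes K={K}, n={n} cannot exceed the universe N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} cannot exceed min(K, n)={min(K, n)}")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when n items are drawn without replacement from a
    universe of N containing K marked items.  The tail is summed in log
    space; the result lies in (0, 1] and equals 1 exactly when k = 0.
    """
    _validate(N, K, n, k)
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    if i.size == 0:
        return 0.0  # unreachable given validation; kept for safety
    logpmf = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Observed overlap over its expectation under independence: k*N/(K*n)."""
    _validate(N, K, n, k)
    if K == 0 or n == 0:
        raise ValueError("fold enrichment undefined for an empty list (K or n = 0)")
    return k * N / (K * n)


@dataclass
class EnrichmentResult:
    """Overlap statistics for two gene lists in a common universe."""

    N: int
    K: int
    n: int
    k: int
    fold: float
    p: float
    shared_percent: float
    q: float | None = None

    def as_dict(self) -> dict:
        return {
            "N": self.N, "K": self.K, "n": self.n, "k": self.k,
            "fold": self.fold, "p": self.p,
            "shared_percent": self.shared_percent, "q": self.q,
        }


def overlap_enrichment(list_a, list_b, universe) -> EnrichmentResult:
    """Hypergeometric enrichment of the overlap between two gene lists.

    Both lists are restricted to the universe first; members outside it are
    dropped with a logged count.  The shared percentage is 100*k/n, the
    fraction of the second list recovered in the first.
    """
    uni = set(str(g).strip() for g in universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(str(g).strip() for g in list_a)
    b = set(str(g).strip() for g in list_b)
    dropped = len(a - uni) + len(b - uni)
    if dropped:
        log.info("dropped %d gene(s) outside the universe", dropped)
    a &= uni
    b &= uni
    N, K, n, k = len(uni), len(a), len(b), len(a & b)
    p = hypergeom_tail(N, K, n, k)
    fold = fold_enrichment(N, K, n, k) if K and n else 0.0
    shared = 100.0 * k / n if n else 0.0
    return EnrichmentResult(N=N, K=K, n=n, k=k, fold=fold, p=p, shared_percent=shared)


def category_enrichment(
    gene_set,
    annotation: GeneSetCollection,
    universe,
    min_size: int = 10,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a query gene list.

    Term memberships are intersected with the universe; only terms holding
    at least ``min_size`` query genes are reported.  Returns a frame indexed
    by term_id with columns term_name, N, K, n, k, fold, p, q, sorted by p;
    q is Benjamini-Hochberg across the tested terms.  An empty result (no
    term passes the size filter) is a warning, not an error.
    """
    uni = set(str(g).strip() for g in universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(str(g).strip() for g in gene_set) & uni
    rows = []
    for term_id, (term_name, members) in annotation:
        term = set(members) & uni
        if not term:
            continue
        k = len(term & query)
        if k < min_size:
            continue
        N, K, n = len(uni), len(term), len(query)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "fold": fold_enrichment(N, K, n, k),
                "p": hypergeom_tail(N, K, n, k),
            }
        )
    if not rows:
        log.warning(
            "no annotation term holds >= %d query genes; empty enrichment table",
            min_size,
        )
        return pd.DataFrame(
            columns=["term_name", "N", "K", "n", "k", "fold", "p", "q"]
        ).rename_axis("term_id")
    out = pd.DataFrame(rows).set_index("term_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable")
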