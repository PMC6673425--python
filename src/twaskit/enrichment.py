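"""Gene-set over-representation analysis.

Given a candidate gene list and term -> gene annotations, each term is
scored with the one-sided hypergeometric upper tail: with universe size N,
term size K, query size n and overlap k, p = P(X >= k) for
X ~ Hypergeom(N, K, n). The EASE variant removes one overlapping gene
(k -> max(k-1, 0)) before taking the tail, a deliberately conservative
score that penalizes terms supported by a single gene.

Annotations are consumed in GMT format; no particular ontology is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .errors import DomainError, FormatError

log = logging.getLogger(__name__)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): population N, K successes,
    n draws, k observed successes."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 1 or not (0 <= K <= N) or not (0 <= n <= N):
        raise DomainError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DomainError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE score: hypergeometric tail at max(k-1, 0). Always >= the plain
    hypergeometric p for the same counts; equals 1 when k <= 1."""
    return hypergeom_p(max(int(k) - 1, 0), K, n, N)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Term -> gene memberships with an explicit background universe."""

    terms: list[GeneSet]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise DomainError("duplicate term_id in gene-set collection")
        for t in self.terms:
            if not t.members <= self.universe:
                raise DomainError(f"term {t.term_id} has members outside the universe")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_terms(cls, terms: Iterable[GeneSet]) -> "GeneSetCollection":
        """Universe defaults to the union of all term members."""
        terms = list(terms)
        universe = frozenset().union(*(t.members for t in terms)) if terms else frozenset()
        return cls(terms=terms, universe=universe)


def read_gmt(path: str | Path, default_category: str = "NA") -> GeneSetCollection:
    """Read GMT: ``term_id <tab> description <tab> gene...`` per line.

    A description of the form ``CATEGORY|Name`` carries the term category
    (our own convention, since plain GMT has no category field); otherwise
    the whole description is the name and the category is
    ``default_category``. The universe is the union of all members.
    """
    path = Path(path)
    terms: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path.name}:{lineno}: GMT line has fewer than 3 fields")
        term_id, desc = parts[0], parts[1]
        category, _, name = desc.partition("|")
        if not name:
            category, name = default_category, desc
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path.name}:{lineno}: term {term_id} has no genes")
        terms.append(GeneSet(term_id=term_id, name=name, category=category, members=genes))
    if not terms:
        raise FormatError(f"{path.name}: no terms found")
    return GeneSetCollection.from_terms(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, f"{t.category}|{t.name}", *sorted(t.members)])
        for t in collection.terms
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p: float
    significant: bool


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    method: str = "hypergeometric",
    p_thresh: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every term against the query gene set.

    Query genes outside the universe are dropped with a warning (they
    cannot contribute to any overlap). Results come back sorted by
    ascending p with ties broken by term_id, and rows with p < p_thresh
    flagged significant. Gene matching is case-insensitive.
    """
    if method not in ("hypergeometric", "ease"):
        raise DomainError(f"unknown enrichment method {method!r}")
    if not (0 < p_thresh <= 1):
        raise DomainError("p_thresh must lie in (0, 1]")
    if not collection.universe:
        raise DomainError("empty universe")

    universe_upper = {g.upper() for g in collection.universe}
    query_upper = {str(g).upper() for g in query}
    dropped = query_upper - universe_upper
    if dropped:
        log.warning("enrich: %d query gene(s) outside the universe dropped", len(dropped))
    q = query_upper & universe_upper

    N = len(universe_upper)
    n = len(q)
    tail = hypergeom_p if method == "hypergeometric" else ease_p
    out = []
    for t in collection.terms:
        members_upper = {g.upper() for g in t.members}
        K = len(members_upper)
        k = len(q & members_upper)
        p = tail(k, K, n, N)
        out.append(
            EnrichmentResult(
                term_id=t.term_id, name=t.name, category=t.category,
                k=k, K=K, n=n, N=N, p=p, significant=p < p_thresh,
            )
        )
    out.sort(key=lambda r: (r.p, r.term_id))
    return out


def bh_qvalues(results: Sequence[EnrichmentResult]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, in the order of ``results``.

    Offered as an optional extra; the primary significance call uses the
    raw p threshold.
    """
    from statsmodels.stats.multitest import multipletests

    if not results:
        return []
    return list(multipletests([r.p for r in results], method="fdr_bh")[1])


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (r.category, r.term_id, r.name, r.p, r.k, r.K, r.n, r.N, r.significant)
            for r in results
        ],
        columns=["CATEGORY", "ID", "NAME", "P", "K_OVERLAP", "K_TERM", "N_QUERY", "N_UNIVERSE", "SIGNIFICANT"],
    ).to_csv(path, sep="\t", index=False, float_format="%.4G")
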