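"""Hypergeometric overrepresentation shared by pathway and regulator
enrichment.

One engine serves both analyses: a regulator->target database is viewed
as a gene-set database whose terms are regulators and whose universe is
the union of all target sets.  For a gene list of size n drawn from a
background of N genes, a term annotating K background genes and
overlapping the list in k genes is scored with the inclusive upper tail
P(X >= k), X ~ Hypergeometric(N, K, n), computed in log space.

Backgrounds are stage dependent: the global stage conditions on the
whole database universe, while the per-component stage conditions on
the differential genes themselves, asking which annotations distinguish
a component's contributors from the rest of the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dgea import bh_adjust
from .io import DataError, GeneSetDB, TrTargetDB

__all__ = [
    "EnrichmentQuery",
    "EnrichmentRow",
    "hypergeometric_upper_tail",
    "run_enrichment",
    "stagewise_backgrounds",
    "significance_stars",
    "enrichment_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentQuery:
    """A gene list, a database, and the background to condition on."""

    gene_list: frozenset[str]
    database: GeneSetDB
    background_mode: str = "database_universe"  # or "custom"
    custom_background: frozenset[str] | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.database, TrTargetDB):
            self.database = self.database.as_gene_set_db()
        self.gene_list = frozenset(self.gene_list)
        if self.background_mode not in ("database_universe", "custom"):
            raise DataError(f"unknown background mode {self.background_mode!r}")
        if self.background_mode == "custom" and not self.custom_background:
            raise DataError("custom background mode needs a non-empty background set")

    @property
    def background(self) -> frozenset[str]:
        if self.background_mode == "database_universe":
            return self.database.universe
        return frozenset(self.custom_background)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    overlap: int            # k
    term_size_in_bg: int    # K
    list_size_in_bg: int    # n
    background_size: int    # N
    p_value: float
    adj_p: float
    up_regulated_pct: float  # NaN when no regulation information
    overlap_genes: frozenset[str]
    significant: bool = False


def _log_hypergeom_pmf(x: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive, in log space.

    N is the background size, K the term size within the background,
    n the gene-list size within the background and k the overlap.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise DataError(f"{name} must be a non-negative integer, got {v!r}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if n > N or K > N or k > min(n, K):
        raise DataError(
            f"invalid counts: need k <= min(n, K) <= N, got k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    lo = max(k, n + K - N)
    hi = min(n, K)
    x = np.arange(lo, hi + 1)
    return float(np.exp(logsumexp(_log_hypergeom_pmf(x, n, K, N))))


def run_enrichment(
    query: EnrichmentQuery,
    regulation: dict[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Score every database term against the query gene list.

    Terms with no background annotation (K = 0) are excluded before the
    Benjamini-Hochberg adjustment, which is applied across all tested
    terms of this query.  ``up_regulated_pct`` is the percentage of
    overlap genes marked "up" in the regulation map; genes missing from
    the map are excluded from the denominator.
    """
    background = query.background
    effective = query.gene_list & background
    if not effective:
        raise DataError(
            f"empty effective gene list: |list|={len(query.gene_list)}, "
            f"|background|={len(background)}, |intersection|=0"
        )
    dropped = len(query.gene_list) - len(effective)
    if dropped:
        logger.info("dropped %d list genes absent from the background", dropped)
    N = len(background)
    n = len(effective)
    rows: list[EnrichmentRow] = []
    skipped = 0
    for term in query.database.terms:
        term_bg = term.genes & background
        K = len(term_bg)
        if K == 0:
            skipped += 1
            continue
        overlap_genes = frozenset(effective & term_bg)
        k = len(overlap_genes)
        p = hypergeometric_upper_tail(k, n, K, N)
        if regulation is not None:
            marked = [g for g in overlap_genes if g in regulation]
            up_pct = (
                100.0 * sum(regulation[g] == "up" for g in marked) / len(marked)
                if marked else float("nan")
            )
        else:
            up_pct = float("nan")
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                term_name=term.term_name,
                category=term.category,
                overlap=k,
                term_size_in_bg=K,
                list_size_in_bg=n,
                background_size=N,
                p_value=p,
                adj_p=np.nan,
                up_regulated_pct=up_pct,
                overlap_genes=overlap_genes,
            )
        )
    if skipped:
        logger.info("excluded %d terms with no background annotation", skipped)
    if not rows:
        raise DataError("no database term has background annotation")
    adj = bh_adjust([r.p_value for r in rows])
    for r, a in zip(rows, adj):
        r.adj_p = float(a)
        r.significant = a < query.alpha
    rows.sort(key=lambda r: (r.adj_p, r.p_value, r.term_id))
    return rows


def stagewise_backgrounds(
    differential_genes: set[str],
    contributors: set[str] | None,
    database: GeneSetDB | TrTargetDB,
    alpha: float = 0.05,
) -> EnrichmentQuery:
    """Build the enrichment query for the global or per-component stage.

    Global stage (``contributors`` is None): background = database
    universe, list = differential genes.  Component stage: background =
    differential genes within the universe, list = the component's
    contributor genes within that background.
    """
    if not differential_genes:
        raise DataError("differential gene set is empty")
    db = database.as_gene_set_db() if isinstance(database, TrTargetDB) else database
    universe = db.universe
    if contributors is None:
        return EnrichmentQuery(
            gene_list=frozenset(differential_genes),
            database=db,
            background_mode="database_universe",
            alpha=alpha,
        )
    background = frozenset(differential_genes) & universe
    if not background:
        raise DataError("no differential gene appears in the database universe")
    return EnrichmentQuery(
        gene_list=frozenset(contributors) & background,
        database=db,
        background_mode="custom",
        custom_background=background,
        alpha=alpha,
    )


def significance_stars(adj_p: float) -> str:
    if adj_p < 0.001:
        return "***"
    if adj_p < 0.01:
        return "**"
    if adj_p < 0.05:
        return "*"
    return "-"


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular report: term, Gene:Bg ratio, p, adj_p, stars, Up-reg[%]."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "category": [r.category for r in rows],
            "gene_bg_ratio": [
                f"{r.overlap}/{r.list_size_in_bg}:{r.term_size_in_bg}" for r in rows
            ],
            "p": [r.p_value for r in rows],
            "adj_p": [r.adj_p for r in rows],
            "stars": [significance_stars(r.adj_p) for r in rows],
            "up_reg_pct": [r.up_regulated_pct for r in rows],
            "overlap_genes": [",".join(sorted(r.overlap_genes)) for r in rows],
        }
    )
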