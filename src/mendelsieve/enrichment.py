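"""Gene–disease literature co-citation enrichment.

Given article counts — articles mentioning a gene, articles mentioning the
disease, articles mentioning both, and the size of the article universe —
build the 2×2 contingency table and test for enrichment with a one-sided
Fisher exact test (upper hypergeometric tail), reporting the sample odds
ratio alongside the exact p-value.

The universe size is a required input: published co-citation tables often
omit it, and without it a non-zero odds ratio cannot be reproduced. When
the co-mention count is zero the answer is universe-independent: the odds
ratio is 0 and the one-sided p is exactly 1.

The tail probability is computed with log-space lgamma binomials, so it is
stable for universes of 10^7 articles and beyond; no factorials are formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class CoCitationCounts:
    """Article counts for one gene against one disease term."""

    n_gene: int
    n_disease: int
    n_both: int
    n_universe: int

    def __post_init__(self) -> None:
        for name, v in (
            ("n_gene", self.n_gene),
            ("n_disease", self.n_disease),
            ("n_both", self.n_both),
            ("n_universe", self.n_universe),
        ):
            if not isinstance(v, int) or v < 0:
                raise EnrichmentError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_both > min(self.n_gene, self.n_disease):
            raise EnrichmentError(
                f"n_both ({self.n_both}) exceeds a margin "
                f"(gene {self.n_gene}, disease {self.n_disease})"
            )
        if self.n_universe < self.n_gene + self.n_disease - self.n_both:
            raise EnrichmentError(
                f"universe {self.n_universe} smaller than the union of margins"
            )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells: a = both, b = gene-only, c = disease-only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float


def to_contingency(c: CoCitationCounts) -> ContingencyTable2x2:
    """Counts → 2×2 table; margins reconstruct the inputs."""
    return ContingencyTable2x2(
        a=c.n_both,
        b=c.n_gene - c.n_both,
        c=c.n_disease - c.n_both,
        d=c.n_universe - c.n_gene - c.n_disease + c.n_both,
    )


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_enrichment_p(t: ContingencyTable2x2) -> float:
    """One-sided (enrichment) Fisher exact p: P(X ≥ a) under the
    hypergeometric null with the table's margins fixed.

    Exact for integer cells; computed in log space so universes of 10^7
    articles pose no overflow. When a = 0 the upper tail is the whole
    support and p is returned as exactly 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a == 0:
        return 1.0
    row1 = a + b       # articles mentioning the gene
    col1 = a + c       # articles mentioning the disease
    n = t.n
    k_max = min(row1, col1)
    denom = _lchoose(n, col1)
    total = 0.0
    for k in range(a, k_max + 1):
        total += math.exp(_lchoose(row1, k) + _lchoose(n - row1, col1 - k) - denom)
    return min(total, 1.0)


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample odds ratio (a·d)/(b·c), with no continuity correction.

    Returns 0 when a = 0 (and the denominator is positive), +inf when the
    denominator vanishes while the numerator does not; a table where both
    products vanish — including the all-zero table — has no defined ratio.
    """
    num = t.a * t.d
    den = t.b * t.c
    if den == 0:
        if num == 0:
            raise EnrichmentError(f"odds ratio undefined for {t}")
        return math.inf
    return num / den


def enrich(c: CoCitationCounts) -> EnrichmentResult:
    t = to_contingency(c)
    return EnrichmentResult(odds_ratio=odds_ratio(t), p_value=fisher_enrichment_p(t))


def batch_enrich(
    rows: "pd.DataFrame | Mapping[str, tuple[int, int]]",
    n_disease: int | None = None,
    n_universe: int | None = None,
) -> pd.DataFrame:
    """Enrichment for a batch of genes sharing a disease count and universe.

    ``rows`` is either a DataFrame with columns ``gene``, ``n_gene``,
    ``n_both`` (plus optional ``n_disease``/``n_universe`` columns
    overriding the shared values) or a mapping gene → (n_gene, n_both).
    Rows that fail validation are reported with NaN results and an error
    message rather than aborting the batch.
    """
    if isinstance(rows, Mapping):
        rows = pd.DataFrame(
            [{"gene": g, "n_gene": ng, "n_both": nb} for g, (ng, nb) in rows.items()]
        )
    out = []
    for row in rows.itertuples(index=False):
        nd = int(getattr(row, "n_disease", n_disease) or 0) or n_disease
        nu = int(getattr(row, "n_universe", n_universe) or 0) or n_universe
        rec = {"gene": row.gene, "n_gene": int(row.n_gene), "n_both": int(row.n_both)}
        try:
            if nd is None or nu is None:
                raise EnrichmentError("n_disease and n_universe are required")
            res = enrich(
                CoCitationCounts(int(row.n_gene), int(nd), int(row.n_both), int(nu))
            )
            rec.update(odds_ratio=res.odds_ratio, p_value=res.p_value, error="")
        except EnrichmentError as e:
            rec.update(odds_ratio=math.nan, p_value=math.nan, error=str(e))
        out.append(rec)
    return pd.DataFrame(out, columns=["gene", "n_gene", "n_both",
                                      "odds_ratio", "p_value", "error"])


# Published co-citation counts for the four candidate genes against the
# enamel-formation disorder (906 disease articles); the universe size was
# not published and must be supplied by the caller.
TABLE_COUNTS: dict[str, tuple[int, int]] = {
    "MROH7": (22, 0),
    "FAT2": (304, 0),
    "MTERF2": (56, 0),
    "HCCS": (234, 6),
}
DISEASE_ARTICLES = 906
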