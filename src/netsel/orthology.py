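"""Homology decision rules over precomputed pairwise similarity hits.

The procedure works on tabular hit files only (it never runs a search
program): hits are filtered on bit score and alignment length, then a
gene is called an ortholog when the best hits of the two reciprocal
searches match; failing that, the surviving hit with the best query
coverage can rescue a homolog call if it clears score, relative
identity and relative similarity thresholds; otherwise the gene is a
non-homolog, or absent when nothing survives filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit (a filtered search-table row)."""

    query: str
    subject: str
    score: float
    alignment_length: int
    percent_identity: float
    percent_similarity: float
    coverage: float = 0.0

    def __post_init__(self) -> None:
        for name in ("query", "subject"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value or any(c.isspace() for c in value):
                raise ValueError(f"malformed {name} id: {value!r}")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not (0 <= self.percent_identity <= self.percent_similarity <= 100):
            raise ValueError(
                "need 0 <= identity <= similarity <= 100, got "
                f"{self.percent_identity}/{self.percent_similarity}"
            )
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds; all comparisons are strict (>)."""

    score: float = 150.0
    alignment_length: int = 50
    identity: float = 30.0
    similarity: float = 40.0


VERDICTS = ("ortholog_rbh", "homolog_fallback", "non_homolog", "absent")


@dataclass
class OrthologyCall:
    """The verdict for one query gene against one target genome."""

    gene: str
    target_genome: str
    verdict: str
    supporting_hits: list[HitRecord] = field(default_factory=list)
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def filter_hits(hits: list[HitRecord], thresholds: Thresholds = Thresholds()) -> list[HitRecord]:
    """Keep hits with score and alignment length strictly above threshold."""
    return [
        h
        for h in hits
        if h.score > thresholds.score and h.alignment_length > thresholds.alignment_length
    ]


def best_hit(hits: list[HitRecord]) -> HitRecord | None:
    """Top-scoring hit of one query; deterministic under input reordering.

    Ties on score break by higher percent similarity, then by
    lexicographically smallest subject id.
    """
    if not hits:
        return None
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits from multiple queries: {sorted(queries)}")
    return min(hits, key=lambda h: (-h.score, -h.percent_similarity, h.subject))


def classify_orthologs(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    thresholds: Thresholds = Thresholds(),
    queries: list[str] | None = None,
    target_genome: str = "target",
) -> list[OrthologyCall]:
    """Three-way homology verdict for each query of the A->B search.

    ``hits_ab`` are hits of genome-A queries against genome B, and
    ``hits_ba`` the reciprocal search.  Both tables are filtered here
    (filtering twice is harmless).  ``queries`` optionally fixes the
    query universe so genes with no surviving hit are reported absent.
    """
    kept_ab = filter_hits(hits_ab, thresholds)
    kept_ba = filter_hits(hits_ba, thresholds)

    by_query_ab: dict[str, list[HitRecord]] = {}
    for h in kept_ab:
        by_query_ab.setdefault(h.query, []).append(h)
    by_query_ba: dict[str, list[HitRecord]] = {}
    for h in kept_ba:
        by_query_ba.setdefault(h.query, []).append(h)

    if queries is None:
        queries = sorted({h.query for h in hits_ab})

    calls: list[OrthologyCall] = []
    for gene in queries:
        mine = by_query_ab.get(gene, [])
        if not mine:
            calls.append(
                OrthologyCall(gene, target_genome, "absent",
                              rationale="no hit survives score/length filtering")
            )
            continue
        top = best_hit(mine)
        reciprocal = best_hit(by_query_ba.get(top.subject, []))
        if reciprocal is not None and reciprocal.subject == gene:
            calls.append(
                OrthologyCall(
                    gene, target_genome, "ortholog_rbh",
                    supporting_hits=[top, reciprocal],
                    rationale=f"best hits reciprocate via {top.subject}",
                )
            )
            continue
        candidate = max(mine, key=lambda h: (h.coverage, h.score, h.subject))
        if (
            candidate.score > thresholds.score
            and candidate.percent_identity > thresholds.identity
            and candidate.percent_similarity > thresholds.similarity
        ):
            calls.append(
                OrthologyCall(
                    gene, target_genome, "homolog_fallback",
                    supporting_hits=[candidate],
                    rationale=(
                        f"best-coverage hit {candidate.subject}: "
                        f"score {candidate.score:g}, "
                        f"identity {candidate.percent_identity:g}%, "
                        f"similarity {candidate.percent_similarity:g}%"
                    ),
                )
            )
        else:
            calls.append(
                OrthologyCall(
                    gene, target_genome, "non_homolog",
                    supporting_hits=[candidate],
                    rationale=(
                        "no reciprocal best hit and best-coverage hit below "
                        "identity/similarity thresholds"
                    ),
                )
            )
    return calls


def presence_matrix(
    calls: list[OrthologyCall],
    genes: list[str] | None = None,
    genomes: list[str] | None = None,
) -> pd.DataFrame:
    """Copy-count matrix (gene x genome) from orthology calls.

    Each ``ortholog_rbh`` or ``homolog_fallback`` call adds one copy;
    ``absent`` and ``non_homolog`` count zero.
    """
    if genes is None:
        genes = sorted({c.gene for c in calls})
    if genomes is None:
        genomes = sorted({c.target_genome for c in calls})
    matrix = pd.DataFrame(0, index=genes, columns=genomes, dtype=int)
    for call in calls:
        if call.verdict in ("ortholog_rbh", "homolog_fallback"):
            matrix.loc[call.gene, call.target_genome] += 1
    return matrix


def presence_flags(matrix: pd.DataFrame) -> pd.DataFrame:
    """0/1 presence annotation derived from a copy-count matrix."""
    return (matrix > 0).astype(int)
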