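"""Scored reciprocal-best-hit merge of protein databases.

Builds a nonredundant search database from entries pooled across SwissProt,
Ensembl, NCBI, TrEMBL and GENESCAN.  Cross-database reciprocal-best-hit
(RBH) BLAST hits are scored on identity, e-value and coverage (0-5 points);
pairs at or above a score cut-off are clustered as the same protein, and one
representative per cluster is retained — the longest sequence, with the
source-priority order breaking ties at equal length and similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ANALYSIS_DEFAULTS, SOURCE_PRIORITY

_SOURCE_RANK = {s: i for i, s in enumerate(SOURCE_PRIORITY)}


@dataclass(frozen=True)
class SequenceEntry:
    accession: str
    source: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.source not in _SOURCE_RANK:
            raise ValueError(f"unknown source {self.source!r}; expected one of "
                             f"{list(SOURCE_PRIORITY)}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"sequence length {len(self.sequence)} does not "
                             f"match declared length {self.length}")


@dataclass(frozen=True)
class RbhHit:
    query: str
    subject: str
    identity_pct: float
    evalue: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct must be in [0, 100], got {self.identity_pct}")
        if self.evalue <= 0.0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")


@dataclass(frozen=True)
class MatchScore:
    """Composite 0-5 match score with its per-criterion components."""
    value: int
    identity_pts: int
    evalue_pts: int
    coverage_pts: int


def score_match(hit: RbhHit) -> MatchScore:
    """Score an RBH hit: identity >97.5 (+2) / >95 (+1); e-value <1E-180
    (+2) / <1E-150 (+1); coverage >0.95 (+1).  All inequalities strict;
    boundary values score the lower tier."""
    if hit.identity_pct > ANALYSIS_DEFAULTS["identity_high"]:
        ident = 2
    elif hit.identity_pct > ANALYSIS_DEFAULTS["identity_low"]:
        ident = 1
    else:
        ident = 0
    if hit.evalue < ANALYSIS_DEFAULTS["evalue_high"]:
        ev = 2
    elif hit.evalue < ANALYSIS_DEFAULTS["evalue_low"]:
        ev = 1
    else:
        ev = 0
    cov = 1 if hit.coverage > ANALYSIS_DEFAULTS["coverage_high"] else 0
    return MatchScore(value=ident + ev + cov, identity_pts=ident,
                      evalue_pts=ev, coverage_pts=cov)


def filter_short(entries: list[SequenceEntry], min_length: int = 30,
                 ) -> tuple[list[SequenceEntry], int]:
    """Drop sequences shorter than ``min_length`` residues (default 30;
    a 30-residue sequence is retained).  Returns (kept, n_removed)."""
    kept = [e for e in entries if e.length >= min_length]
    return kept, len(entries) - len(kept)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice, independent of input order
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def merge_databases(entries: list[SequenceEntry], hits: list[RbhHit],
                    min_score: int | None = None,
                    ) -> tuple[list[SequenceEntry], pd.DataFrame]:
    """Collapse duplicate entries across databases into one representative.

    Entries linked (transitively) by RBH hits scoring at least ``min_score``
    (default 3; the published workflow does not state the cut-off, so it is
    configurable) form a duplicate cluster.  The representative is the
    longest sequence; at equal length and linking similarity, the source
    priority SwissProt > Ensembl > NCBI > TrEMBL > GENESCAN decides; the
    accession string is the final deterministic tie-break.  Hits referring
    to unknown accessions are ignored (this makes the merge idempotent).

    Returns ``(kept_entries, provenance)`` where provenance is a DataFrame
    with one row per input entry: accession, cluster, kept, representative,
    reason.
    """
    if min_score is None:
        min_score = int(ANALYSIS_DEFAULTS["merge_min_score"])
    by_acc = {}
    for e in entries:
        if e.accession in by_acc:
            raise ValueError(f"duplicate accession in input: {e.accession}")
        by_acc[e.accession] = e

    uf = _UnionFind(by_acc)
    link_score: dict[str, int] = {a: 0 for a in by_acc}
    for h in hits:
        if h.query not in by_acc or h.subject not in by_acc:
            continue
        s = score_match(h).value
        if s >= min_score:
            uf.union(h.query, h.subject)
            link_score[h.query] = max(link_score[h.query], s)
            link_score[h.subject] = max(link_score[h.subject], s)

    clusters: dict[str, list[str]] = {}
    for acc in by_acc:
        clusters.setdefault(uf.find(acc), []).append(acc)

    kept: list[SequenceEntry] = []
    prov_rows = []
    for root in sorted(clusters):
        members = clusters[root]
        # longest first; then strongest linking similarity; then source
        # priority; then accession for determinism
        rep = min(members, key=lambda a: (-by_acc[a].length, -link_score[a],
                                          _SOURCE_RANK[by_acc[a].source], a))
        kept.append(by_acc[rep])
        for acc in sorted(members):
            if acc == rep:
                reason = "representative" if len(members) > 1 else "singleton"
            else:
                reason = f"duplicate_of:{rep}"
            prov_rows.append((acc, root, acc == rep, rep, reason))

    kept.sort(key=lambda e: e.accession)
    provenance = pd.DataFrame(prov_rows, columns=[
        "accession", "cluster", "kept", "representative", "reason"])
    return kept, provenance


# ---------------------------------------------------------------------------
# tabular adapters
# ---------------------------------------------------------------------------

def entries_from_frame(df: pd.DataFrame) -> list[SequenceEntry]:
    """Build entries from a metadata table (accession, source, length
    [, sequence])."""
    has_seq = "sequence" in df.columns
    out = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "sequence", None) if has_seq else None
        if isinstance(seq, float):  # NaN from CSV round-trip
            seq = None
        out.append(SequenceEntry(accession=str(row.accession),
                                 source=str(row.source),
                                 length=int(row.length),
                                 sequence=seq))
    return out


def hits_from_frame(df: pd.DataFrame) -> list[RbhHit]:
    """Build RBH hits from BLAST outfmt-6-style columns
    (query, subject, identity_pct/pident, evalue, coverage)."""
    cols = {c.lower(): c for c in df.columns}
    ident_col = cols.get("identity_pct") or cols.get("pident")
    if ident_col is None:
        raise ValueError("hit table needs an identity_pct or pident column")
    return [RbhHit(query=str(r[cols.get("query", "query")]),
                   subject=str(r[cols.get("subject", "subject")]),
                   identity_pct=float(r[ident_col]),
                   evalue=float(r[cols["evalue"]]),
                   coverage=float(r[cols["coverage"]]))
            for _, r in df.iterrows()]
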