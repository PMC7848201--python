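"""Three-source transcript-annotation merging and symbol assignment.

The merge algebra works on stranded exon-chain transcript records with
0-based half-open exon intervals (GTF I/O converts to and from 1-based
closed coordinates).  Merging proceeds stepwise: a secondary annotation is
used to supplement the primary one, remaining novel models are integrated
with the same rules, then novel models are re-assigned or removed using
splice-junction evidence.  Finally gene symbols are assigned from alignment
hits with coverage-dependent ``_like`` / ``_containing`` suffixes.

Every input transcript is accounted for exactly once in the provenance log
returned alongside each merged set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .config import MergeRules, SymbolRules

__all__ = [
    "TranscriptModel",
    "JunctionEvidence",
    "AlignmentHit",
    "ProvenanceEntry",
    "exon_overlap",
    "reciprocal_overlap",
    "supplement_secondary",
    "integrate_novel",
    "reassign_by_splice_evidence",
    "assign_symbols",
    "read_gtf",
    "write_gtf",
    "read_junction_evidence",
    "write_junction_evidence",
    "read_alignment_hits",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded exon-chain transcript record.

    ``exons`` are sorted, non-overlapping half-open intervals on one
    chromosome and strand.  ``source`` records provenance: one of
    ``primary``, ``secondary``, ``novel``.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "primary"
    symbol: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.tx_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.tx_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.tx_id}: exon start must be < end")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.tx_id}: exons must be sorted, non-overlapping")
            prev_end = end

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class JunctionEvidence:
    """One spliced junction with supporting read count.

    ``donor`` and ``acceptor`` are genomic coordinates of the last exonic
    base of the upstream exon and the first exonic base of the downstream
    exon (0-based), so both endpoints fall inside exons.
    """

    chrom: str
    strand: str
    donor: int
    acceptor: int
    count: int

    def __post_init__(self):
        if self.donor >= self.acceptor:
            raise ValueError("junction donor must be < acceptor")
        if self.count < 0:
            raise ValueError("junction count must be >= 0")


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    evalue: float
    identity: float
    coverage: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class ProvenanceEntry:
    tx_id: str
    source: str
    action: str  # kept / dropped / reassigned
    reason: str
    detail: str = ""


def _intervals_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff some exon of ``a`` shares >= 1 base with some exon of ``b``
    on the same chromosome and strand."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    # exon lists are sorted: merge-walk
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        if _intervals_intersect(a.exons[i], b.exons[j]):
            return True
        if a.exons[i][1] <= b.exons[j][1]:
            i += 1
        else:
            j += 1
    return False


def reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    """min(shared exonic bases / exonic length of a, same for b).

    Returns 0.0 for transcripts on different chromosomes or strands.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    shared = 0
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        s = max(a.exons[i][0], b.exons[j][0])
        e = min(a.exons[i][1], b.exons[j][1])
        if e > s:
            shared += e - s
        if a.exons[i][1] <= b.exons[j][1]:
            i += 1
        else:
            j += 1
    if shared == 0:
        return 0.0
    return min(shared / a.exonic_length, shared / b.exonic_length)


def _check_unique_ids(existing: list[TranscriptModel], incoming: list[TranscriptModel]):
    seen = {t.tx_id for t in existing}
    collisions = [t.tx_id for t in incoming if t.tx_id in seen]
    dup_in = [t for t in {x.tx_id for x in incoming} if sum(x.tx_id == t for x in incoming) > 1]
    if collisions or dup_in:
        raise ValueError(f"duplicate tx_id across sources: {sorted(set(collisions) | set(dup_in))}")


def _supplement(
    base: list[TranscriptModel],
    incoming: list[TranscriptModel],
    rules: MergeRules,
) -> tuple[list[TranscriptModel], list[ProvenanceEntry]]:
    rules.validate()
    _check_unique_ids(base, incoming)
    merged = list(base)
    log: list[ProvenanceEntry] = []
    by_chrom: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in base:
        by_chrom.setdefault((t.chrom, t.strand), []).append(t)
    for t in incoming:
        candidates = by_chrom.get((t.chrom, t.strand), [])
        overlapping = [p for p in candidates if exon_overlap(t, p)]
        if not overlapping:
            merged.append(t)
            log.append(ProvenanceEntry(t.tx_id, t.source, "kept", "no_exon_overlap"))
            continue
        if len(t.exons) == 1 and t.exonic_length < rules.short_tx_max_len:
            max_ro = max(reciprocal_overlap(t, p) for p in overlapping)
            if max_ro < rules.reciprocal_overlap_max:
                merged.append(t)
                log.append(
                    ProvenanceEntry(
                        t.tx_id, t.source, "kept",
                        "short_single_exon_low_reciprocal_overlap",
                        f"max_ro={max_ro:.4f}",
                    )
                )
                continue
            log.append(
                ProvenanceEntry(
                    t.tx_id, t.source, "dropped",
                    "reciprocal_overlap_at_or_above_max", f"max_ro={max_ro:.4f}",
                )
            )
            continue
        log.append(ProvenanceEntry(t.tx_id, t.source, "dropped", "exon_overlap"))
    return merged, log


def supplement_secondary(
    primary: list[TranscriptModel],
    secondary: list[TranscriptModel],
    rules: MergeRules | None = None,
) -> tuple[list[TranscriptModel], list[ProvenanceEntry]]:
    """Add secondary transcripts with no exon overlap to any primary one,
    plus short (<1 kb) single-exon secondary transcripts whose best
    reciprocal overlap with any primary transcript is below the cutoff."""
    return _supplement(primary, secondary, rules or MergeRules())


def integrate_novel(
    merged: list[TranscriptModel],
    novel: list[TranscriptModel],
    rules: MergeRules | None = None,
) -> tuple[list[TranscriptModel], list[ProvenanceEntry]]:
    """Apply the same supplement rules with the novel set as incoming."""
    return _supplement(merged, novel, rules or MergeRules())


def _position_in_exons(pos: int, tx: TranscriptModel) -> bool:
    return any(s <= pos < e for s, e in tx.exons)


def reassign_by_splice_evidence(
    merged: list[TranscriptModel],
    evidence: list[JunctionEvidence],
    rules: MergeRules | None = None,
) -> tuple[list[TranscriptModel], list[ProvenanceEntry]]:
    """Re-assign or remove novel transcripts using splice-junction evidence.

    A novel transcript linked by a sufficiently supported junction (one
    endpoint in one of its exons, the other in an exon of a non-novel
    transcript, same strand) takes the gene id of that reference
    transcript.  A novel transcript with no such evidence whose whole span
    lies inside a single intron of a reference transcript (either strand)
    is removed.  Everything else is unchanged.
    """
    rules = rules or MergeRules()
    rules.validate()
    reference = [t for t in merged if t.source != "novel"]
    out: list[TranscriptModel] = []
    log: list[ProvenanceEntry] = []
    for t in merged:
        if t.source != "novel":
            out.append(t)
            log.append(ProvenanceEntry(t.tx_id, t.source, "kept", "reference"))
            continue
        # gene_id -> total supporting reads over linking junctions
        support: dict[str, int] = {}
        for j in evidence:
            if j.chrom != t.chrom or j.strand != t.strand:
                continue
            if j.count < rules.min_spliced_reads:
                continue
            for p1, p2 in ((j.donor, j.acceptor), (j.acceptor, j.donor)):
                if not _position_in_exons(p1, t):
                    continue
                for ref in reference:
                    if ref.chrom == j.chrom and ref.strand == j.strand and _position_in_exons(p2, ref):
                        support[ref.gene_id] = support.get(ref.gene_id, 0) + j.count
        if support:
            # tie-break: most evidence, then lexicographically smaller gene id
            best = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            detail = ""
            if len(support) > 1:
                detail = f"multiple linked genes {sorted(support)} -> {best}"
            out.append(replace(t, gene_id=best))
            log.append(
                ProvenanceEntry(t.tx_id, t.source, "reassigned", "splice_evidence",
                                detail or f"gene_id={best}")
            )
            continue
        span = t.span
        host = None
        for ref in reference:
            if ref.chrom != t.chrom:
                continue  # intronic containment is strand-agnostic
            for intron in ref.introns:
                if intron[0] <= span[0] and span[1] <= intron[1]:
                    host = (ref.tx_id, intron)
                    break
            if host:
                break
        if host:
            log.append(
                ProvenanceEntry(
                    t.tx_id, t.source, "dropped", "contained_in_retained_intron",
                    f"host={host[0]} intron={host[1][0]}-{host[1][1]}",
                )
            )
            continue
        out.append(t)
        log.append(ProvenanceEntry(t.tx_id, t.source, "kept", "no_evidence_not_intronic"))
    return out, log


def assign_symbols(
    transcripts: list[TranscriptModel],
    hits_primary: list[AlignmentHit],
    hits_fallback: list[AlignmentHit],
    rules: SymbolRules | None = None,
) -> pd.DataFrame:
    """Assign the most significant qualifying symbol per transcript.

    Primary hits are preferred; fallback hits are consulted only when no
    primary hit passes the e-value gate.  Coverage >= like_cov_high keeps
    the plain symbol; strictly between the bounds appends ``_like``;
    coverage <= like_cov_low appends ``_containing`` (boundary 0.50 counts
    as containing, boundary 0.90 as plain).  Ties on e-value are broken by
    higher coverage, then higher identity, then subject name.
    """
    rules = rules or SymbolRules()
    rules.validate()

    def best_hit(hits: list[AlignmentHit]) -> AlignmentHit | None:
        ok = [h for h in hits if h.evalue <= rules.max_evalue]
        if not ok:
            return None
        return sorted(ok, key=lambda h: (h.evalue, -h.coverage, -h.identity, h.subject))[0]

    prim: dict[str, list[AlignmentHit]] = {}
    for h in hits_primary:
        prim.setdefault(h.query, []).append(h)
    fall: dict[str, list[AlignmentHit]] = {}
    for h in hits_fallback:
        fall.setdefault(h.query, []).append(h)

    rows = []
    for t in transcripts:
        hit = best_hit(prim.get(t.tx_id, []))
        db = "primary"
        if hit is None:
            hit = best_hit(fall.get(t.tx_id, []))
            db = "fallback"
        if hit is None:
            rows.append(
                {"tx_id": t.tx_id, "symbol": None, "suffix": None,
                 "db": None, "evalue": None, "coverage": None}
            )
            continue
        if hit.coverage >= rules.like_cov_high:
            symbol, suffix = hit.subject, ""
        elif hit.coverage > rules.like_cov_low:
            symbol, suffix = hit.subject + "_like", "_like"
        else:
            symbol, suffix = hit.subject + "_containing", "_containing"
        rows.append(
            {"tx_id": t.tx_id, "symbol": symbol, "suffix": suffix,
             "db": db, "evalue": hit.evalue, "coverage": hit.coverage}
        )
    return pd.DataFrame(rows).set_index("tx_id")


# ---------------------------------------------------------------------------
# I/O: GTF2.2 / GFF3, junction-evidence TSV, alignment-hit tables


def write_gtf(transcripts: list[TranscriptModel], path, source_field: str = "hiberseq") -> None:
    """Write transcripts as GTF2.2 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.tx_id}"; source_db "{t.source}";'
            if t.symbol:
                attrs += f' assigned_symbol "{t.symbol}";'
            span = t.span
            fh.write(
                "\t".join(
                    [t.chrom, source_field, "transcript", str(span[0] + 1),
                     str(span[1]), ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source_field, "exon", str(s + 1), str(e),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path, source: str = "primary") -> list[TranscriptModel]:
    """Read a GTF2.2 or GFF3 file into transcript models (exon features
    grouped by transcript id); coordinates converted to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tx_raw = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        gene_raw = feat.attributes.get("gene_id")
        sym_raw = feat.attributes.get("assigned_symbol")
        src_raw = feat.attributes.get("source_db")
        if not tx_raw:
            raise ValueError(f"{path}: exon feature without transcript_id/Parent")
        tx_id = tx_raw[0]
        rec = grouped.setdefault(
            tx_id,
            {
                "gene_id": gene_raw[0] if gene_raw else tx_id,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "symbol": sym_raw[0] if sym_raw else None,
                "source": src_raw[0] if src_raw else source,
            },
        )
        rec["exons"].append((feat.start - 1, feat.end))
    out = []
    for tx_id, rec in grouped.items():
        exons = tuple(sorted(rec["exons"]))
        out.append(
            TranscriptModel(
                tx_id=tx_id, gene_id=rec["gene_id"], chrom=rec["chrom"],
                strand=rec["strand"], exons=exons, source=rec["source"],
                symbol=rec["symbol"],
            )
        )
    out.sort(key=lambda t: (t.chrom, t.span, t.tx_id))
    return out


def write_junction_evidence(evidence: list[JunctionEvidence], path) -> None:
    pd.DataFrame(
        [
            {"chrom": j.chrom, "strand": j.strand, "donor": j.donor,
             "acceptor": j.acceptor, "count": j.count}
            for j in evidence
        ]
    ).to_csv(path, sep="\t", index=False)


def read_junction_evidence(path) -> list[JunctionEvidence]:
    df = pd.read_csv(path, sep="\t")
    return [
        JunctionEvidence(
            chrom=str(r.chrom), strand=str(r.strand), donor=int(r.donor),
            acceptor=int(r.acceptor), count=int(r.count),
        )
        for r in df.itertuples()
    ]


def read_alignment_hits(path) -> list[AlignmentHit]:
    """Read a tab-separated outfmt-6-like table:
    query, subject, evalue, identity, coverage."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                out.append(
                    AlignmentHit(
                        query=parts[0], subject=parts[1], evalue=float(parts[2]),
                        identity=float(parts[3]), coverage=float(parts[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out
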