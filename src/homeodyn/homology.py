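"""Homoeolog identification between two subgenomes.

The pipeline mirrors the classic three-tier allopolyploid protocol:

1. all-vs-all local alignment of gene sequences with identity >= 0.6 and
   query coverage >= 0.2 (a k-mer prefilter keeps the pair count linear);
2. synteny: candidate pairs are chained by a monotone dynamic program over
   gene-order ranks into collinear blocks (same and inverted orientation);
3. reciprocal best hits among the remaining genes, then a greedy
   homology supplement admitting the best remaining above-threshold hit
   for each still-unpaired gene.

Genes left unpaired are re-aligned against the other subgenome under
stricter *presence* thresholds; those with no hit passing both are
confirmed subgenome-specific.

Local alignment scoring is BLASTN-like (match +2, mismatch -3, gap open -5,
gap extend -2, where "open" is the score of the first gap column) and runs
on Bio.Align.PairwiseAligner.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align

from .io_formats import GeneModel, GenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0      # score of the first column of a gap
    gap_extend: float = -2.0


DEFAULT_SCORING = AlignScoring()


@dataclass(frozen=True)
class SimilarityHit:
    """Directional local-alignment hit; coverage is query-side."""

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must be fractions in [0, 1]")


@dataclass(frozen=True)
class SyntenyAnchor:
    a_gene: str
    b_gene: str
    a_rank: int
    b_rank: int
    chrom_a: str = ""
    chrom_b: str = ""

    def __post_init__(self) -> None:
        if self.a_rank < 0 or self.b_rank < 0:
            raise ValueError("ranks must be non-negative")


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[SyntenyAnchor]
    orientation: str  # same | inverted
    score: float


@dataclass(frozen=True)
class HomoeologRecord:
    a_gene: str
    b_gene: str
    evidence: str  # synteny | rbh | homology_supplement
    identity: float
    coverage: float


@dataclass(frozen=True)
class SpecificGeneRecord:
    gene_id: str
    subgenome: str
    confirmed: bool
    best_cross_identity: float
    best_cross_coverage: float


@dataclass
class ClassificationSummary:
    n_homoeolog_pairs: int
    n_a_specific: int
    n_b_specific: int
    n_unresolved_a: int
    n_unresolved_b: int
    total_a: int
    total_b: int


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_pair(seq1: str, seq2: str, scoring: AlignScoring = DEFAULT_SCORING) -> SimilarityHit:
    """Best local alignment of seq1 (query) vs seq2 (subject).

    identity = matches / alignment columns (gap columns included);
    coverage = query span of the alignment / query length.
    """
    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    aligner = _make_aligner(scoring)
    alignments = aligner.align(seq1, seq2)
    score = float(alignments.score)
    if score <= 0:
        return SimilarityHit("query", "subject", 0.0, 0.0, 0.0)
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned  # target = seq1? Bio aligns (target, query) = (seq1, seq2)
    # Bio.Align: align(a, b) -> a is "target", b is "query"; blocks are
    # [target_segments, query_segments].  Our query is seq1 == target here.
    matches = 0
    block_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        block_cols += te - ts
        matches += sum(1 for x, y in zip(seq1[ts:te], seq2[qs:qe]) if x == y)
    gap_cols = 0
    for i in range(len(t_blocks) - 1):
        gap_cols += (t_blocks[i + 1][0] - t_blocks[i][1]) + (q_blocks[i + 1][0] - q_blocks[i][1])
    columns = block_cols + gap_cols
    identity = matches / columns if columns else 0.0
    span = t_blocks[-1][1] - t_blocks[0][0]
    coverage = span / len(seq1)
    return SimilarityHit("query", "subject", identity, min(coverage, 1.0), score)


def filter_hits(hits: list[SimilarityHit], identity_min: float = 0.6,
                coverage_min: float = 0.2) -> list[SimilarityHit]:
    """Keep hits meeting both the identity and (query-side) coverage thresholds."""
    return [h for h in hits if h.identity >= identity_min and h.coverage >= coverage_min]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(seqs_a: dict[str, str], seqs_b: dict[str, str],
                     k: int, min_shared: int) -> set[tuple[str, str]]:
    """Unordered candidate pairs sharing >= min_shared distinct k-mers.

    Genes shorter than 2k skip the filter (too few k-mers to judge)."""
    index: dict[str, set[str]] = defaultdict(set)
    for gid, seq in seqs_b.items():
        for kmer in _kmer_set(seq, k):
            index[kmer].add(gid)
    cands: set[tuple[str, str]] = set()
    short_b = [g for g, s in seqs_b.items() if len(s) < 2 * k]
    for ga, seq in seqs_a.items():
        if len(seq) < 2 * k:
            cands.update((ga, gb) for gb in seqs_b)
            continue
        shared: dict[str, int] = defaultdict(int)
        for kmer in _kmer_set(seq, k):
            for gb in index.get(kmer, ()):
                shared[gb] += 1
        cands.update((ga, gb) for gb, n in shared.items() if n >= min_shared)
        cands.update((ga, gb) for gb in short_b)
    return cands


def all_vs_all_hits(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    identity_min: float = 0.6,
    coverage_min: float = 0.2,
    k: int = 12,
    min_shared_kmers: int = 3,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[SimilarityHit]:
    """Thresholded hits in both directions (A queries and B queries).

    Each candidate pair is aligned once; the alignment yields one hit per
    direction (identity and score shared, coverage recomputed per query).
    """
    hits: list[SimilarityHit] = []
    for ga, gb in sorted(_candidate_pairs(seqs_a, seqs_b, k, min_shared_kmers)):
        base = align_pair(seqs_a[ga], seqs_b[gb], scoring)
        if base.score <= 0:
            continue
        cov_b = base.coverage * len(seqs_a[ga]) / len(seqs_b[gb])
        fwd = SimilarityHit(ga, gb, base.identity, base.coverage, base.score)
        rev = SimilarityHit(gb, ga, base.identity, min(cov_b, 1.0), base.score)
        hits.extend(filter_hits([fwd, rev], identity_min, coverage_min))
    return hits


def reciprocal_best_hits(hits: list[SimilarityHit],
                         a_ids: set[str] | None = None) -> list[tuple[str, str]]:
    """Pairs whose members are each other's best hit.

    Best = highest score, ties broken by higher identity then lexicographic
    subject id (logged).  If ``a_ids`` is given, pairs are oriented
    (a_gene, b_gene); otherwise members are sorted lexicographically.
    """
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        if (h.score, h.identity) > (cur.score, cur.identity):
            best[h.query_id] = h
        elif (h.score, h.identity) == (cur.score, cur.identity) and h.subject_id < cur.subject_id:
            logger.debug("RBH tie for %s: keeping %s over %s", h.query_id, h.subject_id, cur.subject_id)
            best[h.query_id] = h
    pairs: set[tuple[str, str]] = set()
    for q, h in best.items():
        back = best.get(h.subject_id)
        if back is not None and back.subject_id == q:
            x, y = q, h.subject_id
            if a_ids is not None:
                if y in a_ids:
                    x, y = y, x
            elif x > y:
                x, y = y, x
            pairs.add((x, y))
    return sorted(pairs)


def _gap_penalty(da: int, db: int, gap_open: float, gap_extend_per_rank: float) -> float:
    skipped = (da - 1) + (db - 1)
    return (gap_open if skipped > 0 else 0.0) + gap_extend_per_rank * skipped


def chain_score(chain: list[SyntenyAnchor], orientation: str, gap_open: float,
                gap_extend_per_rank: float, max_rank_gap: int,
                anchor_weight: float = 1.0) -> float | None:
    """Score of a candidate chain, or None if it violates monotonicity/gaps.

    Shared by the DP and by exhaustive-enumeration oracles.
    """
    total = anchor_weight * len(chain)
    for p, q in zip(chain, chain[1:]):
        da = q.a_rank - p.a_rank
        db = (q.b_rank - p.b_rank) if orientation == "same" else (p.b_rank - q.b_rank)
        if da < 1 or db < 1 or da > max_rank_gap or db > max_rank_gap:
            return None
        total -= _gap_penalty(da, db, gap_open, gap_extend_per_rank)
    return total


def _best_chain(anchors: list[SyntenyAnchor], orientation: str, gap_open: float,
                gap_extend_per_rank: float, max_rank_gap: int) -> tuple[float, list[SyntenyAnchor]]:
    """Maximum-weight monotone chain by O(n^2) DP; anchors pre-sorted by a_rank."""
    n = len(anchors)
    dp = [1.0] * n
    back = [-1] * n
    sign = 1 if orientation == "same" else -1
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            da = ai.a_rank - aj.a_rank
            db = sign * (ai.b_rank - aj.b_rank)
            if da < 1 or db < 1 or da > max_rank_gap or db > max_rank_gap:
                continue
            cand = dp[j] + 1.0 - _gap_penalty(da, db, gap_open, gap_extend_per_rank)
            if cand > dp[i] + 1e-12:
                dp[i] = cand
                back[i] = j
    if not n:
        return 0.0, []
    end = max(range(n), key=lambda i: (dp[i], -anchors[i].a_rank))
    chain = []
    i = end
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    return dp[end], chain[::-1]


def chain_anchors(
    anchors: list[SyntenyAnchor],
    gap_open: float = 0.5,
    gap_extend_per_rank: float = 0.1,
    min_block_anchors: int = 3,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Collinear blocks from candidate anchors, grouped by chromosome pair.

    Best chains (same and inverted orientation scored separately) are
    extracted iteratively; anchors sharing a gene with an extracted block
    are retired, so each gene lands in at most one block.  Chains shorter
    than ``min_block_anchors`` are discarded.
    """
    groups: dict[tuple[str, str], list[SyntenyAnchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.chrom_a, a.chrom_b)].append(a)
    blocks: list[SyntenyBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        pool = sorted(group, key=lambda x: (x.a_rank, x.b_rank, x.a_gene))
        while True:
            best_score, best_chain_, best_orient = 0.0, [], ""
            for orient in ("same", "inverted"):
                score, chain = _best_chain(pool, orient, gap_open, gap_extend_per_rank, max_rank_gap)
                if len(chain) >= min_block_anchors and score > best_score + 1e-12:
                    best_score, best_chain_, best_orient = score, chain, orient
            if not best_chain_:
                break
            blocks.append(SyntenyBlock(ca, cb, best_chain_, best_orient, best_score))
            used_a = {x.a_gene for x in best_chain_}
            used_b = {x.b_gene for x in best_chain_}
            pool = [x for x in pool if x.a_gene not in used_a and x.b_gene not in used_b]
            if len(pool) < min_block_anchors:
                break
    return blocks


def build_homoeolog_table(
    blocks: list[SyntenyBlock],
    rbh_pairs: list[tuple[str, str]],
    hits: list[SimilarityHit],
    a_ids: set[str],
) -> list[HomoeologRecord]:
    """Merge evidence tiers into one table (synteny > rbh > homology supplement).

    ``hits`` supplies identity/coverage stats and the pool for the greedy
    supplement; a gene already paired is never re-paired.
    """
    stat: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query_id in a_ids:
            key = (h.query_id, h.subject_id)
            if key not in stat or h.score > stat[key].score:
                stat[key] = h
    records: list[HomoeologRecord] = []
    used: set[str] = set()

    def add(a: str, b: str, evidence: str) -> None:
        if a in used or b in used:
            return
        h = stat.get((a, b))
        records.append(HomoeologRecord(a, b, evidence,
                                       h.identity if h else 1.0, h.coverage if h else 1.0))
        used.add(a)
        used.add(b)

    for block in blocks:
        for anchor in block.anchors:
            add(anchor.a_gene, anchor.b_gene, "synteny")
    for a, b in rbh_pairs:
        add(a, b, "rbh")
    for h in sorted(hits, key=lambda h: (-h.score, -h.identity, h.query_id, h.subject_id)):
        a, b = (h.query_id, h.subject_id) if h.query_id in a_ids else (h.subject_id, h.query_id)
        add(a, b, "homology_supplement")
    return records


def confirm_specific(
    unpaired: list[GeneModel],
    own_sequences: dict[str, str],
    other_sequences: dict[str, str],
    presence_identity: float = 0.8,
    presence_coverage: float = 0.5,
    k: int = 12,
    min_shared_kmers: int = 2,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[SpecificGeneRecord]:
    """Cross-subgenome presence check for unpaired genes.

    A gene is confirmed specific iff no alignment against the other
    subgenome reaches BOTH presence thresholds (deliberately stricter than
    the pairing thresholds, so "specific" is conservative).  The best cross
    identity/coverage found is recorded either way.
    """
    seqs_q = {g.gene_id: own_sequences[g.sequence_key] for g in unpaired}
    cands = _candidate_pairs(seqs_q, other_sequences, k, min_shared_kmers)
    by_query: dict[str, list[str]] = defaultdict(list)
    for q, s in cands:
        by_query[q].append(s)
    out: list[SpecificGeneRecord] = []
    for g in sorted(unpaired, key=lambda x: x.gene_id):
        best_id, best_cov, present = 0.0, 0.0, False
        best_score = -1.0
        for sid in sorted(by_query.get(g.gene_id, ())):
            hit = align_pair(seqs_q[g.gene_id], other_sequences[sid], scoring)
            if hit.identity >= presence_identity and hit.coverage >= presence_coverage:
                present = True
            if hit.score > best_score:
                best_score = hit.score
                best_id, best_cov = hit.identity, hit.coverage
        if present:
            logger.info("unpaired gene %s has a cross-subgenome homolog; not confirmed specific", g.gene_id)
        out.append(SpecificGeneRecord(g.gene_id, g.subgenome, not present, best_id, best_cov))
    return out


def classify_genes(
    table: list[HomoeologRecord],
    specific_records: list[SpecificGeneRecord],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
) -> ClassificationSummary:
    """Partition every gene into paired / confirmed specific / unresolved."""
    paired_a = {r.a_gene for r in table}
    paired_b = {r.b_gene for r in table}
    if len(paired_a) != len(table) or len(paired_b) != len(table):
        raise RuntimeError("internal error: a gene appears in two homoeolog records")
    spec_a = {r.gene_id for r in specific_records if r.subgenome == "A" and r.confirmed}
    spec_b = {r.gene_id for r in specific_records if r.subgenome == "B" and r.confirmed}
    if (paired_a & spec_a) or (paired_b & spec_b):
        raise RuntimeError("internal error: gene classified both paired and specific")
    all_a, all_b = set(ann_a.gene_ids), set(ann_b.gene_ids)
    unresolved_a = all_a - paired_a - spec_a
    unresolved_b = all_b - paired_b - spec_b
    return ClassificationSummary(
        n_homoeolog_pairs=len(table),
        n_a_specific=len(spec_a),
        n_b_specific=len(spec_b),
        n_unresolved_a=len(unresolved_a),
        n_unresolved_b=len(unresolved_b),
        total_a=len(all_a),
        total_b=len(all_b),
    )


@dataclass
class HomologyConfig:
    identity_min: float = 0.6
    coverage_min: float = 0.2
    presence_identity: float = 0.8
    presence_coverage: float = 0.5
    kmer_size: int = 12
    min_shared_kmers: int = 3
    gap_open: float = 0.5
    gap_extend_per_rank: float = 0.1
    min_block_anchors: int = 3
    max_rank_gap: int = 25
    scoring: AlignScoring = field(default_factory=AlignScoring)


def identify_homoeologs(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    config: HomologyConfig | None = None,
) -> tuple[list[HomoeologRecord], list[SpecificGeneRecord], ClassificationSummary]:
    """End-to-end classification: hits -> synteny -> RBH -> supplement -> confirm."""
    cfg = config or HomologyConfig()
    seqs_a = {g.gene_id: ann_a.sequence_of(g.gene_id) for g in ann_a.iter_genes()}
    seqs_b = {g.gene_id: ann_b.sequence_of(g.gene_id) for g in ann_b.iter_genes()}
    hits = all_vs_all_hits(seqs_a, seqs_b, cfg.identity_min, cfg.coverage_min,
                           cfg.kmer_size, cfg.min_shared_kmers, cfg.scoring)
    a_ids = set(seqs_a)

    ranks_a, ranks_b = ann_a.ranks(), ann_b.ranks()
    chrom_of_a = {g.gene_id: g.chrom for g in ann_a.iter_genes()}
    chrom_of_b = {g.gene_id: g.chrom for g in ann_b.iter_genes()}
    anchors = [
        SyntenyAnchor(h.query_id, h.subject_id, ranks_a[h.query_id], ranks_b[h.subject_id],
                      chrom_of_a[h.query_id], chrom_of_b[h.subject_id])
        for h in hits if h.query_id in a_ids
    ]
    blocks = chain_anchors(anchors, cfg.gap_open, cfg.gap_extend_per_rank,
                           cfg.min_block_anchors, cfg.max_rank_gap)
    rbh = reciprocal_best_hits(hits, a_ids=a_ids)
    table = build_homoeolog_table(blocks, rbh, hits, a_ids)

    paired = {r.a_gene for r in table} | {r.b_gene for r in table}
    unpaired_a = [g for g in ann_a.iter_genes() if g.gene_id not in paired]
    unpaired_b = [g for g in ann_b.iter_genes() if g.gene_id not in paired]
    specific = confirm_specific(unpaired_a, ann_a.sequences, seqs_b,
                                cfg.presence_identity, cfg.presence_coverage,
                                cfg.kmer_size, scoring=cfg.scoring)
    specific += confirm_specific(unpaired_b, ann_b.sequences, seqs_a,
                                 cfg.presence_identity, cfg.presence_coverage,
                                 cfg.kmer_size, scoring=cfg.scoring)
    summary = classify_genes(table, specific, ann_a, ann_b)
    return table, specific, summary
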