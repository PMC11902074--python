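"""Flanking-interval analysis of subgenome-specific genes.

For each specific gene, the nearest paired (homoeolog) genes to its left and
right on its own chromosome serve as anchors; the interval between their
inner boundaries is measured on the carrier subgenome and between the
anchors' partners on the other subgenome.  A carrier interval clearly
enlarged relative to the other subgenome points to an insertion in the
carrier; an interval of comparable length combined with a confirmed absent
cross-subgenome homolog points to a gene loss in the other subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import HomoeologRecord, SpecificGeneRecord
from .io_formats import GenomeAnnotation

INSERTION, LOSS, AMBIGUOUS = "insertion", "loss", "ambiguous"


class Unanchorable(ValueError):
    """No flanking syntenic anchor within max_scan on one side."""


@dataclass
class FlankingInterval:
    specific_gene_id: str
    left_anchor: HomoeologRecord
    right_anchor: HomoeologRecord
    interval_len_carrier: int
    interval_len_other: int

    def __post_init__(self) -> None:
        if self.interval_len_carrier < 0 or self.interval_len_other < 0:
            raise ValueError("interval lengths must be >= 0")


@dataclass(frozen=True)
class OriginCall:
    specific_gene_id: str
    call: str  # insertion | loss | ambiguous
    length_ratio: float


def _partner_maps(table: list[HomoeologRecord]) -> tuple[dict[str, str], dict[str, str]]:
    a2b = {r.a_gene: r.b_gene for r in table}
    b2a = {r.b_gene: r.a_gene for r in table}
    return a2b, b2a


def flanking_interval(
    specific_gene_id: str,
    table: list[HomoeologRecord],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    max_scan: int = 10,
) -> FlankingInterval:
    """Nearest flanking anchors and the inter-anchor interval on both subgenomes.

    Scans outward up to ``max_scan`` genes per side for paired genes whose
    partners lie on a single chromosome of the other subgenome; raises
    :class:`Unanchorable` when a side has none.
    """
    a2b, b2a = _partner_maps(table)
    if specific_gene_id in ann_a:
        carrier, other = ann_a, ann_b
        partner_of = a2b
        carrier_on_table_a = True
    elif specific_gene_id in ann_b:
        carrier, other = ann_b, ann_a
        partner_of = b2a
        carrier_on_table_a = False
    else:
        raise KeyError(f"{specific_gene_id} not found in either annotation")
    gene = carrier.gene(specific_gene_id)
    row = carrier.genes[gene.chrom]
    idx = next(i for i, g in enumerate(row) if g.gene_id == specific_gene_id)
    rec_of = {(r.a_gene if carrier_on_table_a else r.b_gene): r for r in table}

    def scan(step: int):
        j = idx + step
        steps = 0
        while 0 <= j < len(row) and steps < max_scan:
            gid = row[j].gene_id
            if gid in partner_of:
                return row[j], carrier.gene(gid), other.gene(partner_of[gid]), rec_of[gid]
            j += step
            steps += 1
        return None

    left = scan(-1)
    right = scan(+1)
    if left is None or right is None:
        raise Unanchorable(f"{specific_gene_id}: no flanking anchor within {max_scan} genes")
    _, lg, lp, lrec = left
    _, rg, rp, rrec = right
    if lp.chrom != rp.chrom:
        raise Unanchorable(f"{specific_gene_id}: flanking anchors map to different chromosomes")
    carrier_len = max(0, rg.start - lg.end)
    if lp.start <= rp.start:
        other_len = max(0, rp.start - lp.end)
    else:
        other_len = max(0, lp.start - rp.end)
    return FlankingInterval(specific_gene_id, lrec, rrec, carrier_len, other_len)


def call_origin(
    interval: FlankingInterval,
    confirmed_absent: bool,
    insertion_ratio_min: float = 1.5,
    pseudo_bp: int = 100,
) -> OriginCall:
    """Insertion/loss/ambiguous call from the interval length ratio.

    ratio = (carrier + pseudo) / (other + pseudo).  ratio >= threshold is an
    insertion; otherwise a loss requires the specific gene to be confirmed
    absent cross-subgenome; anything else is ambiguous.  The pseudo-count
    keeps adjacent anchors with zero spacer well-defined.
    """
    ratio = (interval.interval_len_carrier + pseudo_bp) / (interval.interval_len_other + pseudo_bp)
    if ratio >= insertion_ratio_min:
        call = INSERTION
    elif confirmed_absent:
        call = LOSS
    else:
        call = AMBIGUOUS
    return OriginCall(interval.specific_gene_id, call, ratio)


def analyze_specific_genes(
    specific_records: list[SpecificGeneRecord],
    table: list[HomoeologRecord],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    max_scan: int = 10,
    insertion_ratio_min: float = 1.5,
    pseudo_bp: int = 100,
) -> tuple[list[FlankingInterval], list[OriginCall], list[str]]:
    """Intervals + origin calls for all confirmed specific genes.

    Returns (intervals, calls, unanchorable gene ids); unanchorable genes
    are excluded from origin calling rather than guessed.
    """
    intervals: list[FlankingInterval] = []
    calls: list[OriginCall] = []
    unanchorable: list[str] = []
    confirmed = {r.gene_id: r for r in specific_records if r.confirmed}
    for gid in sorted(confirmed):
        try:
            iv = flanking_interval(gid, table, ann_a, ann_b, max_scan)
        except Unanchorable:
            unanchorable.append(gid)
            continue
        intervals.append(iv)
        calls.append(call_origin(iv, True, insertion_ratio_min, pseudo_bp))
    return intervals, calls, unanchorable


def plot_locus(interval: FlankingInterval, ann_a: GenomeAnnotation, ann_b: GenomeAnnotation,
               path) -> None:
    """Two-track coordinate sketch of a specific gene and its flanking anchors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    carrier_ann = ann_a if interval.specific_gene_id in ann_a else ann_b
    other_ann = ann_b if carrier_ann is ann_a else ann_a
    on_a = carrier_ann.subgenome == "A"
    l, r = interval.left_anchor, interval.right_anchor
    carrier_genes = [carrier_ann.gene(l.a_gene if on_a else l.b_gene),
                     carrier_ann.gene(interval.specific_gene_id),
                     carrier_ann.gene(r.a_gene if on_a else r.b_gene)]
    other_genes = [other_ann.gene(l.b_gene if on_a else l.a_gene),
                   other_ann.gene(r.b_gene if on_a else r.a_gene)]
    fig, ax = plt.subplots(figsize=(8, 2.5))
    for y, genes, label in ((1.0, carrier_genes, f"{carrier_ann.subgenome} (carrier)"),
                            (0.0, other_genes, other_ann.subgenome)):
        origin = min(g.start for g in genes)
        for g in genes:
            color = "crimson" if g.gene_id == interval.specific_gene_id else "steelblue"
            ax.barh(y, g.length, left=g.start - origin, height=0.25, color=color)
            ax.text(g.start - origin, y + 0.18, g.gene_id, fontsize=6, rotation=20)
        ax.text(-0.01, y, label, transform=ax.get_yaxis_transform(), ha="right", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel("bp (locus-relative)")
    ax.set_title(interval.specific_gene_id, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
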