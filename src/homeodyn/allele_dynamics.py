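"""Homoeolog expression balance and pathway-level allele summaries.

For each homoeolog pair and stage, the A:B balance is the log2 ratio of
stage-mean FPKM (pseudo-count 0.5 per side).  |ratio| <= 1 is *balanced*,
beyond that the higher allele dominates; pairs with both alleles below the
expression floor are *not_expressed* and excluded from the per-stage
fractions.  Pathway tables (user-supplied memberships) are summarized by
counts of DE subgenome-specific alleles and by an upper-tail
hypergeometric enrichment test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import DegResult
from .homology import HomoeologRecord, SpecificGeneRecord

logger = logging.getLogger(__name__)

BALANCED, A_DOMINANT, B_DOMINANT, NOT_EXPRESSED = (
    "balanced", "A_dominant", "B_dominant", "not_expressed")


@dataclass(frozen=True)
class BiasCall:
    a_gene: str
    b_gene: str
    stage: str
    log2_ab_ratio: float
    call: str


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    k: int  # DE genes in the set
    K: int  # set size
    n: int  # DE genes in the universe
    N: int  # universe size
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k exceeds min(K, n)")


def bias_call(
    pair: HomoeologRecord,
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    stage: str,
    design,
    bias_threshold: float = 1.0,
    min_expr: float = 1.0,
) -> BiasCall:
    """A/B balance of one homoeolog pair at one stage.

    FPKM frames are genes x samples; means are taken over the stage's
    replicate columns.
    """
    for df, gid in ((fpkm_a, pair.a_gene), (fpkm_b, pair.b_gene)):
        if gid not in df.index:
            raise KeyError(f"gene {gid} absent from FPKM matrix")
    cols = design.samples_for_stage(stage)
    mean_a = float(fpkm_a.loc[pair.a_gene, cols].mean())
    mean_b = float(fpkm_b.loc[pair.b_gene, cols].mean())
    ratio = float(np.log2((mean_a + 0.5) / (mean_b + 0.5)))
    if mean_a < min_expr and mean_b < min_expr:
        call = NOT_EXPRESSED
    elif abs(ratio) <= bias_threshold:
        call = BALANCED
    else:
        call = A_DOMINANT if ratio > 0 else B_DOMINANT
    return BiasCall(pair.a_gene, pair.b_gene, stage, ratio, call)


def bias_table(
    pairs: list[HomoeologRecord],
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    design,
    bias_threshold: float = 1.0,
    min_expr: float = 1.0,
) -> list[BiasCall]:
    """Bias calls for every pair at every stage of the design."""
    return [
        bias_call(p, fpkm_a, fpkm_b, stage, design, bias_threshold, min_expr)
        for stage in design.stages
        for p in pairs
    ]


def bias_summary(calls: list[BiasCall]) -> pd.DataFrame:
    """Per-stage fractions of balanced / A_dominant / B_dominant over expressed pairs."""
    rows = []
    by_stage: dict[str, list[BiasCall]] = {}
    for c in calls:
        by_stage.setdefault(c.stage, []).append(c)
    for stage in by_stage:
        expressed = [c for c in by_stage[stage] if c.call != NOT_EXPRESSED]
        n = len(expressed)
        row = {"stage": stage, "n_expressed": n}
        for cls in (BALANCED, A_DOMINANT, B_DOMINANT):
            row[f"frac_{cls}"] = (sum(c.call == cls for c in expressed) / n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def read_pathways(path) -> dict[str, set[str]]:
    """TSV with columns pathway_id, gene_id -> {pathway: gene set}."""
    df = pd.read_csv(path, sep="\t")
    if not {"pathway_id", "gene_id"} <= set(df.columns):
        raise ValueError("pathway table needs pathway_id and gene_id columns")
    out: dict[str, set[str]] = {}
    for pid, sub in df.groupby("pathway_id"):
        out[str(pid)] = set(sub["gene_id"].astype(str))
    if any(not genes for genes in out.values()):
        raise ValueError("empty pathway set")
    return out


def pathway_specific_allele_counts(
    specific_records: list[SpecificGeneRecord],
    stagewise: dict[tuple[str, str], list[DegResult]],
    pathways: dict[str, set[str]],
    known_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-pathway counts of subgenome-specific genes, split by DE status.

    DE = flagged in at least one comparison.  Pathway members not present in
    ``known_genes`` (when given) are warned about and ignored.
    """
    de_union: set[str] = set()
    for results in stagewise.values():
        de_union |= {r.gene_id for r in results if r.is_de}
    spec = {r.gene_id: r.subgenome for r in specific_records if r.confirmed}
    rows = []
    for pid in sorted(pathways):
        genes = pathways[pid]
        if known_genes is not None:
            unknown = genes - known_genes
            if unknown:
                logger.warning("pathway %s references %d unknown genes; ignored", pid, len(unknown))
                genes = genes & known_genes
        row = {"pathway_id": pid, "n_genes": len(genes),
               "a_specific_de": 0, "a_specific_not_de": 0,
               "b_specific_de": 0, "b_specific_not_de": 0}
        for g in genes:
            sub = spec.get(g)
            if sub is None:
                continue
            key = f"{sub.lower()}_specific_{'de' if g in de_union else 'not_de'}"
            row[key] += 1
        rows.append(row)
    return pd.DataFrame(rows)


def hypergeometric_enrichment(
    de_set: set[str],
    pathways: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test P(X >= k) per pathway, BH-adjusted."""
    if not universe:
        raise ValueError("empty universe")
    if not de_set <= universe:
        raise ValueError("de_set must be a subset of the universe")
    N = len(universe)
    n = len(de_set)
    results = []
    pvals = []
    for pid in sorted(pathways):
        genes = pathways[pid] & universe
        K = len(genes)
        k = len(genes & de_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        pvals.append(min(p, 1.0))
        results.append((pid, k, K))
    padj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return [
        EnrichmentResult(pid, k, K, n, N, p, float(q))
        for (pid, k, K), p, q in zip(results, pvals, padj)
    ]
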