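"""qPCR relative quantification (ddCt) and RNA-seq concordance.

dCt = Ct(target) - Ct(reference gene) per replicate; ddCt is the stage-mean
dCt minus the calibrator stage's mean dCt; relative expression = 2**(-ddCt)
with amplification efficiency fixed at 2.  Replicates are aggregated on the
dCt scale (mean and SD) before exponentiation, so the reported spread is
symmetric in cycles, not in fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    gene_id: str
    stage: str
    replicate: int
    ct_target: float
    ct_reference: float


def delta_delta_ct(records: list[CtRecord], calibrator_stage: str = "0M") -> pd.DataFrame:
    """Relative expression per gene x stage via the ddCt method.

    Returns columns gene_id, stage, delta_ct_mean, delta_ct_sd, ddct,
    rel_expr, rel_expr_lo, rel_expr_hi (the lo/hi bounds are +-1 SD on the
    dCt scale).  Records with a missing reference Ct are skipped with a
    warning; a gene without the calibrator stage is an error.
    """
    usable: list[CtRecord] = []
    for r in records:
        if not (math.isfinite(r.ct_target) and math.isfinite(r.ct_reference)):
            logger.warning("skipping %s %s rep %d: missing Ct", r.gene_id, r.stage, r.replicate)
            continue
        usable.append(r)
    dct: dict[tuple[str, str], list[float]] = {}
    for r in usable:
        dct.setdefault((r.gene_id, r.stage), []).append(r.ct_target - r.ct_reference)
    genes = sorted({g for g, _ in dct})
    rows = []
    for gene in genes:
        if (gene, calibrator_stage) not in dct:
            raise ValueError(f"gene {gene}: calibrator stage {calibrator_stage!r} missing")
        cal = float(np.mean(dct[(gene, calibrator_stage)]))
        for (g, stage), values in sorted(dct.items()):
            if g != gene:
                continue
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
            ddct = mean - cal
            rows.append({
                "gene_id": gene,
                "stage": stage,
                "delta_ct_mean": mean,
                "delta_ct_sd": sd,
                "ddct": ddct,
                "rel_expr": 2.0 ** (-ddct),
                "rel_expr_lo": 2.0 ** (-(ddct + sd)),
                "rel_expr_hi": 2.0 ** (-(ddct - sd)),
            })
    return pd.DataFrame(rows)


def qpcr_rnaseq_concordance(
    rel_expr: pd.DataFrame,
    fpkm_stage_means: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Pearson and Spearman correlation across stages, log2 scale.

    ``rel_expr`` is the output of :func:`delta_delta_ct`;
    ``fpkm_stage_means`` is genes x stages.  Both sides are compared on the
    log2 scale; stages where a gene's FPKM is not positive are dropped for
    that gene (log undefined there).  Genes with zero variance on either
    side get NaN correlations.
    """
    rows = []
    wide = rel_expr.pivot(index="gene_id", columns="stage", values="rel_expr")
    for gene in wide.index:
        if gene not in fpkm_stage_means.index:
            continue
        stages = [s for s in wide.columns if s in fpkm_stage_means.columns
                  and math.isfinite(wide.loc[gene, s])
                  and fpkm_stage_means.loc[gene, s] > 0]
        if len(stages) < 3:
            raise ValueError(f"gene {gene}: fewer than 3 shared stages")
        x = np.log2(wide.loc[gene, stages].to_numpy(dtype=float))
        y = np.log2(fpkm_stage_means.loc[gene, stages].to_numpy(dtype=float))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pearson = spearman = float("nan")
        else:
            pearson = float(stats.pearsonr(x, y).statistic)
            spearman = float(stats.spearmanr(x, y).statistic)
        rows.append({"gene_id": gene, "n_stages": len(stages),
                     "pearson_r": pearson, "spearman_r": spearman})
    return pd.DataFrame(rows)


def read_ct_table(path) -> list[CtRecord]:
    """TSV with columns gene_id, stage, replicate, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "stage", "replicate", "ct_target", "ct_reference"}
    if not needed <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(needed)}")
    return [
        CtRecord(str(r.gene_id), str(r.stage), int(r.replicate),
                 float(r.ct_target), float(r.ct_reference))
        for r in df.itertuples()
    ]
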