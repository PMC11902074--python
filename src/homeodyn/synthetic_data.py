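"""Synthetic allopolyploid subgenome pairs with stage-structured counts.

The generator lays out an ancestral gene array per chromosome, diverges two
subgenome copies (A and B) by i.i.d. substitutions, then applies
lineage-specific structural events:

* **insertion** — a novel-sequence gene is inserted into an intergenic
  spacer of one subgenome, widening the interval between its flanking
  ancestral genes by exactly the inserted gene's length;
* **loss** — a gene is removed from one subgenome's annotation while its
  genomic span is retained as relic intergenic DNA, so flanking intervals
  stay (nearly) equal between subgenomes but the homolog is absent.

That asymmetry is what the synteny-context stage must detect to separate
insertion-origin from loss-origin subgenome-specific genes.  Event loci are
placed at least two ancestral genes apart so each event's local context is
unambiguous.

Counts are negative-binomial with gene-wise baseline means shared within a
homoeolog pair, stage-specific fold changes for planted DE genes, a constant
subgenome fold for planted biased pairs, and per-sample library-size
factors.  Both returned matrices are indexed by the union of A and B gene
ids; a gene absent from a subgenome has an all-zero row in that subgenome's
matrix (the analogue of quantifying reads against one reference at a time).

Everything is reproducible from one seed; independent substreams are spawned
per operation so structure and counts can be regenerated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SampleDesign
from .io_formats import GeneModel, GenomeAnnotation

ORIGIN_INSERTION = "insertion"
ORIGIN_LOSS = "loss"
BALANCED, A_DOMINANT, B_DOMINANT = "balanced", "A_dominant", "B_dominant"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationParams:
    """Knobs of the generator.

    Defaults model a small allopolyploid fixture: 2 chromosomes x 200 genes,
    5% per-copy substitution divergence, 20 insertions and 10 losses per
    subgenome, log-uniform NB means on [5, 500] with dispersion 0.1, 10% DE
    per stage transition at |log2FC| in [1, 3], and a homoeolog-bias
    composition dominated by the A subgenome (10% A-dominant, 2% B-dominant)
    as seen in ABB banana.
    """

    n_chrom: int = 2
    genes_per_chrom: int = 200
    mean_gene_len: int = 900
    substitution_rate: float = 0.05
    n_insertions_a: int = 20
    n_deletions_b: int = 10
    n_insertions_b: int = 20
    n_deletions_a: int = 10
    spacer_range: tuple[int, int] = (100, 500)
    mean_expr_range: tuple[float, float] = (5.0, 500.0)
    dispersion: float = 0.1
    de_fraction: float = 0.10
    de_log2fc_range: tuple[float, float] = (1.0, 3.0)
    bias_fraction_a: float = 0.10
    bias_fraction_b: float = 0.02
    bias_log2fc: float = 2.0
    size_factor_range: tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "genes_per_chrom", "mean_gene_len",
                     "n_insertions_a", "n_deletions_b", "n_insertions_b", "n_deletions_a"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("de_fraction", "bias_fraction_a", "bias_fraction_b"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bias_fraction_a + self.bias_fraction_b > 1.0:
            raise ValueError("bias fractions sum above 1")


@dataclass
class TruthTable:
    """Ground truth of one simulated genome pair.

    ``a_specific``/``b_specific`` map gene id -> origin (insertion | loss);
    ``de_genes`` maps a (numerator, denominator) stage comparison to
    {gene_id: true log2FC}; ``bias_genes`` maps the A-side gene id of each
    homoeolog pair to its planted bias class.
    """

    homoeolog_pairs: set[tuple[str, str]] = field(default_factory=set)
    a_specific: dict[str, str] = field(default_factory=dict)
    b_specific: dict[str, str] = field(default_factory=dict)
    de_genes: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    bias_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        paired_a = {a for a, _ in self.homoeolog_pairs}
        paired_b = {b for _, b in self.homoeolog_pairs}
        if paired_a & set(self.a_specific) or paired_b & set(self.b_specific):
            raise ValueError("specific genes overlap homoeolog pairs")

    @property
    def all_a_genes(self) -> set[str]:
        return {a for a, _ in self.homoeolog_pairs} | set(self.a_specific)

    @property
    def all_b_genes(self) -> set[str]:
        return {b for _, b in self.homoeolog_pairs} | set(self.b_specific)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=n)
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def _draw_len(rng: np.random.Generator, mean_len: int) -> int:
    lo, hi = max(30, (2 * mean_len) // 3), (4 * mean_len) // 3
    return int(rng.integers(lo, hi + 1))


def _pick_separated(rng: np.random.Generator, n_slots: int, n_pick: int, min_sep: int = 2) -> list[int]:
    """Pick n_pick slot indices pairwise >= min_sep apart.

    Uniform via the standard stars-and-bars bijection: choose from a
    contracted range, then re-expand by the mandatory gaps.
    """
    if n_pick == 0:
        return []
    contracted = n_slots - (n_pick - 1) * (min_sep - 1)
    if contracted < n_pick:
        raise ValueError("cannot place structural events with required separation; too many events")
    picks = sorted(rng.choice(contracted, size=n_pick, replace=False).tolist())
    return [p + i * (min_sep - 1) for i, p in enumerate(picks)]


def simulate_subgenomes(params: SimulationParams) -> tuple[GenomeAnnotation, GenomeAnnotation, TruthTable]:
    """Generate diverged A/B annotations + sequences and the ground truth."""
    n_events = (params.n_insertions_a + params.n_insertions_b
                + params.n_deletions_a + params.n_deletions_b)
    total_genes = params.n_chrom * params.genes_per_chrom
    if params.n_deletions_a + params.n_deletions_b > total_genes:
        raise ValueError("more deletions than ancestral genes")
    if n_events * 2 > total_genes:
        raise ValueError("insertions+deletions exceed what the gene count can host")

    ss = np.random.SeedSequence(params.seed)
    rng_seq, rng_layout, rng_events = (np.random.default_rng(s) for s in ss.spawn(3))

    # global event assignment: each event occupies one ancestral slot (chrom, idx)
    slots = [(c, i) for c in range(params.n_chrom) for i in range(params.genes_per_chrom)]
    flat_picks = _pick_separated(rng_events, len(slots), n_events)
    picked = [slots[i] for i in flat_picks]
    rng_events.shuffle(picked)
    kinds = (["ins_a"] * params.n_insertions_a + ["ins_b"] * params.n_insertions_b
             + ["del_a"] * params.n_deletions_a + ["del_b"] * params.n_deletions_b)
    events = dict(zip(picked, kinds))

    genes_a: dict[str, list[GeneModel]] = {}
    genes_b: dict[str, list[GeneModel]] = {}
    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}
    truth = TruthTable()
    n_ins = 0

    for c in range(params.n_chrom):
        chrom_a, chrom_b = f"chrA{c + 1:02d}", f"chrB{c + 1:02d}"
        genes_a[chrom_a], genes_b[chrom_b] = [], []
        n = params.genes_per_chrom
        lengths = [_draw_len(rng_layout, params.mean_gene_len) for _ in range(n)]
        # spacers[i] precedes ancestral gene i; spacers[n] trails the chromosome
        spacers = [int(rng_layout.integers(*params.spacer_range)) for _ in range(n + 1)]
        strands = ["+" if rng_layout.random() < 0.5 else "-" for _ in range(n)]
        pos_a = pos_b = 0
        for i in range(n):
            anc_id = f"g{c + 1:02d}_{i + 1:04d}"
            length = lengths[i]
            anc_seq = _random_seq(rng_seq, length)
            seq_a = _mutate(rng_seq, anc_seq, params.substitution_rate)
            seq_b = _mutate(rng_seq, anc_seq, params.substitution_rate)
            pos_a += spacers[i]
            pos_b += spacers[i]
            event = events.get((c, i))
            id_a, id_b = f"MA_{anc_id}", f"MB_{anc_id}"
            if event == "del_a":
                # lost in A: span retained as relic, gene only annotated in B
                genes_b[chrom_b].append(GeneModel(id_b, chrom_b, pos_b, pos_b + length, strands[i], "B"))
                seqs_b[id_b] = seq_b
                truth.b_specific[id_b] = ORIGIN_LOSS
            elif event == "del_b":
                genes_a[chrom_a].append(GeneModel(id_a, chrom_a, pos_a, pos_a + length, strands[i], "A"))
                seqs_a[id_a] = seq_a
                truth.a_specific[id_a] = ORIGIN_LOSS
            else:
                genes_a[chrom_a].append(GeneModel(id_a, chrom_a, pos_a, pos_a + length, strands[i], "A"))
                genes_b[chrom_b].append(GeneModel(id_b, chrom_b, pos_b, pos_b + length, strands[i], "B"))
                seqs_a[id_a] = seq_a
                seqs_b[id_b] = seq_b
                truth.homoeolog_pairs.add((id_a, id_b))
            pos_a += length
            pos_b += length
            if event in ("ins_a", "ins_b"):
                # novel gene splits the following inter-gene spacer, so the
                # carrier's flanking interval grows by exactly its length
                nxt = spacers[i + 1]
                cut = int(rng_layout.integers(0, nxt + 1))
                ins_len = _draw_len(rng_layout, params.mean_gene_len)
                ins_strand = "+" if rng_layout.random() < 0.5 else "-"
                ins_seq = _random_seq(rng_seq, ins_len)
                n_ins += 1
                if event == "ins_a":
                    ins_id = f"MA_ins_{n_ins:04d}"
                    genes_a[chrom_a].append(
                        GeneModel(ins_id, chrom_a, pos_a + cut, pos_a + cut + ins_len, ins_strand, "A"))
                    seqs_a[ins_id] = ins_seq
                    truth.a_specific[ins_id] = ORIGIN_INSERTION
                    pos_a += ins_len
                else:
                    ins_id = f"MB_ins_{n_ins:04d}"
                    genes_b[chrom_b].append(
                        GeneModel(ins_id, chrom_b, pos_b + cut, pos_b + cut + ins_len, ins_strand, "B"))
                    seqs_b[ins_id] = ins_seq
                    truth.b_specific[ins_id] = ORIGIN_INSERTION
                    pos_b += ins_len

    ann_a = GenomeAnnotation(subgenome="A", genes=genes_a, sequences=seqs_a)
    ann_b = GenomeAnnotation(subgenome="B", genes=genes_b, sequences=seqs_b)
    ann_a.validate_sequences()
    ann_b.validate_sequences()
    return ann_a, ann_b, truth


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    truth: TruthTable,
    design: SampleDesign,
    params: SimulationParams,
    annotations: tuple[GenomeAnnotation, GenomeAnnotation] | None = None,
) -> tuple[CountMatrix, CountMatrix]:
    """NB counts for both subgenomes under the planted DE/bias structure.

    Homoeolog pairs share a baseline mean; planted DE applies the same fold
    to both alleles (co-regulated homoeologs); planted bias multiplies one
    allele's mean by ``2**bias_log2fc`` at every stage.  If ``annotations``
    are supplied, gene lengths are attached for FPKM.
    """
    ss = np.random.SeedSequence((params.seed, 815))
    rng_mu, rng_de, rng_bias, rng_counts = (np.random.default_rng(s) for s in ss.spawn(4))

    pairs = sorted(truth.homoeolog_pairs)
    a_spec = sorted(truth.a_specific)
    b_spec = sorted(truth.b_specific)
    # expression units: one per pair, one per specific gene
    units: list[tuple[str, str | None]] = [(a, b) for a, b in pairs]
    units += [(g, None) for g in a_spec] + [(None, g) for g in b_spec]  # type: ignore[list-item]

    lo, hi = params.mean_expr_range
    base_mu = np.exp(rng_mu.uniform(np.log(lo), np.log(hi), size=len(units)))

    # planted bias on pairs (constant across stages)
    truth.bias_genes.clear()
    n_pairs = len(pairs)
    n_bias_a = int(round(params.bias_fraction_a * n_pairs))
    n_bias_b = int(round(params.bias_fraction_b * n_pairs))
    order = rng_bias.permutation(n_pairs)
    bias_a_idx = set(order[:n_bias_a].tolist())
    bias_b_idx = set(order[n_bias_a : n_bias_a + n_bias_b].tolist())
    for j, (a, _b) in enumerate(pairs):
        truth.bias_genes[a] = A_DOMINANT if j in bias_a_idx else B_DOMINANT if j in bias_b_idx else BALANCED

    # stage means per unit: random-walk of planted fold changes along stages
    stage_mu = {design.stages[0]: base_mu.copy()}
    truth.de_genes.clear()
    for num, den in design.consecutive_comparisons:
        prev = stage_mu[den]
        cur = prev.copy()
        n_de = int(round(params.de_fraction * len(units)))
        de_idx = rng_de.choice(len(units), size=n_de, replace=False)
        lfc_lo, lfc_hi = params.de_log2fc_range
        lfcs = rng_de.uniform(lfc_lo, lfc_hi, size=n_de) * rng_de.choice([-1.0, 1.0], size=n_de)
        cur[de_idx] = prev[de_idx] * np.exp2(lfcs)
        stage_mu[num] = cur
        comp = {}
        for j, lfc in zip(de_idx.tolist(), lfcs.tolist()):
            a, b = units[j]
            if a is not None:
                comp[a] = lfc
            if b is not None:
                comp[b] = lfc
        truth.de_genes[(num, den)] = comp

    bias_mult = float(np.exp2(params.bias_log2fc))
    all_ids = sorted(truth.all_a_genes | truth.all_b_genes)
    row_of = {g: i for i, g in enumerate(all_ids)}
    samples = design.sample_ids
    size_factors = rng_counts.uniform(*params.size_factor_range, size=len(samples))

    mat_a = np.zeros((len(all_ids), len(samples)), dtype=np.int64)
    mat_b = np.zeros_like(mat_a)
    for si, sample in enumerate(samples):
        stage = design.stage_of(sample)
        mu = stage_mu[stage] * size_factors[si]
        mu_a = mu.copy()
        mu_b = mu.copy()
        for j, (a, b) in enumerate(units):
            if a is not None and b is not None:
                cls = truth.bias_genes[a]
                if cls == A_DOMINANT:
                    mu_a[j] *= bias_mult
                elif cls == B_DOMINANT:
                    mu_b[j] *= bias_mult
        draws_a = _nb_draws(rng_counts, mu_a, params.dispersion)
        draws_b = _nb_draws(rng_counts, mu_b, params.dispersion)
        for j, (a, b) in enumerate(units):
            if a is not None:
                mat_a[row_of[a], si] = draws_a[j]
            if b is not None:
                mat_b[row_of[b], si] = draws_b[j]

    lengths = None
    if annotations is not None:
        ann_a, ann_b = annotations
        lens = {}
        for ann in (ann_a, ann_b):
            for g in ann.iter_genes():
                lens[g.gene_id] = float(g.length)
        lengths = pd.Series([lens.get(g, np.nan) for g in all_ids], index=all_ids)

    cm_a = CountMatrix(pd.DataFrame(mat_a, index=all_ids, columns=samples), design, lengths)
    cm_b = CountMatrix(pd.DataFrame(mat_b, index=all_ids, columns=samples), design,
                       None if lengths is None else lengths.copy())
    return cm_a, cm_b


def simulate_two_group(
    n_genes: int,
    n_per_group: int = 3,
    dispersion: float = 0.1,
    mean: float | tuple[float, float] | None = None,
    lfc: dict[int, float] | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Small two-condition NB matrix for DE-calibration studies.

    ``mean`` is a fixed mean or a (lo, hi) log-uniform range (default
    (10, 1000)); ``lfc`` plants log2 fold changes (group2 vs group1) on the
    given row indices.  Returns a matrix under a 2-stage design g1/g2.
    """
    rng = np.random.default_rng(seed)
    design = SampleDesign(stages=("g1", "g2"), replicates=n_per_group)
    if mean is None:
        mean = (10.0, 1000.0)
    if isinstance(mean, tuple):
        mu = np.exp(rng.uniform(np.log(mean[0]), np.log(mean[1]), size=n_genes))
    else:
        mu = np.full(n_genes, float(mean))
    mu2 = mu.copy()
    for idx, l2 in (lfc or {}).items():
        mu2[idx] = mu[idx] * 2.0 ** l2
    cols = {}
    for s in design.sample_ids:
        m = mu if design.stage_of(s) == "g1" else mu2
        cols[s] = _nb_draws(rng, m, dispersion)
    ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    return CountMatrix(pd.DataFrame(cols, index=ids), design)


def write_truth_tables(truth: TruthTable, outdir) -> None:
    """Dump the ground truth as TSVs (pairs, specifics, DE, bias)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(truth.homoeolog_pairs), columns=["a_gene", "b_gene"]).to_csv(
        outdir / "truth_pairs.tsv", sep="\t", index=False)
    rows = [{"gene_id": g, "subgenome": "A", "origin": o} for g, o in sorted(truth.a_specific.items())]
    rows += [{"gene_id": g, "subgenome": "B", "origin": o} for g, o in sorted(truth.b_specific.items())]
    pd.DataFrame(rows, columns=["gene_id", "subgenome", "origin"]).to_csv(
        outdir / "truth_specific.tsv", sep="\t", index=False)
    de_rows = [
        {"comparison": f"{num}_vs_{den}", "gene_id": g, "log2fc": l}
        for (num, den), genes in sorted(truth.de_genes.items())
        for g, l in sorted(genes.items())
    ]
    pd.DataFrame(de_rows, columns=["comparison", "gene_id", "log2fc"]).to_csv(
        outdir / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"a_gene": g, "bias": c} for g, c in sorted(truth.bias_genes.items())],
        columns=["a_gene", "bias"],
    ).to_csv(outdir / "truth_bias.tsv", sep="\t", index=False)
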