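"""Two-condition differential quantification of polyadenylated read counts.

Per-gene counts from two libraries are compared with an exact conditional
binomial test: given the gene's total count n = c1 + c2, c2 is binomial
with success probability s2/(s1+s2) under the null of equal normalized
expression, where s1 and s2 are the library sizes.  P-values are adjusted
by the Benjamini-Hochberg step-up procedure and genes are classified as
up / down / nc by a 2-fold-change threshold; by default the call also
requires q <= 0.05, and ``fold_only=True`` reproduces pure fold-change
classification.  Replicate-aware dispersion modeling is out of scope: the
test conditions on two libraries, one per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Per-gene counts for two conditions plus per-condition library sizes.

    Counts may cover only a gene subset, so library sizes are stored
    explicitly rather than derived from column sums.
    """

    counts: pd.DataFrame  # index gene_id, one column per condition
    lib_sizes: dict[str, float]

    def __post_init__(self) -> None:
        if self.counts.shape[1] != 2:
            raise ValueError("exactly two condition columns are required")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        for cond in self.counts.columns:
            if cond not in self.lib_sizes:
                raise ValueError(f"missing library size for condition {cond!r}")
            if self.lib_sizes[cond] <= 0:
                raise ValueError(f"library size for {cond!r} must be positive")

    @property
    def conditions(self) -> tuple[str, str]:
        c1, c2 = self.counts.columns
        return str(c1), str(c2)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            sizes = ",".join(f"{c}={self.lib_sizes[c]:g}" for c in self.counts.columns)
            fh.write(f"#library_sizes\t{sizes}\n")
            self.counts.rename_axis("gene_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 lib_sizes: Optional[dict[str, float]] = None) -> "CountMatrix":
        path = Path(path)
        header_sizes: dict[str, float] = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#library_sizes"):
                for kv in first.rstrip("\n").split("\t")[1].split(","):
                    k, v = kv.split("=")
                    header_sizes[k] = float(v)
                counts = pd.read_csv(fh, sep="\t", index_col="gene_id")
            else:
                fh.seek(0)
                counts = pd.read_csv(fh, sep="\t", index_col="gene_id")
        sizes = lib_sizes or header_sizes
        if not sizes:
            sizes = {c: float(counts[c].sum()) for c in counts.columns}
        return cls(counts=counts, lib_sizes=sizes)


@dataclass
class DiffResult:
    gene_id: str
    count1: int
    count2: int
    log2_fold_change: float
    p_value: float
    q_value: float
    call: str  # up | down | nc


def normalize(lib_sizes: Sequence[float]) -> list[float]:
    """Total-count size factors: library size over geometric mean of sizes."""
    sizes = [float(s) for s in lib_sizes]
    if any(s <= 0 for s in sizes):
        raise ValueError("library sizes must be positive")
    gm = math.exp(sum(math.log(s) for s in sizes) / len(sizes))
    return [s / gm for s in sizes]


def test_gene(count1: int, count2: int, size1: float, size2: float) -> float:
    """Exact two-sided conditional binomial test of count2 vs count1.

    Under equal normalized expression, count2 | (count1 + count2) is
    binomial with p = size2 / (size1 + size2).  Returns 1 for a 0/0 gene.
    """
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    if size1 <= 0 or size2 <= 0:
        raise ValueError("library sizes must be positive")
    n = count1 + count2
    if n == 0:
        return 1.0
    p = size2 / (size1 + size2)
    return float(stats.binomtest(count2, n, p, alternative="two-sided").pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(count1: int, count2: int, factor1: float = 1.0,
                     factor2: float = 1.0) -> float:
    """Size-factor-normalized log2(condition2 / condition1).

    A 0.5 pseudocount is added to both counts only when either is zero, so
    fold changes stay finite without perturbing well-covered genes.
    """
    c1, c2 = float(count1), float(count2)
    if c1 == 0 or c2 == 0:
        c1, c2 = c1 + 0.5, c2 + 0.5
    return math.log2((c2 / factor2) / (c1 / factor1))


def classify(log2fc: float, q: float, fc_threshold: float = 2.0,
             q_threshold: float = 0.05, fold_only: bool = False) -> str:
    """Classify a gene as up / down / nc.

    '2-fold or more' is inclusive: |log2fc| >= log2(fc_threshold) together
    with q <= q_threshold (unless ``fold_only``).
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc_cut = math.log2(fc_threshold)
    significant = fold_only or q <= q_threshold
    if log2fc >= lfc_cut and significant:
        return "up"
    if log2fc <= -lfc_cut and significant:
        return "down"
    return "nc"


def run_differential(matrix: CountMatrix, fc_threshold: float = 2.0,
                     q_threshold: float = 0.05,
                     fold_only: bool = False) -> pd.DataFrame:
    """Full differential-polyadenylation analysis on a count matrix.

    Returns a DataFrame of per-gene results sorted by q-value (ties keep
    gene order stable), with condition2-vs-condition1 orientation.
    """
    c1, c2 = matrix.conditions
    s1, s2 = matrix.lib_sizes[c1], matrix.lib_sizes[c2]
    f1, f2 = normalize([s1, s2])
    genes = list(matrix.counts.index)
    n1 = matrix.counts[c1].to_numpy()
    n2 = matrix.counts[c2].to_numpy()
    pvals = [test_gene(int(a), int(b), s1, s2) for a, b in zip(n1, n2)]
    qvals = bh_adjust(pvals)
    rows = []
    for g, a, b, p, q in zip(genes, n1, n2, pvals, qvals):
        lfc = log2_fold_change(int(a), int(b), f1, f2)
        rows.append(DiffResult(
            gene_id=str(g), count1=int(a), count2=int(b),
            log2_fold_change=lfc, p_value=p, q_value=float(q),
            call=classify(lfc, float(q), fc_threshold, q_threshold, fold_only)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("q_value", kind="stable").reset_index(drop=True)


def counts_from_site_tables(tables: dict[str, "SiteTable"],
                            lib_sizes: Optional[dict[str, float]] = None,
                            label: str = "stem_loop_site") -> CountMatrix:
    """Build a CountMatrix from per-condition gene-annotated site tables.

    Only sites carrying ``label`` (the stem-loop cleavage sites by default)
    contribute.  Library sizes default to each condition's total raw calls,
    which is only appropriate when the tables cover a whole library; for a
    gene subset (e.g. histone genes out of a full transcriptome) pass the
    true per-library sequencing depths instead.
    """
    conds = list(tables)
    if len(conds) != 2:
        raise ValueError("exactly two condition site tables are required")
    gene_ids: list[str] = []
    for t in tables.values():
        for g in t.genes:
            if g not in gene_ids:
                gene_ids.append(g)
    data = {}
    for cond, t in tables.items():
        per_gene = {g: 0 for g in gene_ids}
        for s in t.sites:
            if s.gene_id is not None and (label is None or s.label == label):
                per_gene[s.gene_id] += s.raw_count
        data[cond] = [per_gene[g] for g in gene_ids]
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    sizes = lib_sizes or {
        cond: float(sum(s.raw_count for s in t.sites)) or 1.0
        for cond, t in tables.items()}
    return CountMatrix(counts=counts, lib_sizes=sizes)
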