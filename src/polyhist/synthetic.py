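"""Synthetic data for the histone-polyadenylation pipeline.

Builds a toy genome of histone-like genes, each carrying the canonical 3'
layout of a replication-dependent histone transcript: a 16-nt hairpin
(6-bp perfectly complementary stem, 4-nt loop), a cleavage coordinate 4-6 nt
downstream of the hairpin, and the histone downstream element (HDE,
AAAGAGCTGT in DNA) 9-13 nt after the cleavage coordinate.  From that truth
it simulates strand-specific single-end 3'-end sequencing reads for two
conditions (a wild-type-like low polyadenylated fraction and a
knockout-like elevated one), and triplicate qPCR cycle-threshold tables
with a condition-invariant reference gene.

Because 3'-end libraries are poly(A)-selected, stem-loop-processed (non-
polyadenylated) mRNA ends are never emitted.  A transcript sampled as
polyadenylated yields a read that is a sense-strand genomic suffix ending
exactly at the gene's cleavage coordinate followed by untemplated A's; the
remaining library mass is internal fragments of polyadenylated transcripts,
which align fully and carry no tail, so they contribute no cleavage-site
evidence downstream.

All randomness flows from ``SimConfig.seed``; a fixed seed reproduces the
genome, the read sets and the Ct tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alignio import HDE_CONSENSUS, GeneModel, write_fasta, write_gene_models
from .qpcr import CtRecord

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STEM_LEN = 6
LOOP_LEN = 4
HAIRPIN_LEN = 2 * STEM_LEN + LOOP_LEN  # 16


class SizingError(ValueError):
    """The contig is too short to place the requested genes without overlap."""


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    ``polyA_fraction`` is the per-transcript probability, in the first
    condition, that a histone transcript is polyadenylated at its stem-loop
    cleavage site; the second condition multiplies it by ``effect_size``.
    Reads are SE50-style: the sequenced fragment (aligned prefix plus
    untemplated tail) always totals ``read_length`` nucleotides.
    """

    n_genes: int = 20
    contig_length: int = 20_000
    read_length: int = 50
    tail_length_range: tuple[int, int] = (1, 15)
    error_rate: float = 0.0
    duplicate_rate: float = 0.1
    depth_per_condition: int = 10_000
    polyA_fraction: float = 0.05
    effect_size: float = 4.0
    seed: int = 0
    conditions: tuple[str, str] = ("wt", "ko")
    contig_name: str = "chrS"

    def __post_init__(self) -> None:
        tmin, tmax = self.tail_length_range
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if tmin < 1 or tmax < tmin:
            raise ValueError("tail_length_range must satisfy 1 <= min <= max")
        if tmax >= self.read_length - 20:
            raise ValueError("max tail length leaves too short an aligned prefix")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not (0 <= self.polyA_fraction <= 1):
            raise ValueError("polyA_fraction must be in [0, 1]")
        if not (0 <= self.polyA_fraction * self.effect_size <= 1):
            raise ValueError("polyA_fraction * effect_size must stay in [0, 1]")
        if self.n_genes <= 0 or self.depth_per_condition <= 0:
            raise ValueError("n_genes and depth_per_condition must be positive")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct condition labels are required")

    @property
    def polya_by_condition(self) -> dict[str, float]:
        c1, c2 = self.conditions
        return {c1: self.polyA_fraction,
                c2: self.polyA_fraction * self.effect_size}


@dataclass
class GeneTruth:
    cleavage: int
    polya: dict[str, float]
    reads: dict[str, int]


@dataclass
class TruthTable:
    conditions: tuple[str, str]
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, t in self.genes.items():
            row = {"gene_id": gid, "cleavage": t.cleavage}
            for c in self.conditions:
                row[f"polya_{c}"] = t.polya[c]
                row[f"reads_{c}"] = t.reads[c]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    gene_id: str
    condition: str
    polyadenylated: bool
    site: int  # cleavage coordinate for polyadenylated reads, -1 otherwise
    tail_length: int
    duplicate_of: Optional[str] = None


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _junction_safe(downstream: str, max_mismatches: int = 2,
                   mismatch_penalty: int = 4) -> bool:
    """True when a poly(A) tail cannot align past the cleavage coordinate.

    A prefix-scoring extension (match +1, mismatch -penalty, at most
    ``max_mismatches`` mismatches) of an all-A tail against ``downstream``
    must never reach a positive score, so the planted cleavage coordinate is
    unambiguous ground truth for 3'-anchored alignment.
    """
    score, mm = 0, 0
    for base in downstream:
        if base == "A":
            score += 1
        else:
            mm += 1
            if mm > max_mismatches:
                return True
            score -= mismatch_penalty
        if score > 0:
            return False
    return True


def make_toy_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel], TruthTable]:
    """Build the toy genome, gene models and ground truth.

    Genes are placed non-overlapping on a single plus-strand contig.  Within
    each gene the 3' region reads, 5'->3': hairpin, cleavage coordinate
    (planted on a non-A base so the untemplated tail starts unambiguously),
    HDE.  Sequence outside planted features is uniform over {A,C,G,T}; the
    downstream region is redrawn in the rare case it creates a second HDE
    occurrence or an A-rich junction that would mask the cleavage site.
    """
    rng = np.random.default_rng([config.seed, 1])
    upstream = config.read_length + 8  # room for the longest aligned prefix
    margin, spacing = 50, 30

    seq = list(_random_bases(rng, config.contig_length))
    models: list[GeneModel] = []
    truth = TruthTable(conditions=config.conditions)

    pos = margin
    for i in range(config.n_genes):
        gid = f"hist{i + 1}"
        cleavage = pos + upstream
        sl_gap = int(rng.integers(4, 7))
        sl_start = cleavage - sl_gap - HAIRPIN_LEN
        hde_gap = int(rng.integers(9, 14))
        hde_start = cleavage + hde_gap
        gene_end = hde_start + len(HDE_CONSENSUS) + 12
        if gene_end + margin > config.contig_length:
            raise SizingError(
                f"contig of {config.contig_length} nt cannot hold "
                f"{config.n_genes} non-overlapping genes")

        arm = _random_bases(rng, STEM_LEN)
        hairpin = arm + _random_bases(rng, LOOP_LEN) + _revcomp(arm)
        seq[sl_start:sl_start + HAIRPIN_LEN] = hairpin
        seq[hde_start:hde_start + len(HDE_CONSENSUS)] = HDE_CONSENSUS

        for _ in range(100):
            # first post-cleavage base is non-A by construction
            seq[cleavage] = rng.choice(list("CGT"))
            seq[cleavage + 1:hde_start] = _random_bases(rng, hde_gap - 1)
            region = "".join(seq[cleavage:gene_end])
            if region.count(HDE_CONSENSUS) == 1 and _junction_safe(region[:20]):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not plant an unambiguous 3' end for {gid}")

        model = GeneModel(
            gene_id=gid, contig=config.contig_name, strand="+",
            transcript=(pos, gene_end),
            utr3=(sl_start - 5, gene_end),
            stem_loop=(sl_start, sl_start + HAIRPIN_LEN),
            hde=(hde_start, hde_start + len(HDE_CONSENSUS)),
            canonical_cleavage=cleavage)
        model.validate(config.contig_length)
        models.append(model)

        truth.genes[gid] = GeneTruth(
            cleavage=cleavage,
            polya=dict(config.polya_by_condition),
            reads={c: 0 for c in config.conditions})
        pos = gene_end + spacing

    # per-condition read allocation across genes; totals hit the depth exactly
    for c in config.conditions:
        alloc = rng.multinomial(config.depth_per_condition,
                                np.full(config.n_genes, 1.0 / config.n_genes))
        for model, n in zip(models, alloc):
            truth.genes[model.gene_id].reads[c] = int(n)

    genome = {config.contig_name: "".join(seq)}
    return genome, models, truth


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_aseq_reads(genome: dict[str, str], models: list[GeneModel],
                        truth: TruthTable, condition: str,
                        config: SimConfig) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate one condition's 3'-end library with a per-read truth sidecar.

    Polyadenylated transcripts yield a read that is the genomic suffix ending
    exactly at the gene's cleavage coordinate followed by k untemplated A's
    (k uniform over ``tail_length_range``); the rest are fully templated
    internal fragments.  Substitution errors are applied per base at
    ``error_rate``; PCR duplicates are byte-identical copies (errors
    included) inserted at ``duplicate_rate``.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    for m in models:
        if m.gene_id not in truth.genes:
            raise ValueError(f"truth table does not cover gene {m.gene_id}")
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng([config.seed, 101, cond_idx])
    contig_seq = genome[config.contig_name]
    tmin, tmax = config.tail_length_range

    reads: list[SimulatedRead] = []
    serial = 0
    for model in models:
        t = truth.genes[model.gene_id]
        gene_reads: list[SimulatedRead] = []
        for _ in range(t.reads[condition]):
            serial += 1
            rid = f"{condition}:{serial:06d}"
            if gene_reads and rng.random() < config.duplicate_rate:
                src = gene_reads[int(rng.integers(0, len(gene_reads)))]
                dup = SimulatedRead(
                    read_id=rid, sequence=src.sequence, gene_id=src.gene_id,
                    condition=condition, polyadenylated=src.polyadenylated,
                    site=src.site, tail_length=src.tail_length,
                    duplicate_of=src.read_id)
                gene_reads.append(dup)
                continue
            if rng.random() < t.polya[condition]:
                k = int(rng.integers(tmin, tmax + 1))
                start = t.cleavage - (config.read_length - k)
                seq = contig_seq[start:t.cleavage] + "A" * k
                read = SimulatedRead(
                    read_id=rid, sequence=seq, gene_id=model.gene_id,
                    condition=condition, polyadenylated=True,
                    site=t.cleavage, tail_length=k)
            else:
                end = int(rng.integers(model.transcript[0] + config.read_length,
                                       t.cleavage))
                seq = contig_seq[end - config.read_length:end]
                read = SimulatedRead(
                    read_id=rid, sequence=seq, gene_id=model.gene_id,
                    condition=condition, polyadenylated=False,
                    site=-1, tail_length=0)
            read.sequence = _apply_errors(read.sequence, rng, config.error_rate)
            gene_reads.append(read)
        reads.extend(gene_reads)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    sidecar = pd.DataFrame(
        [{"read_id": r.read_id, "gene_id": r.gene_id, "condition": r.condition,
          "polyadenylated": r.polyadenylated, "site": r.site,
          "tail_length": r.tail_length,
          "duplicate_of": r.duplicate_of or "."} for r in reads])
    return reads, sidecar


def write_fastq(reads: list[SimulatedRead], path: str | Path,
                quality: int = 40) -> None:
    """Write reads as Sanger/Phred+33 FASTQ with a constant quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_ct_table(truth: TruthTable, amplification_efficiency: float = 1.0,
                      n_replicates: int = 3, noise_sd: float = 0.0,
                      seed: int = 0, reference_gene: str = "Rps2",
                      minus_rt_ct: float = 36.0) -> list[CtRecord]:
    """Simulate a comparative-Ct qPCR table from the simulation truth.

    Ct = -log2(q) / log2(1 + E) + per-(gene, priming) offset + Gaussian
    replicate noise, where q is the relative template quantity: the
    condition's polyadenylated fraction for oligo(dT)-primed cDNA, 1 for
    random-primed (total mRNA unchanged between conditions) and 1 for the
    reference gene.  -RT rows with Ct > 33 model clean no-reverse-
    transcriptase controls.
    """
    if not (0 < amplification_efficiency <= 1):
        raise ValueError("amplification_efficiency must be in (0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng([seed, 7])
    base = np.log2(1 + amplification_efficiency)
    records: list[CtRecord] = []

    genes = list(truth.genes) + [reference_gene]
    offsets = {(g, p): float(rng.uniform(18, 26))
               for g in genes for p in ("oligo_dT", "random")}

    def ct_values(q: float, offset: float) -> tuple[float, ...]:
        if q <= 0:
            raise ValueError("relative template quantity must be positive")
        mean = -np.log2(q) / base + offset
        noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd > 0 \
            else np.zeros(n_replicates)
        return tuple(float(mean + d) for d in noise)

    for sample in truth.conditions:
        for gene in genes:
            for priming in ("oligo_dT", "random"):
                if gene == reference_gene:
                    q = 1.0
                elif priming == "oligo_dT":
                    q = truth.genes[gene].polya[sample]
                else:
                    q = 1.0
                records.append(CtRecord(
                    sample_id=sample, target_gene=gene, priming=priming,
                    ct_values=ct_values(q, offsets[(gene, priming)]),
                    is_reference=(gene == reference_gene)))
            records.append(CtRecord(
                sample_id=sample, target_gene=gene, priming="minus_RT",
                ct_values=tuple(float(v) for v in
                                rng.normal(minus_rt_ct, 0.3, size=n_replicates)),
                is_reference=(gene == reference_gene)))
    return records


# ---------------------------------------------------------------------------
# Bundled output
# ---------------------------------------------------------------------------

def write_simulation(config: SimConfig, outdir: str | Path) -> None:
    """Generate and write the complete synthetic dataset to ``outdir``."""
    from .qpcr import write_ct_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models, truth = make_toy_genome(config)
    write_fasta(genome, outdir / "genome.fa")
    write_gene_models(models, outdir / "genes.bed", format="bed")
    write_gene_models(models, outdir / "genes.gff3", format="gff3")
    truth.write_tsv(outdir / "truth_genes.tsv")
    for condition in config.conditions:
        reads, sidecar = simulate_aseq_reads(genome, models, truth, condition, config)
        write_fastq(reads, outdir / f"reads_{condition}.fastq")
        sidecar.to_csv(outdir / f"truth_reads_{condition}.tsv", sep="\t", index=False)
    ct = simulate_ct_table(truth, noise_sd=0.2, seed=config.seed)
    write_ct_table(ct, outdir / "ct_table.tsv")
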