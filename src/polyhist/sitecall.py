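"""Cleavage/polyadenylation site calling from 3'-anchored alignments.

The core rule: the first read nucleotide that does not align to the genome
marks the cleavage site.  Because an adenosine in the tail could equally be
templated by a genomic A immediately downstream of the aligned prefix, such
A's are assigned to the genome and the cut placed after them.  By default
the *maximal* genomic A-run (capped by the number of leading A's the tail
actually has) is reassigned, which is the only convention that does not
depend on how far a particular aligner happened to extend; shifting by a
single A is available via ``a_run="single"``.  Reads whose entire tail
could be templated give no evidence of polyadenylation and are no-calls,
as are reads whose remaining untemplated suffix is not predominantly A
(suspected artifacts).

Identical sequences are collapsed into one representative before alignment;
per-site tallies keep both the raw read count (multiplicities included) and
the collapsed distinct-sequence count.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alignio import AlignedRead, GeneModel, align_3prime_anchored


@dataclass
class ReadSiteCall:
    """A single read's (or collapsed representative's) site evidence."""

    contig: str
    strand: str
    site: int  # 0-based coordinate of the first post-cleavage genomic base
    tail: str  # untemplated suffix after genomic-A reassignment
    multiplicity: int = 1


@dataclass
class CleavageSiteCall:
    contig: str
    strand: str
    site: int
    raw_count: int
    collapsed_count: int
    mean_tail_length: float
    tail_A_fraction: float
    gene_id: Optional[str] = None
    label: Optional[str] = None  # stem_loop_site | downstream | other | intergenic


@dataclass
class GeneSiteSummary:
    gene_id: str
    raw_total: int = 0
    collapsed_total: int = 0
    sites: list[int] = field(default_factory=list)


@dataclass
class SiteTable:
    sites: list[CleavageSiteCall] = field(default_factory=list)
    genes: dict[str, GeneSiteSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"contig": s.contig, "strand": s.strand, "site": s.site,
              "raw_count": s.raw_count, "collapsed_count": s.collapsed_count,
              "mean_tail_length": s.mean_tail_length,
              "tail_A_fraction": s.tail_A_fraction,
              "gene_id": s.gene_id or ".", "label": s.label or "."}
             for s in self.sites])

    # ---- writers -------------------------------------------------------

    def write_bed(self, path: str | Path) -> None:
        """6-column BED; the 1-nt feature is the first post-cleavage base."""
        with open(path, "w") as fh:
            for s in self.sites:
                name = s.gene_id or "."
                fh.write(f"{s.contig}\t{s.site}\t{s.site + 1}\t{name}\t"
                         f"{s.raw_count}\t{s.strand}\n")

    def write_bedgraph(self, path: str | Path, track_name: str = "cp_sites") -> None:
        """Per-position raw read counts for genome-browser display."""
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
            for s in self.sites:
                fh.write(f"{s.contig}\t{s.site}\t{s.site + 1}\t{s.raw_count}\n")

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    # ---- readers (round-trip) -----------------------------------------

    @staticmethod
    def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                c, s, e, n, score, strand = line.rstrip("\n").split("\t")
                rows.append((c, int(s), int(e), n, int(score), strand))
        return rows

    @staticmethod
    def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, int]]:
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                c, s, e, v = line.rstrip("\n").split("\t")
                rows.append((c, int(s), int(e), int(v)))
        return rows

    @staticmethod
    def read_tsv(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


@dataclass
class LibraryStats:
    """Bookkeeping for one library's trip through the site caller."""

    n_reads: int = 0
    n_distinct: int = 0
    n_unaligned: int = 0
    n_multimapped: int = 0
    n_no_tail: int = 0
    n_fully_templated: int = 0
    n_artifact: int = 0
    n_called: int = 0  # raw reads contributing to the site table


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def collapse_identical(reads: Sequence[str]) -> list[tuple[str, int]]:
    """Collapse identical sequences into (representative, multiplicity) pairs.

    Order is deterministic: representatives appear in order of first
    occurrence, and multiplicities sum to the input count.
    """
    counts: OrderedDict[str, int] = OrderedDict()
    for seq in reads:
        counts[seq] = counts.get(seq, 0) + 1
    return list(counts.items())


def call_cleavage_site(aread: AlignedRead, genome: dict[str, str],
                       min_tail: int = 1, tail_a_frac_min: float = 0.8,
                       a_run: str = "maximal") -> Optional[ReadSiteCall]:
    """Call the cleavage site evidenced by one aligned read, or no-call.

    Let e be the first unaligned genomic coordinate.  Tail A's that could be
    templated by the genomic A-run starting at e are assigned to the genome
    and the site placed after them (all of them under ``a_run="maximal"``,
    at most one under ``"single"``).  No-call when the read is multi-mapped
    or antisense, the tail is shorter than ``min_tail``, the entire tail is
    potentially templated, or the untemplated suffix has an A fraction below
    ``tail_a_frac_min`` (0 disables the artifact filter).
    """
    if a_run not in ("maximal", "single"):
        raise ValueError(f"a_run must be 'maximal' or 'single', got {a_run!r}")
    if aread.multimapped or aread.strand != "+":
        return None
    tail = aread.tail
    if len(tail) < min_tail or not tail:
        return None
    seq = genome[aread.contig]
    e = aread.end

    leading_a = 0
    while leading_a < len(tail) and tail[leading_a] == "A":
        leading_a += 1
    run = 0
    while e + run < len(seq) and seq[e + run] == "A":
        run += 1
    shift = min(run, leading_a)
    if a_run == "single":
        shift = min(shift, 1)
    site = e + shift
    untemplated = tail[shift:]
    if len(untemplated) < min_tail:
        return None
    if tail_a_frac_min > 0:
        a_frac = untemplated.count("A") / len(untemplated)
        if a_frac < tail_a_frac_min:
            return None
    return ReadSiteCall(contig=aread.contig, strand=aread.strand, site=site,
                        tail=untemplated, multiplicity=aread.multiplicity)


def build_site_table(calls: Iterable[ReadSiteCall]) -> SiteTable:
    """Merge per-read calls into per-site tallies, sorted by coordinate."""
    grouped: dict[tuple[str, str, int], list[ReadSiteCall]] = {}
    for call in calls:
        grouped.setdefault((call.contig, call.strand, call.site), []).append(call)
    sites = []
    for (contig, strand, site), group in sorted(grouped.items()):
        raw = sum(c.multiplicity for c in group)
        total_tail = sum(len(c.tail) * c.multiplicity for c in group)
        total_a = sum(c.tail.count("A") * c.multiplicity for c in group)
        sites.append(CleavageSiteCall(
            contig=contig, strand=strand, site=site,
            raw_count=raw, collapsed_count=len(group),
            mean_tail_length=total_tail / raw,
            tail_A_fraction=total_a / total_tail if total_tail else 0.0))
    return SiteTable(sites=sites)


def assign_sites_to_genes(table: SiteTable, models: Sequence[GeneModel],
                          tol: int = 2,
                          downstream_window: int = 1000) -> SiteTable:
    """Label each site against the gene models and aggregate per gene.

    A site within ``tol`` nt of a gene's canonical cleavage coordinate is a
    ``stem_loop_site``; one up to ``downstream_window`` nt past the
    canonical coordinate is ``downstream``; any other site inside a gene is
    ``other``; sites on contigs without models (or outside every gene) are
    ``intergenic`` and excluded from gene totals.
    """
    for m in models:
        m.validate()
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    genes = {m.gene_id: GeneSiteSummary(gene_id=m.gene_id) for m in models}

    for s in table.sites:
        s.gene_id, s.label = None, "intergenic"
        candidates = [m for m in by_contig.get(s.contig, [])
                      if m.strand == s.strand]
        # a canonical-site match beats transcript containment beats the
        # (long) downstream window of the nearest upstream gene
        canonical = [m for m in candidates
                     if m.canonical_cleavage is not None
                     and abs(s.site - m.canonical_cleavage) <= tol]
        containing = [m for m in candidates
                      if m.transcript[0] <= s.site < m.transcript[1]]
        windowed = [m for m in candidates
                    if m.canonical_cleavage is not None
                    and m.canonical_cleavage < s.site
                    <= m.canonical_cleavage + downstream_window]
        if canonical:
            m = min(canonical, key=lambda m: abs(s.site - m.canonical_cleavage))
            s.gene_id, s.label = m.gene_id, "stem_loop_site"
        elif containing:
            m = containing[0]
            s.gene_id = m.gene_id
            cc = m.canonical_cleavage
            s.label = "downstream" if (cc is not None and s.site > cc) else "other"
        elif windowed:
            m = max(windowed, key=lambda m: m.canonical_cleavage)
            s.gene_id, s.label = m.gene_id, "downstream"
        if s.gene_id is not None:
            g = genes[s.gene_id]
            g.raw_total += s.raw_count
            g.collapsed_total += s.collapsed_count
            g.sites.append(s.site)
    table.genes = genes
    return table


# ---------------------------------------------------------------------------
# Library-level pipeline
# ---------------------------------------------------------------------------

def call_library(sequences: Sequence[str], genome: dict[str, str],
                 min_seed: int = 20, max_mismatches: int = 2,
                 min_tail: int = 1, tail_a_frac_min: float = 0.8,
                 a_run: str = "maximal") -> tuple[SiteTable, LibraryStats]:
    """Collapse, align and site-call one library of read sequences."""
    stats = LibraryStats(n_reads=len(sequences))
    collapsed = collapse_identical(sequences)
    stats.n_distinct = len(collapsed)
    calls: list[ReadSiteCall] = []
    for i, (seq, mult) in enumerate(collapsed):
        aread = align_3prime_anchored(seq, genome, min_seed=min_seed,
                                      max_mismatches=max_mismatches,
                                      read_id=f"rep{i}")
        if aread is None:
            stats.n_unaligned += mult
            continue
        aread.multiplicity = mult
        if aread.multimapped:
            stats.n_multimapped += mult
            continue
        if not aread.tail:
            stats.n_no_tail += mult
            continue
        call = call_cleavage_site(aread, genome, min_tail=min_tail,
                                  tail_a_frac_min=tail_a_frac_min, a_run=a_run)
        if call is None:
            # distinguish fully templated tails from artifact filtering
            relaxed = call_cleavage_site(aread, genome, min_tail=min_tail,
                                         tail_a_frac_min=0.0, a_run=a_run)
            if relaxed is None:
                stats.n_fully_templated += mult
            else:
                stats.n_artifact += mult
            continue
        stats.n_called += mult
        calls.append(call)
    return build_site_table(calls), stats
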