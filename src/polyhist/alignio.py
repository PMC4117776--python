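"""Gene-model and alignment I/O, plus a minimal 3'-anchored read aligner.

Histone-like gene models carry the features needed to interpret 3'-end
sequencing reads: the 3' UTR, the 16-nt stem-loop, the canonical cleavage
coordinate (first post-cleavage genomic base) and the downstream HDE.
Coordinates are 0-based half-open everywhere internally; BED is emitted
natively and GFF3 (1-based inclusive) is converted on read/write.

The built-in aligner anchors the 5' end of a read on the plus strand by an
exact prefix seed and extends with a bounded number of mismatches; whatever
it cannot align at the 3' end becomes the read's unaligned *tail*, the raw
evidence for untemplated adenosines.  It is adequate for toy genomes only;
alignments against a real genome should be produced externally and imported
from SAM, where a trailing soft-clip plays the role of the tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pysam

Interval = tuple[int, int]

HDE_CONSENSUS = "AAAGAGCTGT"  # DNA transliteration of the RNA consensus AAAGAGCUGU


class ParseError(ValueError):
    """A malformed line in a gene-model file."""


class GeneModelError(ValueError):
    """A gene model violating its structural invariants."""


class ReferenceMismatchError(ValueError):
    """Alignments refer to a contig absent from the provided genome."""


@dataclass
class GeneModel:
    """A histone-like gene with its 3'-end processing landmarks.

    ``canonical_cleavage`` is the 0-based coordinate of the first genomic
    base *after* the cut, i.e. the first base that is not part of the mature
    stem-loop-processed mRNA.
    """

    gene_id: str
    contig: str
    strand: str
    transcript: Interval
    utr3: Optional[Interval] = None
    stem_loop: Optional[Interval] = None
    hde: Optional[Interval] = None
    canonical_cleavage: Optional[int] = None

    def validate(self, contig_length: Optional[int] = None) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, iv in (("transcript", self.transcript), ("utr3", self.utr3),
                         ("stem_loop", self.stem_loop), ("hde", self.hde)):
            if iv is None:
                continue
            if iv[0] < 0 or iv[1] <= iv[0]:
                raise GeneModelError(f"{self.gene_id}: bad {name} interval {iv}")
            if contig_length is not None and iv[1] > contig_length:
                raise GeneModelError(
                    f"{self.gene_id}: {name} interval {iv} exceeds contig length {contig_length}")
        if self.utr3 is not None:
            if not (self.transcript[0] <= self.utr3[0] and self.utr3[1] <= self.transcript[1]):
                raise GeneModelError(f"{self.gene_id}: utr3 outside transcript")
        if self.stem_loop is not None and self.utr3 is not None:
            if not (self.utr3[0] <= self.stem_loop[0] and self.stem_loop[1] <= self.utr3[1]):
                raise GeneModelError(f"{self.gene_id}: stem_loop outside utr3")
        if self.canonical_cleavage is not None:
            if self.stem_loop is not None and self.canonical_cleavage <= self.stem_loop[1]:
                raise GeneModelError(
                    f"{self.gene_id}: cleavage coordinate must lie after the stem-loop")
            if self.hde is not None and self.hde[0] < self.canonical_cleavage:
                raise GeneModelError(
                    f"{self.gene_id}: HDE must start at or after the cleavage coordinate")
            if self.utr3 is not None and not (
                    self.utr3[0] <= self.canonical_cleavage < self.utr3[1]):
                raise GeneModelError(
                    f"{self.gene_id}: cleavage coordinate outside the 3' UTR")


@dataclass
class AlignedRead:
    """A sense-strand alignment with an unaligned 3' suffix (tail).

    ``aligned_span`` counts genomic bases covered by the aligned prefix;
    ``tail`` is the read suffix left unaligned, possibly empty.
    ``multiplicity`` carries the number of identical sequences collapsed
    into this representative.
    """

    read_id: str
    contig: str
    strand: str
    start: int
    aligned_span: int
    tail: str
    n_mismatches: int = 0
    multiplicity: int = 1
    multimapped: bool = False

    @property
    def end(self) -> int:
        """First genomic coordinate after the aligned prefix."""
        return self.start + self.aligned_span


# ---------------------------------------------------------------------------
# Gene-model files
# ---------------------------------------------------------------------------

_BED_HEADER = ("#contig\tstart\tend\tgene_id\tscore\tstrand\tcleavage\t"
               "utr3_start\tutr3_end\tsl_start\tsl_end\thde_start\thde_end")


def _opt_interval(a: str, b: str) -> Optional[Interval]:
    if a == "." or b == ".":
        return None
    return (int(a), int(b))


def parse_gene_models(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from a BED-like TSV or GFF3 file.

    The BED dialect is BED6 optionally extended with seven columns:
    cleavage coordinate and the utr3/stem-loop/HDE intervals (0-based
    half-open, ``.`` for absent).  GFF3 coordinates (1-based inclusive) are
    converted to 0-based half-open.
    """
    path = Path(path)
    if format == "bed":
        models = _parse_bed(path)
    elif format == "gff3":
        models = _parse_gff3(path)
    else:
        raise ValueError(f"unknown gene-model format: {format!r}")
    for m in models:
        m.validate()
    return models


def _parse_bed(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns")
            try:
                contig, start, end, name, _score, strand = fields[:6]
                model = GeneModel(
                    gene_id=name, contig=contig, strand=strand,
                    transcript=(int(start), int(end)))
                if len(fields) >= 13:
                    model.canonical_cleavage = (
                        None if fields[6] == "." else int(fields[6]))
                    model.utr3 = _opt_interval(fields[7], fields[8])
                    model.stem_loop = _opt_interval(fields[9], fields[10])
                    model.hde = _opt_interval(fields[11], fields[12])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            models.append(model)
    return models


def _parse_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            tags = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = tags.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = GeneModel(gene_id=gid, contig=contig, strand=strand,
                                       transcript=iv)
                order.append(gid)
            else:
                gid = tags.get("Parent")
                if gid is None or gid not in genes:
                    raise ParseError(f"{path}:{lineno}: feature with unknown Parent")
                model = genes[gid]
                if ftype == "three_prime_UTR":
                    model.utr3 = iv
                elif ftype == "stem_loop":
                    model.stem_loop = iv
                elif ftype == "histone_downstream_element":
                    model.hde = iv
                elif ftype == "cleavage_site":
                    model.canonical_cleavage = iv[0]
    return [genes[g] for g in order]


def write_gene_models(models: Iterable[GeneModel], path: str | Path,
                      format: str = "bed") -> None:
    path = Path(path)
    if format == "bed":
        with open(path, "w") as fh:
            fh.write(_BED_HEADER + "\n")
            for m in models:
                opt = lambda v: "." if v is None else str(v)
                iv = lambda v: (".", ".") if v is None else (str(v[0]), str(v[1]))
                row = [m.contig, str(m.transcript[0]), str(m.transcript[1]),
                       m.gene_id, "0", m.strand, opt(m.canonical_cleavage),
                       *iv(m.utr3), *iv(m.stem_loop), *iv(m.hde)]
                fh.write("\t".join(row) + "\n")
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in models:
                def line(ftype: str, iv: Interval, attrs: str) -> str:
                    return "\t".join([m.contig, "polyhist", ftype,
                                      str(iv[0] + 1), str(iv[1]), ".", m.strand,
                                      ".", attrs])
                fh.write(line("gene", m.transcript, f"ID={m.gene_id}") + "\n")
                if m.utr3 is not None:
                    fh.write(line("three_prime_UTR", m.utr3, f"Parent={m.gene_id}") + "\n")
                if m.stem_loop is not None:
                    fh.write(line("stem_loop", m.stem_loop, f"Parent={m.gene_id}") + "\n")
                if m.canonical_cleavage is not None:
                    cc = m.canonical_cleavage
                    fh.write(line("cleavage_site", (cc, cc + 1),
                                  f"Parent={m.gene_id}") + "\n")
                if m.hde is not None:
                    fh.write(line("histone_downstream_element", m.hde,
                                  f"Parent={m.gene_id}") + "\n")
    else:
        raise ValueError(f"unknown gene-model format: {format!r}")


# ---------------------------------------------------------------------------
# Built-in 3'-anchored aligner
# ---------------------------------------------------------------------------

def _extend(read: str, ref: str, start: int, min_seed: int,
            max_mismatches: int, mismatch_penalty: int) -> tuple[int, int]:
    """Extend an exact seed match at ref[start:] along the read.

    Returns (aligned_span, n_mismatches).  The extension stops when the
    mismatch budget is exhausted or the read/contig ends, and the alignment
    is trimmed back to the best-scoring prefix (match +1, mismatch
    -mismatch_penalty) so that a poly(A) tail is soft-clipped rather than
    absorbed as mismatches.
    """
    n = len(read)
    score = min_seed  # the seed is an exact match
    best_score, best_end, best_mm = score, min_seed, 0
    mm = 0
    i = min_seed
    while i < n and start + i < len(ref):
        if read[i] == ref[start + i]:
            score += 1
        else:
            mm += 1
            if mm > max_mismatches:
                break
            score -= mismatch_penalty
        i += 1
        if score > best_score:
            best_score, best_end, best_mm = score, i, mm
    return best_end, best_mm


def align_3prime_anchored(read_sequence: str, genome: dict[str, str],
                          min_seed: int = 20, max_mismatches: int = 2,
                          mismatch_penalty: int = 4,
                          read_id: str = "read") -> Optional[AlignedRead]:
    """Align a sense-strand read by exact-prefix seed + bounded extension.

    Returns ``None`` when no locus carries an exact match of the first
    ``min_seed`` bases (reads matching only the reverse strand are therefore
    unaligned, matching the sense-strand-only convention of strand-specific
    3'-end libraries).  Among loci of equal aligned length the leftmost is
    chosen and the read is flagged multi-mapped.
    """
    if len(read_sequence) < min_seed:
        raise ValueError(f"read shorter than min_seed={min_seed}")
    seed = read_sequence[:min_seed]
    candidates: list[tuple[str, int, int, int]] = []
    for contig in sorted(genome):
        ref = genome[contig]
        idx = ref.find(seed)
        while idx != -1:
            span, nmm = _extend(read_sequence, ref, idx, min_seed,
                                max_mismatches, mismatch_penalty)
            candidates.append((contig, idx, span, nmm))
            idx = ref.find(seed, idx + 1)
    if not candidates:
        return None
    best_span = max(c[2] for c in candidates)
    hits = [c for c in candidates if c[2] == best_span]
    contig, start, span, nmm = hits[0]
    return AlignedRead(
        read_id=read_id, contig=contig, strand="+", start=start,
        aligned_span=span, tail=read_sequence[span:], n_mismatches=nmm,
        multimapped=len(hits) > 1)


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

@dataclass
class ImportStats:
    n_records: int = 0
    n_imported: int = 0
    n_reverse_dropped: int = 0
    n_secondary_dropped: int = 0
    n_unmapped_dropped: int = 0


def import_alignments(sam_path: str | Path,
                      genome: dict[str, str]) -> tuple[list[AlignedRead], ImportStats]:
    """Import plus-strand alignments from SAM; a trailing soft-clip is the tail.

    Reverse-strand, secondary and supplementary records are dropped (with
    counters in the returned :class:`ImportStats`), consistent with a
    sense-strand 3'-end library.
    """
    stats = ImportStats()
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in genome:
                raise ReferenceMismatchError(
                    f"contig {ref!r} in SAM header is absent from the genome")
        for rec in sam:
            stats.n_records += 1
            if rec.is_unmapped:
                stats.n_unmapped_dropped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.n_secondary_dropped += 1
                continue
            if rec.is_reverse:
                stats.n_reverse_dropped += 1
                continue
            if rec.reference_name not in genome:
                raise ReferenceMismatchError(
                    f"contig {rec.reference_name!r} is absent from the genome")
            cigar = rec.cigartuples or []
            tail = ""
            if cigar and cigar[-1][0] == 4:  # trailing soft-clip
                tail = rec.query_sequence[-cigar[-1][1]:]
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(AlignedRead(
                read_id=rec.query_name, contig=rec.reference_name, strand="+",
                start=rec.reference_start,
                aligned_span=rec.reference_end - rec.reference_start,
                tail=tail, n_mismatches=int(nm)))
            stats.n_imported += 1
    return out, stats


# ---------------------------------------------------------------------------
# FASTA / FASTQ helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
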