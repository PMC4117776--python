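"""Histone 3'-end motif annotation: stem-loop and HDE detection.

Replication-dependent histone mRNAs end in a conserved 16-nt hairpin
(6-bp stem, 4-nt loop) and carry a purine-rich downstream element (HDE,
consensus AAAGAGCUGU) that base-pairs with U7 snRNA.  The stem-loop is
detected structurally -- a window whose first six bases are the reverse
complement of its last six -- rather than by a consensus string, and the
HDE by Hamming-distance scan against the DNA-transliterated consensus.
No thermodynamic folding is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .alignio import HDE_CONSENSUS, GeneModel

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class StemLoopHit:
    start: int
    stem_len: int
    loop: tuple[int, int]
    paired_fraction: float

    @property
    def length(self) -> int:
        return 2 * self.stem_len + (self.loop[1] - self.loop[0])


@dataclass(frozen=True)
class HdeHit:
    start: int
    matched: str
    mismatches: int


@dataclass
class GeneLayoutReport:
    """Validation of a gene's 3'-end architecture against its annotation."""

    gene_id: str
    stem_loop_found: bool
    hde_found: bool
    cleavage_between: bool
    sl_to_cleavage: Optional[int] = None
    cleavage_to_hde: Optional[int] = None

    @property
    def ok(self) -> bool:
        return self.stem_loop_found and self.hde_found and self.cleavage_between


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _pairs(a: str, b: str, allow_GU: bool) -> bool:
    return (a, b) in _WC or (allow_GU and (a, b) in _WOBBLE)


def find_stem_loops(seq: str, stem_len: int = 6, loop_len: int = 4,
                    allow_GU: bool = False) -> list[StemLoopHit]:
    """Report every window folding into a perfect hairpin.

    A hit is a window of length ``2*stem_len + loop_len`` whose i-th base
    pairs with its (length-1-i)-th base for all stem positions
    (Watson-Crick; G.T wobble only with ``allow_GU``).  Overlapping hits
    are all reported, in left-to-right order.
    """
    seq = _norm(seq)
    window = 2 * stem_len + loop_len
    hits = []
    for start in range(len(seq) - window + 1):
        w = seq[start:start + window]
        if all(_pairs(w[i], w[window - 1 - i], allow_GU) for i in range(stem_len)):
            hits.append(StemLoopHit(
                start=start, stem_len=stem_len,
                loop=(start + stem_len, start + stem_len + loop_len),
                paired_fraction=1.0))
    return hits


def scan_hde(seq: str, consensus: str = HDE_CONSENSUS,
             max_mismatches: int = 2) -> list[HdeHit]:
    """All windows within the given Hamming distance of the HDE consensus."""
    seq = _norm(seq)
    consensus = _norm(consensus)
    k = len(consensus)
    hits = []
    for start in range(len(seq) - k + 1):
        w = seq[start:start + k]
        d = sum(a != b for a, b in zip(w, consensus))
        if d <= max_mismatches:
            hits.append(HdeHit(start=start, matched=w, mismatches=d))
    return hits


def annotate_gene_layout(model: GeneModel, genome: dict[str, str],
                         max_hde_mismatches: int = 2,
                         allow_GU: bool = False) -> GeneLayoutReport:
    """Check that a gene's annotated 3' end has the histone architecture.

    Flags (never exceptions) report whether a hairpin folds within the
    annotated stem-loop interval, the HDE consensus matches within the
    annotated HDE interval, and the canonical cleavage coordinate falls
    strictly between the two; spacings are in nucleotides.
    """
    seq = genome[model.contig]
    sl_found = False
    if model.stem_loop is not None:
        s, e = model.stem_loop
        sl_found = bool(find_stem_loops(seq[s:e], allow_GU=allow_GU))
    hde_found = False
    if model.hde is not None:
        s, e = model.hde
        hde_found = bool(scan_hde(seq[s:e], max_mismatches=max_hde_mismatches))
    between = False
    sl_gap = hde_gap = None
    if (model.canonical_cleavage is not None and model.stem_loop is not None
            and model.hde is not None):
        cc = model.canonical_cleavage
        between = model.stem_loop[1] <= cc < model.hde[0]
        sl_gap = cc - model.stem_loop[1]
        hde_gap = model.hde[0] - cc
    return GeneLayoutReport(
        gene_id=model.gene_id, stem_loop_found=sl_found, hde_found=hde_found,
        cleavage_between=between, sl_to_cleavage=sl_gap, cleavage_to_hde=hde_gap)
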