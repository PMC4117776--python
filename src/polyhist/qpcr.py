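"""Comparative-Ct (2^-ddCt) relative quantification for qPCR tables.

The workflow mirrors standard SYBR-green practice: triplicate cycle
thresholds are averaged, each target is normalized to a reference gene
(Rps2 in the mouse ESC experiments this package models) to give dCt,
the control sample's dCt is subtracted to give ddCt, and relative
quantity is 2^-ddCt.  A no-reverse-transcriptase (-RT) reaction passing
only when its mean Ct exceeds 33 cycles guards against genomic DNA
contamination.  Oligo(dT)- and random-primed quantifications of the same
gene can be paired to ask whether the polyadenylated fraction changed
while total mRNA did not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

PRIMINGS = ("oligo_dT", "random", "minus_RT")


@dataclass
class CtRecord:
    """Replicate cycle-threshold measurements for one well group."""

    sample_id: str
    target_gene: str
    priming: str  # oligo_dT | random | minus_RT
    ct_values: tuple[float, ...]
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.priming not in PRIMINGS:
            raise ValueError(f"unknown priming {self.priming!r}")
        if len(self.ct_values) < 1:
            raise ValueError("at least one Ct replicate is required")
        if any(v <= 0 for v in self.ct_values):
            raise ValueError("Ct values must be positive")


@dataclass
class RqResult:
    sample_id: str
    target_gene: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    rq_sd: float = 0.0
    contamination_flag: bool = False


@dataclass
class PolyTotalReport:
    target_gene: str
    rq_poly: float
    rq_total: float
    ratio: float
    pattern_flag: bool  # polyadenylated fraction changed while total did not


def summarize_ct(record: CtRecord) -> tuple[float, float, bool]:
    """Mean and sample standard deviation of the Ct replicates.

    Returns (mean, sd, single_replicate_flag); the sd of a single replicate
    is reported as 0 with the flag raised.
    """
    vals = record.ct_values
    n = len(vals)
    mean = sum(vals) / n
    if n == 1:
        return mean, 0.0, True
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var), False


def relative_expression(target: CtRecord, reference: CtRecord,
                        target_ctrl: CtRecord, reference_ctrl: CtRecord,
                        amplification_efficiency: float = 1.0) -> RqResult:
    """Relative quantity of ``target`` in its sample versus the control sample.

    dCt = Ct_target - Ct_reference within each sample; ddCt subtracts the
    control sample's dCt; rq = (1+E)^-ddCt, which is the textbook 2^-ddCt
    at 100% amplification efficiency.  Replicate scatter is propagated into
    ``rq_sd`` by the delta method but never used for gating.
    """
    if target.target_gene != target_ctrl.target_gene:
        raise ValueError(
            f"target gene mismatch between sample ({target.target_gene}) "
            f"and control ({target_ctrl.target_gene})")
    if not (reference.is_reference and reference_ctrl.is_reference):
        raise ValueError("reference records must be flagged is_reference")
    if not (0 < amplification_efficiency <= 1):
        raise ValueError("amplification_efficiency must be in (0, 1]")

    mt, st, _ = summarize_ct(target)
    mr, sr, _ = summarize_ct(reference)
    mtc, stc, _ = summarize_ct(target_ctrl)
    mrc, src, _ = summarize_ct(reference_ctrl)

    delta_ct = mt - mr
    delta_delta_ct = delta_ct - (mtc - mrc)
    base = 1 + amplification_efficiency
    rq = base ** (-delta_delta_ct)
    sd_ddct = math.sqrt(st ** 2 + sr ** 2 + stc ** 2 + src ** 2)
    rq_sd = math.log(base) * rq * sd_ddct
    return RqResult(sample_id=target.sample_id, target_gene=target.target_gene,
                    delta_ct=delta_ct, delta_delta_ct=delta_delta_ct,
                    rq=rq, rq_sd=rq_sd)


def check_minus_rt(record: CtRecord, threshold: float = 33.0) -> str:
    """Genomic-DNA check on a -RT control; passes only strictly above threshold."""
    if record.priming != "minus_RT":
        raise ValueError("check_minus_rt expects a minus_RT record")
    mean, _, _ = summarize_ct(record)
    return "pass" if mean > threshold else "contaminated"


def poly_vs_total(rq_oligo_dT: RqResult, rq_random: RqResult,
                  fc_threshold: float = 2.0) -> PolyTotalReport:
    """Pair oligo(dT)- and random-primed quantifications of one gene.

    The pattern flag reports the signature of selective polyadenylation
    change: the polyadenylated quantity moved by at least ``fc_threshold``
    in either direction while total mRNA stayed within [1/fc, fc].
    """
    if rq_oligo_dT.target_gene != rq_random.target_gene:
        raise ValueError("oligo(dT) and random-primed results must share a gene")
    if rq_oligo_dT.sample_id != rq_random.sample_id:
        raise ValueError("oligo(dT) and random-primed results must share a sample")
    poly_changed = (rq_oligo_dT.rq >= fc_threshold
                    or rq_oligo_dT.rq <= 1.0 / fc_threshold)
    total_flat = 1.0 / fc_threshold < rq_random.rq < fc_threshold
    return PolyTotalReport(
        target_gene=rq_oligo_dT.target_gene,
        rq_poly=rq_oligo_dT.rq, rq_total=rq_random.rq,
        ratio=rq_oligo_dT.rq / rq_random.rq,
        pattern_flag=poly_changed and total_flat)


# ---------------------------------------------------------------------------
# Table-level workflow and TSV I/O
# ---------------------------------------------------------------------------

def quantify_table(records: Iterable[CtRecord], sample: str, control: str,
                   priming: str = "oligo_dT",
                   amplification_efficiency: float = 1.0,
                   rt_threshold: float = 33.0) -> list[RqResult]:
    """Run relative_expression for every non-reference gene in a Ct table.

    -RT rows, when present for a gene/sample, gate the contamination flag of
    the corresponding result.
    """
    records = list(records)

    def pick(sample_id: str, gene: Optional[str], prim: str,
             reference: bool) -> Optional[CtRecord]:
        for r in records:
            if (r.sample_id == sample_id and r.priming == prim
                    and r.is_reference == reference
                    and (gene is None or r.target_gene == gene)):
                return r
        return None

    ref_s = pick(sample, None, priming, True)
    ref_c = pick(control, None, priming, True)
    if ref_s is None or ref_c is None:
        raise ValueError("reference-gene records missing for sample or control")

    results = []
    genes = sorted({r.target_gene for r in records
                    if not r.is_reference and r.priming == priming})
    for gene in genes:
        tgt_s = pick(sample, gene, priming, False)
        tgt_c = pick(control, gene, priming, False)
        if tgt_s is None or tgt_c is None:
            continue
        res = relative_expression(tgt_s, ref_s, tgt_c, ref_c,
                                  amplification_efficiency)
        for sid in (sample, control):
            mrt = pick(sid, gene, "minus_RT", False)
            if mrt is not None and check_minus_rt(mrt, rt_threshold) == "contaminated":
                res.contamination_flag = True
        results.append(res)
    return results


def ct_table_to_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "target_gene": r.target_gene,
          "priming": r.priming, "is_reference": int(r.is_reference),
          "ct_values": ",".join(f"{v:.4f}" for v in r.ct_values)}
         for r in records])


def write_ct_table(records: Iterable[CtRecord], path: str | Path) -> None:
    ct_table_to_frame(records).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"ct_values": str})
    return [CtRecord(sample_id=str(row.sample_id), target_gene=str(row.target_gene),
                     priming=str(row.priming),
                     ct_values=tuple(float(v) for v in row.ct_values.split(",")),
                     is_reference=bool(row.is_reference))
            for row in df.itertuples()]


def write_rq_results(results: Iterable[RqResult], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
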