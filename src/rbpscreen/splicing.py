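"""Splicing defect versus intron turnover from intron-body and junction reads.

An accumulation of intron-mapping reads in a mutant has two explanations:
(1) splicing is inefficient, so unspliced pre-mRNA accumulates — then reads
spanning exon–intron junctions (EIJs) accumulate together with intron-body
reads; or (2) splicing proceeds but the excised intron lariat is not turned
over — then intron-body reads accumulate while EIJ reads stay flat.  The
classifier forms mutant/wild-type CPM ratios for both read types per intron
and applies fold thresholds:

    r_int >= theta_up and r_eij >= theta_up            -> splicing_defect
    r_int >= theta_up and r_eij within theta_flat of 1 -> intron_turnover
    r_int <  theta_up                                  -> unchanged
    otherwise                                          -> ambiguous

Counts are normalized to counts-per-million with a pseudocount, so the
classification is invariant to joint library rescaling.  The thresholds
(theta_up = 2, theta_flat = 1.5, pseudocount 0.5) are this package's
operationalization of a comparison the screen makes graphically.  The
classifier consumes count tables; junction-read extraction (with its minimum
junction overhang) happens upstream and is recorded as table metadata.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "IntronCountRecord",
    "cpm",
    "accumulation_ratios",
    "classify_intron",
    "classify_table",
    "strain_call",
]


@dataclass(frozen=True)
class IntronCountRecord:
    intron_id: str
    gene_id: str
    condition: str  # "wt" | "mutant"
    intron_reads: int
    eij_reads: int
    library_size: int

    def __post_init__(self):
        if self.intron_reads < 0 or self.eij_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def cpm(record: IntronCountRecord, pseudocount: float = 0.5) -> tuple[float, float]:
    """Counts-per-million for intron-body and EIJ reads, with a pseudocount."""
    scale = 1e6 / record.library_size
    return (
        (record.intron_reads + pseudocount) * scale,
        (record.eij_reads + pseudocount) * scale,
    )


def accumulation_ratios(
    mutant: IntronCountRecord, wildtype: IntronCountRecord, pseudocount: float = 0.5
) -> tuple[float, float]:
    """Mutant/wt CPM ratio for intron-body and EIJ reads of one intron."""
    if mutant.intron_id != wildtype.intron_id:
        raise ValueError(
            f"records refer to different introns: {mutant.intron_id!r} vs {wildtype.intron_id!r}"
        )
    mi, me = cpm(mutant, pseudocount)
    wi, we = cpm(wildtype, pseudocount)
    return mi / wi, me / we


def classify_intron(
    r_int: float, r_eij: float, theta_up: float = 2.0, theta_flat: float = 1.5
) -> str:
    """Classify one intron from its (intron, EIJ) accumulation ratios."""
    if theta_up <= 1 or theta_flat <= 1:
        raise ValueError("thresholds must exceed 1")
    if r_int < theta_up:
        return "unchanged"
    if r_eij >= theta_up:
        return "splicing_defect"
    if 1.0 / theta_flat <= r_eij <= theta_flat:
        return "intron_turnover"
    return "ambiguous"


def classify_table(
    counts: pd.DataFrame,
    theta_up: float = 2.0,
    theta_flat: float = 1.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Classify every intron in a long count table.

    Expected columns: intron_id, gene_id, condition (wt/mutant), intron_reads,
    eij_reads, library_size, and optionally replicate.  Replicate counts are
    summed per condition before the ratio is formed (library sizes summed
    accordingly); per-replicate ratios are additionally reported for
    diagnostics when a replicate column is present.
    """
    required = {"intron_id", "condition", "intron_reads", "eij_reads", "library_size"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table lacks columns {sorted(missing)}")

    agg = (
        counts.groupby(["intron_id", "condition"], sort=True)
        .agg(
            gene_id=("gene_id", "first") if "gene_id" in counts.columns else ("intron_id", "first"),
            intron_reads=("intron_reads", "sum"),
            eij_reads=("eij_reads", "sum"),
            library_size=("library_size", "sum"),
        )
        .reset_index()
    )
    wide = agg.pivot(index="intron_id", columns="condition",
                     values=["intron_reads", "eij_reads", "library_size"])
    if "mutant" not in wide["intron_reads"] or "wt" not in wide["intron_reads"]:
        raise ValueError("count table must contain both 'wt' and 'mutant' conditions")
    wide = wide.dropna()

    rows = []
    gene_of = dict(zip(agg["intron_id"], agg["gene_id"]))
    for intron_id, row in wide.iterrows():
        mut = IntronCountRecord(
            str(intron_id), str(gene_of[intron_id]), "mutant",
            int(row[("intron_reads", "mutant")]), int(row[("eij_reads", "mutant")]),
            int(row[("library_size", "mutant")]),
        )
        wt = IntronCountRecord(
            str(intron_id), str(gene_of[intron_id]), "wt",
            int(row[("intron_reads", "wt")]), int(row[("eij_reads", "wt")]),
            int(row[("library_size", "wt")]),
        )
        r_int, r_eij = accumulation_ratios(mut, wt, pseudocount)
        rows.append(
            {
                "intron_id": str(intron_id),
                "gene_id": str(gene_of[intron_id]),
                "r_int": r_int,
                "r_eij": r_eij,
                "call": classify_intron(r_int, r_eij, theta_up, theta_flat),
            }
        )
    return pd.DataFrame(rows)


def strain_call(classified: pd.DataFrame, min_introns: int = 10) -> dict:
    """Strain-level verdict from per-intron calls.

    A strain is ``splicing_defective`` when at least ``min_introns`` introns
    are splicing_defect calls and those outnumber intron_turnover calls;
    symmetrically for ``turnover_defective``; otherwise ``normal``.  The
    supporting intron set of the winning class is returned alongside.
    """
    tally = Counter(classified["call"])
    n_sd, n_to = tally.get("splicing_defect", 0), tally.get("intron_turnover", 0)
    if n_sd >= min_introns and n_sd > n_to:
        verdict = "splicing_defective"
        support = set(classified.loc[classified["call"] == "splicing_defect", "intron_id"])
    elif n_to >= min_introns and n_to > n_sd:
        verdict = "turnover_defective"
        support = set(classified.loc[classified["call"] == "intron_turnover", "intron_id"])
    else:
        verdict = "normal"
        support = set()
    return {"verdict": verdict, "supporting_introns": support, "counts": dict(tally)}
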