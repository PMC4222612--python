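"""Validation arithmetic: efficiency-corrected qPCR ratios and motif enrichment.

Reporter expression is quantified relative to an internal control with the
efficiency-corrected ratio

    ratio = eff_target^(-Ct_target) / eff_reference^(-Ct_reference)

where the efficiencies are the per-cycle amplification factors (2.0 for
perfect doubling) and Ct the critical cycles.  Candidate regulatory motifs
(e.g. the hexamer UUAAAC) are scored by exact occurrence counting on the
RNA alphabet and tested for enrichment between a target and a background
sequence set via the hypergeometric overlap machinery, on per-sequence
presence/absence (robust to length differences between sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .overlap import GeneSet, overlap_test

__all__ = [
    "QpcrSample",
    "MotifSpec",
    "qpcr_ratio",
    "qpcr_summary",
    "count_motif",
    "motif_enrichment",
]

_RNA = set("ACGU")


@dataclass(frozen=True)
class QpcrSample:
    sample_id: str
    condition: str
    ct_target: float
    ct_reference: float
    eff_target: float = 2.0
    eff_reference: float = 2.0


@dataclass(frozen=True)
class MotifSpec:
    motif: str
    allow_overlaps: bool = False

    def __post_init__(self):
        norm = self.motif.upper().replace("T", "U")
        if len(norm) < 4:
            raise ValueError(f"motif must be >=4 nt, got {self.motif!r}")
        bad = set(norm) - _RNA
        if bad:
            raise ValueError(
                f"motif may only contain A/C/G/U (exact matching; IUPAC degeneracy "
                f"is not supported): bad characters {sorted(bad)}"
            )
        object.__setattr__(self, "motif", norm)


def qpcr_ratio(sample: QpcrSample) -> float:
    """Efficiency-corrected target/reference expression ratio for one sample."""
    for name, eff in (("eff_target", sample.eff_target), ("eff_reference", sample.eff_reference)):
        if not 1.0 < eff <= 2.0:
            raise ValueError(f"{name} must be in (1, 2], got {eff}")
    if sample.ct_target <= 0 or sample.ct_reference <= 0:
        raise ValueError("Ct values must be positive")
    return sample.eff_target ** (-sample.ct_target) / sample.eff_reference ** (-sample.ct_reference)


def qpcr_summary(
    replicates: list[QpcrSample], normalizer: str | None = None
) -> pd.DataFrame:
    """Per-condition mean ± sd of efficiency-corrected ratios.

    With ``normalizer`` set to a condition name, all means and sds are
    rescaled so that condition's mean equals 1 (the usual reporter-assay
    presentation).  Single-replicate conditions carry sd = NaN and are
    flagged.
    """
    rows = [(s.condition, qpcr_ratio(s)) for s in replicates]
    df = pd.DataFrame(rows, columns=["condition", "ratio"])
    out = df.groupby("condition", sort=True)["ratio"].agg(["mean", "std", "count"]).reset_index()
    out["single_replicate"] = out["count"] == 1
    if normalizer is not None:
        if normalizer not in set(out["condition"]):
            raise ValueError(f"normalizer condition {normalizer!r} not present")
        scale = float(out.loc[out["condition"] == normalizer, "mean"].iloc[0])
        out["mean"] /= scale
        out["std"] /= scale
    return out


def _normalize_seq(seq: str) -> str:
    return str(seq).upper().replace("T", "U")


def count_motif(sequence: str, spec: MotifSpec) -> int:
    """Exact occurrences of the motif on the given strand (U and T equivalent)."""
    seq = _normalize_seq(sequence)
    motif = spec.motif
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1 if spec.allow_overlaps else i + len(motif)


def motif_enrichment(targets: dict[str, str], background: dict[str, str], spec: MotifSpec) -> dict:
    """Motif presence enrichment in target vs background sequences.

    ``targets`` and ``background`` map sequence ids to sequences (ids must be
    disjoint between the sets).  Each sequence scores present/absent; the
    one-sided hypergeometric test asks whether motif-bearing sequences are
    over-represented among the targets, with the union of both sets as the
    universe.
    """
    if not targets:
        raise ValueError("target sequence set is empty")
    if not background:
        raise ValueError("background sequence set is empty")
    shared = set(targets) & set(background)
    if shared:
        raise ValueError(f"sequence ids shared between sets, e.g. {sorted(shared)[:3]}")
    universe = frozenset(targets) | frozenset(background)
    with_motif = frozenset(
        sid for sid, seq in {**targets, **background}.items() if count_motif(seq, spec) > 0
    )
    res = overlap_test(
        GeneSet("targets", frozenset(targets), universe),
        GeneSet("motif_bearing", with_motif, universe),
    )
    return {
        "target_rate": sum(1 for s in targets if s in with_motif) / len(targets),
        "background_rate": sum(1 for s in background if s in with_motif) / len(background),
        "p_value": res.p_value,
        "test": res,
    }
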