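"""Strain/gene/feature registry: domain accounting, deletion verification, tabular I/O.

The screen starts from a registry of predicted RNA-binding proteins (RBPs),
each carrying one or more RNA-binding domain assignments (RRM, PUF, KH, zinc
fingers, ...), and a collection of deletion strains, one per non-essential
candidate gene.  This module holds the registry record types, the protein /
essentiality accounting, and the microarray-based check that a strain's
target gene really is deleted.

All registry files are plain TSV with a header line.  Feature coordinates,
when present, are 1-based inclusive on disk and converted to 0-based
half-open in memory (the GFF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Essentiality",
    "VerificationStatus",
    "DomainAssignment",
    "StrainRecord",
    "FeatureAnnotation",
    "AnnotationConflictError",
    "count_unique_proteins",
    "essential_fraction",
    "essentiality_enrichment",
    "verify_deletion",
    "verify_strains",
    "read_domains",
    "read_strains",
    "read_features",
    "write_tsv",
]


class Essentiality(str, Enum):
    ESSENTIAL = "essential"
    NONESSENTIAL = "nonessential"
    UNKNOWN = "unknown"


class VerificationStatus(str, Enum):
    VERIFIED = "verified"
    NOT_DELETED = "not_deleted"
    UNCHECKED = "unchecked"


@dataclass(frozen=True)
class DomainAssignment:
    """One RNA-binding-domain assignment on one protein.

    A protein may carry assignments from several domain families; its
    essentiality must be identical across all of them.
    """

    protein_id: str
    domain_name: str
    pfam_id: str
    essentiality: Essentiality = Essentiality.UNKNOWN


@dataclass(frozen=True)
class StrainRecord:
    """A deletion strain and the gene it is supposed to lack."""

    strain_id: str
    deleted_gene: str
    verified: VerificationStatus = VerificationStatus.UNCHECKED


@dataclass(frozen=True)
class FeatureAnnotation:
    """An array feature (exon, intron or ncRNA) and its probes.

    Intron features carry the gene_id of their parent transcript so that
    intron/exon concordance can be evaluated per gene.
    """

    feature_id: str
    gene_id: str
    feature_class: str  # "exon" | "intron" | "ncRNA"
    probe_ids: tuple[str, ...] = field(default_factory=tuple)


class AnnotationConflictError(ValueError):
    """Raised when one protein carries conflicting essentiality annotations."""


def count_unique_proteins(assignments: Iterable[DomainAssignment]) -> dict[str, int]:
    """Count distinct proteins in a list of domain assignments.

    Returns ``{"unique", "essential", "nonessential", "unknown"}`` where the
    three category counts partition ``unique``.  A protein appearing under
    several domain families is counted once; conflicting essentiality for a
    single protein raises :class:`AnnotationConflictError` rather than being
    silently resolved.
    """
    seen: dict[str, Essentiality] = {}
    for a in assignments:
        ess = Essentiality(a.essentiality)
        if a.protein_id in seen:
            if seen[a.protein_id] is not ess:
                raise AnnotationConflictError(
                    f"protein {a.protein_id!r} annotated both "
                    f"{seen[a.protein_id].value} and {ess.value}"
                )
        else:
            seen[a.protein_id] = ess
    counts = {"unique": len(seen), "essential": 0, "nonessential": 0, "unknown": 0}
    for ess in seen.values():
        counts[ess.value] += 1
    return counts


def essential_fraction(assignments: Iterable[DomainAssignment]) -> float:
    """Percentage of unique proteins whose gene is essential, to one decimal.

    The percentage is truncated (not rounded) at the first decimal — the
    reporting convention of the screen's own summary tables (47/136 ->
    34.5%, not 34.6%).
    """
    counts = count_unique_proteins(assignments)
    if counts["unique"] == 0:
        raise ValueError("essential_fraction requires at least one protein")
    import math

    return math.floor(1000.0 * counts["essential"] / counts["unique"]) / 10.0


def essentiality_enrichment(k_essential: int, n_rbp: int, genome_fraction: float) -> float:
    """Exact upper-tail binomial P(X >= k | n, p).

    Tests whether essential genes are over-represented among the ``n_rbp``
    RBP-encoding genes given the genome-wide essential fraction.
    """
    if not 0 < genome_fraction < 1:
        raise ValueError(f"genome_fraction must be in (0, 1), got {genome_fraction}")
    if not 0 <= k_essential <= n_rbp:
        raise ValueError(f"need 0 <= k <= n, got k={k_essential}, n={n_rbp}")
    from scipy import stats

    return float(stats.binom.sf(k_essential - 1, n_rbp, genome_fraction))


def verify_deletion(
    strain: StrainRecord,
    probe_signals: Mapping[str, Sequence[str]] | pd.DataFrame,
    mutant_signal: Mapping[str, float] | pd.Series,
    background: float,
) -> StrainRecord:
    """Check a deletion from mutant-channel microarray signal.

    A strain is ``verified`` iff every probe of its deleted gene is at or
    below ``background`` in the mutant channel; a single probe clearly above
    background means the gene is still expressed (``not_deleted``).  A gene
    with no probes on the array cannot be checked and stays ``unchecked``
    (with a warning), mirroring the cases that needed gene-specific PCR.

    Parameters
    ----------
    probe_signals : mapping gene_id -> probe ids
    mutant_signal : mapping probe_id -> mutant-channel signal
    background : signal threshold
    """
    if isinstance(probe_signals, pd.DataFrame):
        probe_signals = {
            g: list(sub["probe_id"]) for g, sub in probe_signals.groupby("gene_id")
        }
    probes = list(probe_signals.get(strain.deleted_gene, []))
    if not probes:
        warnings.warn(
            f"no probes for {strain.deleted_gene!r}; strain "
            f"{strain.strain_id!r} left unchecked",
            stacklevel=2,
        )
        return StrainRecord(strain.strain_id, strain.deleted_gene, VerificationStatus.UNCHECKED)
    sig = np.asarray([mutant_signal[p] for p in probes], dtype=float)
    status = (
        VerificationStatus.VERIFIED
        if np.all(sig <= background)
        else VerificationStatus.NOT_DELETED
    )
    return StrainRecord(strain.strain_id, strain.deleted_gene, status)


def verify_strains(
    strains: Iterable[StrainRecord],
    probe_signals: Mapping[str, Sequence[str]],
    mutant_signals: Mapping[str, Mapping[str, float]],
    background_quantile: float = 0.05,
) -> list[StrainRecord]:
    """Verify every strain against its own mutant-channel signal table.

    The background threshold defaults to the ``background_quantile`` of each
    strain's full mutant-channel signal distribution (5th percentile), since
    silenced probes sit in the low tail of the array.
    """
    out = []
    for strain in strains:
        sig = mutant_signals[strain.strain_id]
        thresh = float(np.quantile(np.asarray(list(sig.values()), dtype=float), background_quantile))
        out.append(verify_deletion(strain, probe_signals, sig, thresh))
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def read_domains(path: str | Path) -> list[DomainAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        DomainAssignment(r.protein_id, r.domain_name, r.pfam_id, Essentiality(r.essentiality))
        for r in df.itertuples(index=False)
    ]


def read_strains(path: str | Path) -> list[StrainRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "verified" not in df.columns:
        df["verified"] = VerificationStatus.UNCHECKED.value
    if df["deleted_gene"].duplicated().any():
        dup = df.loc[df["deleted_gene"].duplicated(), "deleted_gene"].iloc[0]
        raise ValueError(f"deleted_gene must be unique per strain; {dup!r} repeats")
    return [
        StrainRecord(r.strain_id, r.deleted_gene, VerificationStatus(r.verified))
        for r in df.itertuples(index=False)
    ]


def read_features(path: str | Path) -> list[FeatureAnnotation]:
    """Read features.tsv (feature_id, gene_id, feature_class, probe_ids comma-joined).

    Optional ``start``/``end`` columns are 1-based inclusive on disk; they are
    returned as extra 0-based half-open attributes on the dataframe route only
    and ignored here (the pipeline never needs coordinates).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    feats = []
    for r in df.itertuples(index=False):
        probes = tuple(p for p in str(getattr(r, "probe_ids", "")).split(",") if p and p != "nan")
        feats.append(FeatureAnnotation(r.feature_id, r.gene_id, r.feature_class, probes))
    probe_owner: dict[str, str] = {}
    for f in feats:
        for p in f.probe_ids:
            if p in probe_owner and probe_owner[p] != f.feature_id:
                raise ValueError(f"probe {p!r} maps to multiple features")
            probe_owner[p] = f.feature_id
    return feats


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
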