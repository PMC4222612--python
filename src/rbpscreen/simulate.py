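"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (spec, seed) and returns truth labels
alongside the data, so every downstream stage can be exercised end-to-end
without the original deposited experiments.  Defaults encode the study
conditions: regulons of 4–104 genes per affected strain (mostly up-regulated),
first-order decay with class-median half-lives of 31 min (coding), 30.5 min
(ncRNA) and 14.5 min (introns) and a replicate CV of 12.6%, RIp-chip
rankings where bound targets sit at the top, negative-binomial intron /
exon–intron-junction counts under normal, splicing-defect and
intron-turnover regimes, and 3'-UTR-like sequences with an embedded hexamer.

Array platform scale mirrors the screen: 5037 coding genes (two probes
each), 496 ncRNAs, 1491 introns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegulonSpec",
    "DecaySpec",
    "SplicingRegime",
    "N_CODING",
    "N_NCRNA",
    "N_INTRONS",
    "gen_expression",
    "gen_decay",
    "gen_ripchip",
    "gen_splicing_counts",
    "gen_utr_sequences",
    "gen_screen_truth",
    "write_fasta",
    "read_fasta",
]

# array platform scale
N_CODING = 5037
N_NCRNA = 496
N_INTRONS = 1491


@dataclass(frozen=True)
class RegulonSpec:
    """True differential-expression structure of one deletion strain."""

    strain_id: str
    target_gene_ids: frozenset[str]
    direction: str = "up"  # "up" | "down" | "mixed"
    log2_effect_mean: float = 2.0
    log2_effect_sd: float = 0.2
    n_replicates: int = 3

    def __post_init__(self):
        object.__setattr__(self, "target_gene_ids", frozenset(self.target_gene_ids))
        if self.target_gene_ids and not 4 <= len(self.target_gene_ids) <= 104:
            raise ValueError(
                f"regulon size {len(self.target_gene_ids)} outside the observed 4–104 range"
            )
        if self.log2_effect_sd <= 0:
            raise ValueError("effect sd must be positive")


@dataclass(frozen=True)
class DecaySpec:
    """Class-structured first-order decay with multiplicative replicate noise."""

    class_medians: tuple[tuple[str, float], ...] = (
        ("exon", 31.0), ("ncRNA", 30.5), ("intron", 14.5),
    )
    dispersion: float = 0.5  # log-scale sd of half-lives within a class
    labelling_time: float = 7.0  # minutes; 7 or 10 in practice
    replicate_cv: float = 0.126
    n_replicates: int = 3

    def __post_init__(self):
        if any(m <= 0 for _, m in self.class_medians):
            raise ValueError("class median half-lives must be positive")
        if self.labelling_time <= 0:
            raise ValueError("labelling time must be positive")

    @property
    def medians(self) -> dict[str, float]:
        return dict(self.class_medians)


@dataclass(frozen=True)
class SplicingRegime:
    regime: str = "normal"  # "normal" | "splicing_defect" | "intron_turnover"
    fold: float = 1.0
    nb_dispersion: float = 0.1

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.regime not in ("normal", "splicing_defect", "intron_turnover"):
            raise ValueError(f"unknown regime {self.regime!r}")


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("seed is required: generators are deterministic by contract")
    return np.random.default_rng(seed)


def gene_ids(n: int, prefix: str = "gene") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def gen_expression(
    spec: RegulonSpec,
    n_genes: int = 2000,
    noise_sd: float = 0.2,
    dye_bias=None,
    seed: int | None = None,
    prefix: str = "gene",
    feature_class: str = "exon",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-colour expression table for one strain plus per-gene truth labels.

    Non-target log-ratios are Normal(dye_bias(A), noise_sd); targets are
    shifted by a signed log2 effect drawn once per gene from
    Normal(effect_mean, effect_sd); replicate columns are independent.
    Intensities A are drawn uniformly on [6, 14] (log2 scale).

    Returns (table with feature_id/feature_class/M1..Mk/A1..Ak, truth frame
    with feature_id/is_target/true_direction/true_log2_effect).
    """
    rng = _require_seed(seed)
    if len(spec.target_gene_ids) > n_genes:
        raise ValueError("more targets than genes")
    ids = gene_ids(n_genes, prefix)
    targets = sorted(spec.target_gene_ids)
    missing = set(targets) - set(ids)
    if missing:
        raise ValueError(f"target ids not in generated universe, e.g. {sorted(missing)[:3]}")
    k = spec.n_replicates
    target_idx = {g: i for i, g in enumerate(ids)}

    effect = np.zeros(n_genes)
    direction = np.array([""] * n_genes, dtype=object)
    for g in targets:
        mag = rng.normal(spec.log2_effect_mean, spec.log2_effect_sd)
        if spec.direction == "mixed":
            sign = 1.0 if rng.random() < 0.5 else -1.0
        else:
            sign = 1.0 if spec.direction == "up" else -1.0
        effect[target_idx[g]] = sign * abs(mag)
        direction[target_idx[g]] = "up" if sign > 0 else "down"

    table = pd.DataFrame({"feature_id": ids, "feature_class": feature_class})
    for j in range(1, k + 1):
        A = rng.uniform(6, 14, n_genes)
        bias = dye_bias(A) if dye_bias is not None else 0.0
        M = rng.normal(0.0, noise_sd, n_genes) + bias + effect
        table[f"M{j}"] = M
        table[f"A{j}"] = A
    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "is_target": effect != 0,
            "true_direction": direction,
            "true_log2_effect": effect,
        }
    )
    return table, truth


def gen_decay(
    spec: DecaySpec, n_per_class: int = 1000, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long decay table (fraction mode) plus true half-lives.

    True half-lives are log-normal with the configured class median; the
    labelled fraction f = 1 - 2^(-t/T) receives multiplicative log-normal
    noise with the configured replicate CV and is clipped to (0, 1).
    """
    rng = _require_seed(seed)
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    sigma_noise = math.sqrt(math.log(1.0 + spec.replicate_cv**2))
    rows, truth_rows = [], []
    for fclass, median in spec.class_medians:
        T = median * np.exp(rng.normal(0.0, spec.dispersion, n_per_class))
        ids = [f"{fclass}_{i:05d}" for i in range(n_per_class)]
        f_true = 1.0 - 2.0 ** (-spec.labelling_time / T)
        for rep in range(1, spec.n_replicates + 1):
            if spec.replicate_cv > 0:
                noise = np.exp(rng.normal(-0.5 * sigma_noise**2, sigma_noise, n_per_class))
            else:
                noise = 1.0
            f = np.clip(f_true * noise, 1e-6, 1.0 - 1e-6)
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": ids,
                        "feature_class": fclass,
                        "mode": "fraction",
                        "value": f,
                        "time_min": spec.labelling_time,
                        "replicate": rep,
                    }
                )
            )
        truth_rows.append(
            pd.DataFrame({"feature_id": ids, "feature_class": fclass, "true_half_life": T})
        )
    return pd.concat(rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)


def gen_ripchip(
    n_genes: int = 2000,
    true_targets: frozenset[str] | set[str] = frozenset(),
    target_shift: float = 5.0,
    n_replicates: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked-enrichment tables (one row per gene per replicate) plus truth.

    Non-target enrichments are standard normal; targets are shifted up by
    ``target_shift`` enrichment units.  Replicates are independent draws.
    """
    rng = _require_seed(seed)
    ids = gene_ids(n_genes)
    is_target = np.isin(ids, sorted(true_targets))
    if is_target.sum() != len(set(true_targets)):
        raise ValueError("some true targets are not in the generated universe")
    frames = []
    for rep in range(1, n_replicates + 1):
        enr = rng.normal(0.0, 1.0, n_genes) + target_shift * is_target
        frames.append(pd.DataFrame({"gene_id": ids, "enrichment": enr, "replicate": rep}))
    truth = pd.DataFrame({"gene_id": ids, "is_target": is_target})
    return pd.concat(frames, ignore_index=True), truth


def gen_splicing_counts(
    n_introns: int = 1491,
    regime_map: dict[str, SplicingRegime] | None = None,
    lib_sizes: tuple[int, int] = (10_000_000, 10_000_000),
    base_mean_intron: float = 50.0,
    base_mean_eij: float = 20.0,
    n_replicates: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial intron/EIJ count table (wt + mutant) plus truth.

    Baseline means are per 10M reads and scaled by library size.  A
    ``splicing_defect`` regime multiplies both the intron and the EIJ mean in
    the mutant by ``fold``; ``intron_turnover`` multiplies the intron mean
    only.  NB is parameterized by (mean, dispersion alpha) with
    var = mu + alpha mu^2.  ``lib_sizes`` are per-library (wt, mutant) depths;
    each condition is sequenced as ``n_replicates`` independent libraries
    (biological duplicates by default), which the classifier sums.
    """
    rng = _require_seed(seed)
    regime_map = regime_map or {}
    ids = [f"intron_{i:05d}" for i in range(n_introns)]
    unknown = set(regime_map) - set(ids)
    if unknown:
        raise ValueError(f"regimes for unknown introns, e.g. {sorted(unknown)[:3]}")
    lib_wt, lib_mut = lib_sizes

    def _nb(mean: np.ndarray, alpha: float) -> np.ndarray:
        # scipy/NumPy NB: n = 1/alpha, p = n / (n + mu)
        n = 1.0 / alpha
        p = n / (n + mean)
        return rng.negative_binomial(n, p)

    default = SplicingRegime()
    regimes = [regime_map.get(i, default) for i in ids]
    alpha = np.array([r.nb_dispersion for r in regimes])
    if len(set(alpha)) > 1:
        raise ValueError("a single NB dispersion per table is assumed")
    alpha = float(alpha[0]) if len(alpha) else 0.1

    fold_int = np.array(
        [r.fold if r.regime in ("splicing_defect", "intron_turnover") else 1.0 for r in regimes]
    )
    fold_eij = np.array([r.fold if r.regime == "splicing_defect" else 1.0 for r in regimes])

    base_i = rng.lognormal(math.log(base_mean_intron), 0.5, n_introns)
    base_e = rng.lognormal(math.log(base_mean_eij), 0.5, n_introns)

    frames = []
    for cond, lib, fi, fe in (
        ("wt", lib_wt, 1.0, 1.0),
        ("mutant", lib_mut, fold_int, fold_eij),
    ):
        scale = lib / 1e7
        for rep in range(1, n_replicates + 1):
            frames.append(
                pd.DataFrame(
                    {
                        "intron_id": ids,
                        "gene_id": [f"gene_of_{i}" for i in ids],
                        "condition": cond,
                        "replicate": rep,
                        "intron_reads": _nb(base_i * fi * scale, alpha),
                        "eij_reads": _nb(base_e * fe * scale, alpha),
                        "library_size": lib,
                    }
                )
            )
    truth = pd.DataFrame(
        {"intron_id": ids, "true_regime": [r.regime for r in regimes],
         "true_fold": [r.fold for r in regimes]}
    )
    return pd.concat(frames, ignore_index=True), truth


def gen_utr_sequences(
    n_target: int = 50,
    n_background: int = 50,
    motif: str = "UUAAAC",
    embed_rate: float = 0.8,
    length: int = 200,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Target and background 3'-UTR-like sequence sets plus embedding truth.

    Background sequences are i.i.d. uniform RNA; the motif is written at a
    uniform random position into ``embed_rate`` of the target sequences.
    """
    rng = _require_seed(seed)
    motif = motif.upper().replace("T", "U")
    if length < len(motif):
        raise ValueError(f"sequence length {length} shorter than motif ({len(motif)} nt)")
    alphabet = np.array(list("ACGU"))

    def _random_seq() -> list[str]:
        return list(alphabet[rng.integers(0, 4, length)])

    targets, truth_rows = {}, []
    for i in range(n_target):
        seq = _random_seq()
        embedded = bool(rng.random() < embed_rate)
        if embedded:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos : pos + len(motif)] = list(motif)
        sid = f"target_{i:04d}"
        targets[sid] = "".join(seq)
        truth_rows.append({"seq_id": sid, "embedded": embedded})
    background = {f"bg_{i:04d}": "".join(_random_seq()) for i in range(n_background)}
    return targets, background, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# screen-level truth


def gen_screen_truth(
    n_affected: int = 25,
    n_strains: int = 74,
    n_up_only: int = 483,
    n_down_only: int = 287,
    n_both: int = 46,
    max_regulon: int = 104,
    min_regulon: int = 4,
    seed: int | None = None,
) -> list[RegulonSpec]:
    """Regulon truth for a whole deletion screen.

    ``n_affected`` strains receive non-empty regulons; the remaining strains
    are true nulls.  Distinct coding genes are partitioned into up-only,
    down-only and both-direction pools (defaults give a union of 816 genes,
    the consistent counterpart of the published partition); each both-gene is
    up in one strain and down in another.  Regulon sizes fall in the observed
    4–104 range.
    """
    rng = _require_seed(seed)
    ids = gene_ids(N_CODING)
    n_union = n_up_only + n_down_only + n_both
    pool = list(rng.choice(ids, size=n_union, replace=False))
    up_pool = pool[:n_up_only]
    down_pool = pool[n_up_only : n_up_only + n_down_only]
    both_pool = pool[n_up_only + n_down_only :]

    # incidences: each up/down gene once, each both gene once up and once down
    up_assign = up_pool + both_pool
    down_assign = down_pool + both_pool
    n_strain_up = (n_affected + 1) // 2
    n_strain_down = n_affected - n_strain_up

    def _split(genes: list[str], parts: int) -> list[list[str]]:
        if parts == 0:
            return []
        genes = list(genes)
        rng.shuffle(genes)
        # sizes as equal as possible, clipped to the observed range
        base = len(genes) // parts
        sizes = [base + (1 if i < len(genes) % parts else 0) for i in range(parts)]
        if not all(min_regulon <= s <= max_regulon for s in sizes):
            raise ValueError("cannot partition genes into regulons within the 4–104 range")
        out, start = [], 0
        for s in sizes:
            out.append(genes[start : start + s])
            start += s
        return out

    up_parts = _split(up_assign, n_strain_up)
    down_parts = _split(down_assign, n_strain_down)

    specs = []
    idx = 0
    for part in up_parts:
        specs.append(RegulonSpec(f"strain_{idx:03d}", frozenset(part), direction="up"))
        idx += 1
    for part in down_parts:
        specs.append(RegulonSpec(f"strain_{idx:03d}", frozenset(part), direction="down"))
        idx += 1
    for _ in range(n_strains - n_affected):
        specs.append(RegulonSpec(f"strain_{idx:03d}", frozenset(), direction="up"))
        idx += 1
    return specs


# ---------------------------------------------------------------------------
# FASTA I/O (RNA alphabet with U on disk)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.replace("T", "U")), id=sid, description="") for sid, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
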