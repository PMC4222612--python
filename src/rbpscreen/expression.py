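"""Per-strain differential expression: normalization, one-class SAM, concordance rules.

Each deletion strain is compared to wild type on two-colour arrays, giving a
per-feature table of replicate log2 ratios M = log2(mutant/wt) and mean log
intensities A.  Intensity-dependent dye bias is removed by loess of M on A;
stability experiments are median-centred instead.  Differentially expressed
features are then called with a one-class SAM (Significance Analysis of
Microarrays): a moderated statistic

    d_i = m_i / (s_i + s0)

with m_i the mean log-ratio, s_i its standard error, and s0 a fudge factor
chosen to decouple d from s; the null distribution comes from sign-flip
permutations of the replicate columns and false discovery rates from
permuted exceedance counts.

With 2–3 replicates only 4–8 sign assignments exist.  The identity
assignment (no flip) reproduces the observed statistics and is excluded from
the null set, and the FDR numerator is the *mean* permuted exceedance count,
which stays conservative at this granularity (the median-count estimator
degenerates to 0 for the single most extreme gene in a large fraction of
pure-null datasets when only a handful of permutations exist).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import FeatureAnnotation

__all__ = [
    "DECall",
    "SamResult",
    "loess_normalize",
    "median_center",
    "sam_one_class",
    "aggregate_probes",
    "concordance_classify",
    "screen_summary",
    "m_columns",
    "a_columns",
]


def m_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("M")]


def a_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("A")]


def loess_normalize(table: pd.DataFrame, span: float = 0.4) -> pd.DataFrame:
    """Remove intensity-dependent dye bias: per replicate, M <- M - loess(M ~ A).

    Expects paired columns M1..Mk / A1..Ak.  Requires at least 50 features for
    a stable fit and a non-degenerate intensity axis.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(table) < 50:
        raise ValueError(f"loess normalization needs >=50 features, got {len(table)}")
    mcols, acols = m_columns(table), a_columns(table)
    if len(mcols) != len(acols):
        raise ValueError("mismatched M and A replicate columns")
    out = table.copy()
    for mc, ac in zip(mcols, acols):
        a = table[ac].to_numpy(float)
        m = table[mc].to_numpy(float)
        if np.ptp(a) == 0:
            raise ValueError(f"intensity column {ac!r} is constant; loess fit is degenerate")
        # it=0: plain local regression; robustness iterations buy nothing for
        # MA-trend removal and add variance at the intensity extremes
        fit = lowess(m, a, frac=span, it=0, return_sorted=False, delta=0.01 * np.ptp(a))
        out[mc] = m - fit
    return out


def median_center(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-replicate median from every M column (exact zero median)."""
    mcols = m_columns(table)
    if not mcols or len(table) == 0:
        raise ValueError("median_center needs a non-empty table with M columns")
    out = table.copy()
    for mc in mcols:
        out[mc] = table[mc] - table[mc].median()
    return out


# ---------------------------------------------------------------------------
# one-class SAM


@dataclass(frozen=True)
class DECall:
    feature_id: str
    d_statistic: float
    q_value: float
    direction: str  # "up" | "down"
    fold_change: float


@dataclass
class SamResult:
    """Full SAM output: the call list plus per-feature diagnostics."""

    calls: list[DECall]
    d: pd.Series  # per-feature observed d
    q_values: pd.Series
    s0: float
    delta: float
    cut_up: float
    cut_low: float
    pi0: float
    n_permutations: int

    def called_ids(self) -> set[str]:
        return {c.feature_id for c in self.calls}


def _fudge_factor(m: np.ndarray, se: np.ndarray) -> float:
    """s0 minimizing the CV of window-wise MAD of d over an s-percentile grid.

    Candidates are the {0, 5, ..., 100} percentiles of s_i; within each
    candidate, genes are windowed by s-quantile and the coefficient of
    variation of the per-window MAD(d) is computed.
    """
    n = m.size
    n_windows = 100 if n >= 1000 else max(4, n // 10)
    qs = np.quantile(se, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(qs, se, side="right") - 1, 0, n_windows - 1)
    candidates = np.quantile(se, np.arange(0, 101, 5) / 100.0)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = _safe_d(m, se.copy(), float(s0))
        mads = np.array(
            [np.median(np.abs(d[window == w] - np.median(d[window == w])))
             for w in range(n_windows) if np.any(window == w)]
        ) / 0.64
        mu = mads.mean()
        cv = mads.std(ddof=0) / mu if mu > 0 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _sign_assignments(k: int, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Non-identity sign-flip assignments of the k replicate columns."""
    total = 2**k
    if total - 1 <= n_permutations:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=k)))
        return signs[1:]  # drop the all-+1 identity
    idx = rng.choice(total - 1, size=n_permutations, replace=False) + 1
    # decode integers to sign vectors; bit set -> flip
    bits = ((idx[:, None] >> np.arange(k)) & 1).astype(float)
    return 1.0 - 2.0 * bits


def _safe_d(m: np.ndarray, se: np.ndarray, s0: float) -> np.ndarray:
    """d = m / (se + s0), defined as 0 where both numerator and denominator vanish."""
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = m / denom
    d[(m == 0) & (denom == 0)] = 0.0
    return d


def _d_stat(M: np.ndarray, s0: float) -> np.ndarray:
    k = M.shape[1]
    m = M.mean(axis=1)
    se = M.std(axis=1, ddof=1) / np.sqrt(k)
    return _safe_d(m, se, s0)


def sam_one_class(
    table: pd.DataFrame,
    n_permutations: int = 1000,
    delta: float | None = None,
    target_fdr: float | None = None,
    seed: int | None = None,
) -> SamResult:
    """One-class SAM on replicate log-ratios.

    Exactly one of ``delta`` (call threshold on |d - dbar|) or ``target_fdr``
    must be given; with ``target_fdr`` the smallest delta whose estimated FDR
    is at or below the target is used.  Sign-flip permutations are fully
    enumerated whenever 2^k <= n_permutations; otherwise a seeded subset is
    drawn (``seed`` is then required for determinism).

    Returns a :class:`SamResult`; ``result.calls`` is the list of
    :class:`DECall` for the selected delta.
    """
    if (delta is None) == (target_fdr is None):
        raise ValueError("give exactly one of delta or target_fdr")
    mcols = m_columns(table)
    k = len(mcols)
    if k < 2:
        raise ValueError(f"SAM needs >=2 replicates, got {k}")
    M = table[mcols].to_numpy(float)
    if not np.all(np.isfinite(M)):
        raise ValueError("log-ratios must be finite")
    ids = table["feature_id"].astype(str).to_numpy()
    n = len(ids)

    if 2**k > n_permutations and seed is None:
        raise ValueError("seed is required when permutations are subsampled")
    rng = np.random.default_rng(seed)
    signs = _sign_assignments(k, n_permutations, rng)
    B = signs.shape[0]

    m = M.mean(axis=1)
    se = M.std(axis=1, ddof=1) / np.sqrt(k)
    s0 = _fudge_factor(m, se)
    d = _safe_d(m, se, s0)

    d_perm = np.empty((B, n))
    for b in range(B):
        d_perm[b] = _d_stat(M * signs[b][None, :], s0)
    d_perm_sorted = np.sort(d_perm, axis=1)
    dbar = d_perm_sorted.mean(axis=0)  # expected order statistics

    order = np.argsort(d, kind="mergesort")
    ds = d[order]
    diff = ds - dbar

    # personal deltas: a gene is called up at delta iff every gene above it in
    # the ranking also satisfies the criterion (contiguous run from the top)
    up_personal = np.minimum.accumulate(diff[::-1])[::-1]  # cum-min from top
    low_personal = np.minimum.accumulate(-diff)  # cum-min from bottom

    q25, q75 = np.quantile(d_perm, [0.25, 0.75])
    pi0 = min(1.0, np.mean((d_perm > q25) & (d_perm < q75)) / 0.5)

    grid = np.unique(np.concatenate([
        up_personal[up_personal > 0], low_personal[low_personal > 0], [0.0]
    ]))

    def evaluate(dlt: float) -> tuple[float, float, float, int]:
        # a gene needs a strictly positive margin over the expected order
        # statistic; at dlt=0 the >= comparison alone would call every gene
        # of a completely degenerate (all-zero) table
        up_mask = (up_personal >= dlt) & (up_personal > 0)
        low_mask = (low_personal >= dlt) & (low_personal > 0)
        cut_up = ds[up_mask].min() if up_mask.any() else np.inf
        cut_low = ds[low_mask].max() if low_mask.any() else -np.inf
        ncalled = int(up_mask.sum() + low_mask.sum())
        if ncalled == 0:
            return np.inf, -np.inf, 0.0, 0
        counts = (d_perm >= cut_up).sum(axis=1) + (d_perm <= cut_low).sum(axis=1)
        # add-one permutation correction: the expected false-call count is
        # estimated as (1 + total permuted exceedances) / (B + 1), which can
        # never be exactly zero — with only a handful of sign assignments an
        # all-zero count is far too weak evidence for a zero FDR
        false_calls = (1.0 + counts.sum()) / (B + 1)
        fdr = min(1.0, pi0 * false_calls / ncalled)
        return cut_up, cut_low, fdr, ncalled

    fdr_grid = np.empty(grid.size)
    for j, dlt in enumerate(grid):
        fdr_grid[j] = evaluate(dlt)[2] if dlt > 0 else (pi0 if n else 0.0)
    # at delta=0 everything is called; FDR is pi0 by construction
    fdr_grid[grid == 0.0] = pi0

    if delta is None:
        ok = np.nonzero(fdr_grid <= target_fdr)[0]
        chosen = float(grid[ok[0]]) if ok.size else np.inf
    else:
        chosen = float(delta)

    cut_up, cut_low, fdr_at, _ = evaluate(chosen) if np.isfinite(chosen) else (np.inf, -np.inf, 0.0, 0)

    # per-gene q: lowest estimated FDR over the deltas at which the gene is called
    prefix_min = np.minimum.accumulate(fdr_grid)
    q_sorted = np.ones(n)
    for personal, mask_dir in ((up_personal, "up"), (low_personal, "down")):
        callable_ = personal > 0
        if callable_.any():
            idx = np.searchsorted(grid, personal[callable_], side="right") - 1
            q_sorted[callable_] = np.minimum(q_sorted[callable_], prefix_min[idx])

    q = np.empty(n)
    q[order] = q_sorted
    dq = pd.Series(d, index=ids, name="d")
    qs = pd.Series(q, index=ids, name="q")

    calls = []
    called_mask = (d >= cut_up) | (d <= cut_low)
    for i in np.nonzero(called_mask)[0]:
        calls.append(
            DECall(
                feature_id=ids[i],
                d_statistic=float(d[i]),
                q_value=float(q[i]),
                direction="up" if d[i] > 0 else "down",
                fold_change=float(2.0 ** m[i]),
            )
        )
    calls.sort(key=lambda c: (-abs(c.d_statistic), c.feature_id))
    return SamResult(
        calls=calls, d=dq, q_values=qs, s0=s0, delta=chosen,
        cut_up=float(cut_up), cut_low=float(cut_low), pi0=float(pi0), n_permutations=B,
    )


# ---------------------------------------------------------------------------
# probe aggregation and gene-level rules


def aggregate_probes(
    probe_table: pd.DataFrame, probe_to_feature: Mapping[str, str]
) -> pd.DataFrame:
    """Mean the per-replicate log-ratios of the probes of each feature.

    Discordant probe pairs (opposite mean signs, both |M| > 1) are flagged in
    a ``discordant`` column rather than dropped.
    """
    mcols, acols = m_columns(probe_table), a_columns(probe_table)
    tab = probe_table.copy()
    tab["feature_id"] = tab["probe_id"].map(probe_to_feature)
    if tab["feature_id"].isna().any():
        missing = tab.loc[tab["feature_id"].isna(), "probe_id"].iloc[0]
        raise KeyError(f"probe {missing!r} has no feature assignment")

    def _agg(sub: pd.DataFrame) -> pd.Series:
        means = sub[mcols].mean(axis=1)
        discordant = (
            len(sub) > 1
            and means.max() > 1
            and means.min() < -1
        )
        row = sub[mcols + acols].mean(axis=0)
        row["discordant"] = bool(discordant)
        return row

    out = tab.groupby("feature_id", sort=True).apply(_agg, include_groups=False).reset_index()
    return out


def concordance_classify(
    de_calls: Iterable[DECall], features: Iterable[FeatureAnnotation]
) -> dict[str, str]:
    """Classify genes by intron/exon concordance of up-calls.

    ``pre_mrna_accumulation``: an intron of the gene is up but no exon feature
    is — the signature of inefficient splicing (unspliced pre-mRNA carries the
    intron, mature mRNA level unchanged).  ``transcript_increase``: intron and
    exon both up — the whole transcript is more abundant.  ``exon_only``: only
    exonic signal up.  ``none`` otherwise.
    """
    feat_by_id = {f.feature_id: f for f in features}
    intron_up: set[str] = set()
    exon_up: set[str] = set()
    for call in de_calls:
        if call.direction != "up":
            continue
        f = feat_by_id.get(call.feature_id)
        if f is None:
            continue
        if f.feature_class == "intron":
            intron_up.add(f.gene_id)
        elif f.feature_class == "exon":
            exon_up.add(f.gene_id)
    out = {}
    for gene in {f.gene_id for f in feat_by_id.values()}:
        if gene in intron_up and gene in exon_up:
            out[gene] = "transcript_increase"
        elif gene in intron_up:
            out[gene] = "pre_mrna_accumulation"
        elif gene in exon_up:
            out[gene] = "exon_only"
        else:
            out[gene] = "none"
    return out


def screen_summary(
    calls_by_strain: Mapping[str, Iterable[DECall]],
    total_coding: int,
    features: Iterable[FeatureAnnotation] | None = None,
) -> dict:
    """Screen-level union of differentially expressed coding genes.

    Genes are partitioned by whether, across all strains, they were only ever
    called up, only ever down, or both.  ``up_only + down_only + both =
    union_size`` by construction.  When ``features`` is given, calls are
    translated feature -> parent gene and restricted to exon features;
    otherwise call ids are taken to be coding gene ids already.
    """
    to_gene = None
    if features is not None:
        to_gene = {f.feature_id: f.gene_id for f in features if f.feature_class == "exon"}
    up: set[str] = set()
    down: set[str] = set()
    for calls in calls_by_strain.values():
        for c in calls:
            gene = to_gene.get(c.feature_id) if to_gene is not None else c.feature_id
            if gene is None:
                continue
            (up if c.direction == "up" else down).add(gene)
    union = up | down
    both = up & down
    return {
        "union_size": len(union),
        "pct_of_coding": round(100.0 * len(union) / total_coding, 1) if total_coding else 0.0,
        "up_only": len(up - down),
        "down_only": len(down - up),
        "both": len(both),
        "union": union,
    }
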