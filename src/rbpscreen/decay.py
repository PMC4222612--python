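"""First-order mRNA decay from steady-state 4sU labelling.

Cells incorporate 4-thiouridine into newly synthesised RNA for a short pulse
of t minutes (7 or 10 in practice).  Under steady state, a transcript decaying
with first-order rate k has labelled fraction

    f(t) = 1 - exp(-k t) = 1 - 2^(-t / T)

with half-life T = ln2 / k, so T can be read off a single time point:

    T = -t * ln2 / ln(1 - f)

Arrays measure the labelled/total comparison as a centred log-ratio rather
than a fraction; :func:`calibrate_ratios` maps ratios to fractions by scaling
so that the genome-median fraction matches an anchor value.  Half-lives are
computed per replicate and median-combined (robust to the occasional clipped
fraction), then summarized by feature class and compared between strains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import sam_one_class

__all__ = [
    "HalfLifeEstimate",
    "estimate_half_life",
    "calibrate_ratios",
    "estimate_table",
    "class_medians",
    "stability_change",
    "EPSILON",
]

EPSILON = 1e-4  # clipping bound for calibrated fractions


@dataclass(frozen=True)
class HalfLifeEstimate:
    feature_id: str
    feature_class: str
    k: float  # per-minute decay rate
    half_life: float  # minutes
    n_replicates: int
    cv: float  # replicate CV of the half-life


def estimate_half_life(f: float, t: float) -> float:
    """Half-life (minutes) from labelled fraction ``f`` after a ``t``-minute pulse.

    ``f <= 0`` means no detectable labelling within the pulse; the transcript
    is effectively infinitely stable at this resolution, so ``inf`` is
    returned with a warning.  ``f >= 1`` (complete turnover in finite time
    with exact measurement) is not a valid fraction.
    """
    if t <= 0:
        raise ValueError(f"labelling time must be positive, got {t}")
    if f >= 1:
        raise ValueError(f"labelled fraction must be < 1, got {f}")
    if f <= 0:
        warnings.warn("labelled fraction <= 0: half-life unresolvable (returning inf)", stacklevel=2)
        return math.inf
    return -t * math.log(2.0) / math.log1p(-f)


def calibrate_ratios(table: pd.DataFrame, anchor: float = 0.2) -> pd.DataFrame:
    """Convert median-centred log2 ratios to labelled fractions.

    fractions = clip(c * 2^r, EPSILON, 1 - EPSILON) with the constant c chosen
    so the genome-median fraction equals ``anchor``.  Rows at the clipping
    boundary are flagged ``censored`` rather than dropped.

    Expects a ``value`` column in ratio mode (``mode == "ratio"``); returns the
    table in fraction mode.
    """
    if not 0 < anchor < 1:
        raise ValueError(f"anchor must be in (0, 1), got {anchor}")
    if "mode" in table.columns and not (table["mode"] == "ratio").all():
        raise ValueError("calibrate_ratios expects a table uniformly in ratio mode")
    r = table["value"].to_numpy(float)
    # median(c * 2^r) = anchor  =>  c = anchor / 2^median(r)
    c = anchor / 2.0 ** np.median(r)
    f = np.clip(c * 2.0**r, EPSILON, 1 - EPSILON)
    out = table.copy()
    out["value"] = f
    out["censored"] = (f <= EPSILON) | (f >= 1 - EPSILON)
    if "mode" in out.columns:
        out["mode"] = "fraction"
    return out


def estimate_table(table: pd.DataFrame) -> list[HalfLifeEstimate]:
    """Per-feature half-life estimates from a long decay table.

    Columns: feature_id, feature_class, value (labelled fraction), time_min,
    replicate.  The half-life is computed per replicate (each with its own
    labelling time — 7 or 10 min samples mix freely) and replicates are
    combined by the median.
    """
    if "mode" in table.columns and not (table["mode"] == "fraction").all():
        raise ValueError("estimate_table expects fractions; run calibrate_ratios first")
    out = []
    for (fid, fclass), sub in table.groupby(["feature_id", "feature_class"], sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = [estimate_half_life(v, t) for v, t in zip(sub["value"], sub["time_min"])]
        ts = np.asarray(ts, dtype=float)
        finite = ts[np.isfinite(ts)]
        if finite.size == 0:
            continue
        hl = float(np.median(finite))
        cv = float(finite.std(ddof=1) / finite.mean()) if finite.size > 1 else float("nan")
        out.append(
            HalfLifeEstimate(
                feature_id=str(fid), feature_class=str(fclass),
                k=math.log(2.0) / hl, half_life=hl,
                n_replicates=int(finite.size), cv=cv,
            )
        )
    return out


def class_medians(estimates: list[HalfLifeEstimate]) -> dict[str, dict[str, float]]:
    """Median half-life per feature class, with per-class n.

    Classes absent from the input are absent from the output (never reported
    as zero).
    """
    df = pd.DataFrame([(e.feature_class, e.half_life) for e in estimates],
                      columns=["feature_class", "half_life"])
    out = {}
    for fclass, sub in df.groupby("feature_class"):
        out[str(fclass)] = {"median_minutes": float(sub["half_life"].median()), "n": int(len(sub))}
    return out


def stability_change(
    mutant: pd.DataFrame,
    wildtype: pd.DataFrame,
    method: str = "sam",
    target_fdr: float = 0.05,
    log2_threshold: float = math.log2(1.5),
    seed: int | None = None,
) -> dict[str, str]:
    """Call per-feature stability changes between mutant and wild type.

    Both inputs are long decay tables in fraction mode with matching
    ``replicate`` labels.  Per feature and replicate the log2 half-life ratio
    log2(T_mut / T_wt) is formed; ``method="sam"`` feeds these differences to
    :func:`rbpscreen.expression.sam_one_class` at ``target_fdr``, while
    ``method="threshold"`` calls features whose mean |log2 ratio| exceeds
    ``log2_threshold``.  Features missing from either table are skipped with
    a warning.  Returns feature_id -> {stabilized, destabilized, unchanged}.
    """

    def _per_rep_hl(tab: pd.DataFrame) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hl = [estimate_half_life(v, t) for v, t in zip(tab["value"], tab["time_min"])]
        return pd.DataFrame(
            {"feature_id": tab["feature_id"].to_numpy(), "replicate": tab["replicate"].to_numpy(),
             "half_life": hl}
        )

    mut = _per_rep_hl(mutant).pivot(index="feature_id", columns="replicate", values="half_life")
    wt = _per_rep_hl(wildtype).pivot(index="feature_id", columns="replicate", values="half_life")
    common = mut.index.intersection(wt.index)
    skipped = set(mut.index.symmetric_difference(wt.index))
    if skipped:
        warnings.warn(f"{len(skipped)} features present in only one table were skipped", stacklevel=2)
    ratios = np.log2(mut.loc[common] / wt.loc[common])
    ratios = ratios.replace([np.inf, -np.inf], np.nan).dropna()
    common = ratios.index

    if method == "threshold":
        mean_lr = ratios.mean(axis=1)
        out = {}
        for fid, v in mean_lr.items():
            if v >= log2_threshold:
                out[fid] = "stabilized"
            elif v <= -log2_threshold:
                out[fid] = "destabilized"
            else:
                out[fid] = "unchanged"
        return out
    if method != "sam":
        raise ValueError(f"unknown method {method!r}")

    tab = pd.DataFrame({"feature_id": common.astype(str)})
    for j, col in enumerate(ratios.columns, start=1):
        tab[f"M{j}"] = ratios[col].to_numpy(float)
    res = sam_one_class(tab, target_fdr=target_fdr, seed=seed)
    out = {fid: "unchanged" for fid in common.astype(str)}
    for call in res.calls:
        out[call.feature_id] = "stabilized" if call.direction == "up" else "destabilized"
    return out
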