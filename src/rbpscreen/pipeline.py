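"""End-to-end convenience runs of the screen on synthetic data.

These functions wire the generators to the callers exactly the way the
examples do — generate a full deletion-screen's worth of expression tables,
call differential expression per strain, and summarize — so that the screen-
level numbers (union of affected genes, affected-strain count, per-class
recoveries) can be recomputed from scratch with one call.
"""

from __future__ import annotations

import numpy as np

from . import expression, simulate, splicing

__all__ = ["run_expression_screen", "run_ncrna_strain", "run_splicing_strain"]


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def run_expression_screen(
    seed: int,
    n_genes: int = simulate.N_CODING,
    noise_sd: float = 0.2,
    target_fdr: float = 0.05,
    **truth_kwargs,
) -> dict:
    """Generate and analyse a whole deletion screen; return the summary.

    Every strain in the truth (affected and null) gets its own expression
    table and SAM run; the screen summary is computed from the calls, never
    from the truth.  Returns the :func:`expression.screen_summary` dict plus
    ``n_affected_strains`` (strains with at least one call) and the truth
    specs for downstream comparisons.
    """
    rng = np.random.default_rng(seed)
    specs = simulate.gen_screen_truth(seed=_derive_seed(rng), **truth_kwargs)
    calls_by_strain: dict[str, list[expression.DECall]] = {}
    for spec in specs:
        s = _derive_seed(rng)
        table, _ = simulate.gen_expression(spec, n_genes=n_genes, noise_sd=noise_sd, seed=s)
        res = expression.sam_one_class(table, target_fdr=target_fdr, seed=s)
        calls_by_strain[spec.strain_id] = res.calls
    summary = expression.screen_summary(calls_by_strain, total_coding=n_genes)
    summary["n_affected_strains"] = sum(1 for c in calls_by_strain.values() if c)
    summary["calls_by_strain"] = calls_by_strain
    summary["truth"] = specs
    return summary


def run_ncrna_strain(
    seed: int,
    n_ncrna: int = simulate.N_NCRNA,
    n_up: int = 35,
    noise_sd: float = 0.2,
    target_fdr: float = 0.05,
) -> dict:
    """One strain overexpressing a set of ncRNAs; SAM recovery of the set.

    Returns the recovered up-call set, the truth set, and the measured
    universe (for overlap tests on the ncRNA universe).
    """
    rng = np.random.default_rng(seed)
    ids = simulate.gene_ids(n_ncrna, prefix="ncrna")
    chosen = frozenset(rng.choice(ids, size=n_up, replace=False))
    spec = simulate.RegulonSpec("ncrna_strain", chosen, direction="up")
    s = _derive_seed(rng)
    table, truth = simulate.gen_expression(
        spec, n_genes=n_ncrna, noise_sd=noise_sd, seed=s, prefix="ncrna", feature_class="ncRNA"
    )
    res = expression.sam_one_class(table, target_fdr=target_fdr, seed=s)
    up = {c.feature_id for c in res.calls if c.direction == "up"}
    return {"up_calls": up, "truth_up": set(truth.loc[truth.is_target, "feature_id"]),
            "universe": set(ids)}


def run_splicing_strain(
    seed: int,
    n_introns: int = simulate.N_INTRONS,
    n_defective: int = 268,
    fold: float = 4.0,
    nb_dispersion: float = 0.1,
) -> dict:
    """One splicing-mutant strain; classifier recovery of the affected introns."""
    rng = np.random.default_rng(seed)
    ids = [f"intron_{i:05d}" for i in range(n_introns)]
    affected = list(rng.choice(ids, size=n_defective, replace=False))
    regimes = {i: simulate.SplicingRegime("splicing_defect", fold, nb_dispersion) for i in affected}
    counts, truth = simulate.gen_splicing_counts(n_introns, regimes, seed=_derive_seed(rng))
    classified = splicing.classify_table(counts)
    verdict = splicing.strain_call(classified)
    called = set(classified.loc[classified["call"] == "splicing_defect", "intron_id"])
    return {
        "classified": classified,
        "verdict": verdict,
        "splicing_defect_calls": called,
        "truth_affected": set(affected),
        "universe": set(ids),
    }
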