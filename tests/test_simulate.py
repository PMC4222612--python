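import numpy as np
import pandas as pd
import pytest

from rbpscreen import simulate, validation
from rbpscreen.simulate import DecaySpec, RegulonSpec, SplicingRegime


def test_generators_require_a_seed():
    spec = RegulonSpec("s", frozenset())
    with pytest.raises(ValueError, match="seed"):
        simulate.gen_expression(spec)
    with pytest.raises(ValueError, match="seed"):
        simulate.gen_decay(DecaySpec())
    with pytest.raises(ValueError, match="seed"):
        simulate.gen_ripchip()
    with pytest.raises(ValueError, match="seed"):
        simulate.gen_splicing_counts()
    with pytest.raises(ValueError, match="seed"):
        simulate.gen_utr_sequences()


@pytest.mark.parametrize("seed", [0, 17])
def test_generators_are_pure_functions_of_seed(seed):
    spec = RegulonSpec("s", frozenset(simulate.gene_ids(100)[:10]))
    a1, t1 = simulate.gen_expression(spec, n_genes=100, seed=seed)
    a2, t2 = simulate.gen_expression(spec, n_genes=100, seed=seed)
    pd.testing.assert_frame_equal(a1, a2)
    pd.testing.assert_frame_equal(t1, t2)
    d1, _ = simulate.gen_decay(DecaySpec(), n_per_class=20, seed=seed)
    d2, _ = simulate.gen_decay(DecaySpec(), n_per_class=20, seed=seed)
    pd.testing.assert_frame_equal(d1, d2)
    r1, _ = simulate.gen_ripchip(100, seed=seed)
    r2, _ = simulate.gen_ripchip(100, seed=seed)
    pd.testing.assert_frame_equal(r1, r2)


class TestGenExpression:
    def test_zero_targets_is_null(self):
        spec = RegulonSpec("s", frozenset())
        table, truth = simulate.gen_expression(spec, n_genes=200, seed=0)
        assert not truth["is_target"].any()
        assert abs(table["M1"].mean()) < 0.05

    def test_target_shift_recovered(self):
        ids = simulate.gene_ids(2000)
        spec = RegulonSpec("s", frozenset(ids[:50]), direction="up",
                           log2_effect_mean=2.0, log2_effect_sd=0.2)
        table, truth = simulate.gen_expression(spec, n_genes=2000, noise_sd=0.2, seed=42)
        mcols = [c for c in table.columns if c.startswith("M")]
        target_mean = table.loc[truth["is_target"], mcols].to_numpy().mean()
        assert target_mean == pytest.approx(2.0, abs=0.1)

    def test_no_dye_bias_gives_flat_ma_trend(self):
        spec = RegulonSpec("s", frozenset())
        table, _ = simulate.gen_expression(spec, n_genes=2000, seed=3)
        deciles = pd.qcut(table["A1"], 10, labels=False)
        assert table.groupby(deciles)["M1"].median().abs().max() < 0.05

    def test_regulon_size_range_enforced(self):
        with pytest.raises(ValueError, match="4–104"):
            RegulonSpec("s", frozenset(simulate.gene_ids(3)))

    def test_more_targets_than_genes_rejected(self):
        spec = RegulonSpec("s", frozenset(simulate.gene_ids(50)))
        with pytest.raises(ValueError):
            simulate.gen_expression(spec, n_genes=20, seed=0)


class TestGenDecay:
    def test_fraction_matches_half_life_with_no_noise(self):
        # T == t exactly means half the pool is labelled
        spec = DecaySpec(class_medians=(("exon", 7.0),), dispersion=0.0,
                         labelling_time=7.0, replicate_cv=0.0, n_replicates=1)
        table, truth = simulate.gen_decay(spec, n_per_class=5, seed=0)
        assert np.allclose(table["value"], 0.5)
        assert np.allclose(truth["true_half_life"], 7.0)

    def test_zero_cv_means_identical_replicates(self):
        spec = DecaySpec(replicate_cv=0.0)
        table, _ = simulate.gen_decay(spec, n_per_class=10, seed=1)
        wide = table.pivot(index="feature_id", columns="replicate", values="value")
        assert (wide.nunique(axis=1) == 1).all()

    def test_fractions_strictly_inside_unit_interval(self):
        table, _ = simulate.gen_decay(DecaySpec(), n_per_class=500, seed=2)
        assert (table["value"] > 0).all() and (table["value"] < 1).all()

    def test_class_median_half_lives_near_spec(self):
        table, truth = simulate.gen_decay(DecaySpec(), n_per_class=3000, seed=7)
        for fclass, median in DecaySpec().class_medians:
            sample = truth.loc[truth["feature_class"] == fclass, "true_half_life"].median()
            assert sample == pytest.approx(median, rel=0.05)


class TestGenRipchip:
    def test_zero_shift_target_ranks_uniform(self):
        ids = simulate.gene_ids(2000)
        targets = frozenset(ids[:50])
        rip, truth = simulate.gen_ripchip(2000, targets, target_shift=0.0, seed=5)
        sub = rip[rip["replicate"] == 1].sort_values("enrichment", ascending=False)
        ranks = np.nonzero(sub["gene_id"].isin(targets).to_numpy())[0]
        # mean rank of 50 uniform draws from 0..1999: sd ~ 82
        assert abs(ranks.mean() - 999.5) < 3.5 * 2000 / np.sqrt(12 * 50)

    def test_strong_shift_puts_targets_on_top(self):
        ids = simulate.gene_ids(2000)
        targets = frozenset(ids[:50])
        rip, _ = simulate.gen_ripchip(2000, targets, target_shift=5.0, seed=6)
        for _, sub in rip.groupby("replicate"):
            top60 = set(sub.nlargest(60, "enrichment")["gene_id"])
            assert len(top60 & targets) >= 48

    def test_empty_target_set_is_pure_null(self):
        rip, truth = simulate.gen_ripchip(500, frozenset(), target_shift=5.0, seed=7)
        assert not truth["is_target"].any()
        assert abs(rip["enrichment"].mean()) < 0.1


class TestGenSplicingCounts:
    def test_normal_regime_ratios_near_one(self):
        counts, _ = simulate.gen_splicing_counts(400, seed=8)
        agg = counts.groupby(["intron_id", "condition"])[["intron_reads", "eij_reads"]].sum()
        wt = agg.xs("wt", level="condition")
        mut = agg.xs("mutant", level="condition")
        assert np.median(mut["intron_reads"] / wt["intron_reads"]) == pytest.approx(1.0, abs=0.1)

    def test_regime_fold_changes_reach_read_types(self):
        regimes = {
            "intron_00000": SplicingRegime("splicing_defect", 4.0, 0.1),
            "intron_00001": SplicingRegime("intron_turnover", 4.0, 0.1),
        }
        # average over many seeds to beat NB noise on single introns
        r_sd, r_to = [], []
        for seed in range(20):
            counts, _ = simulate.gen_splicing_counts(50, regimes, seed=seed)
            agg = counts.groupby(["intron_id", "condition"])[["intron_reads", "eij_reads"]].sum()
            for intron, acc in (("intron_00000", r_sd), ("intron_00001", r_to)):
                mut = agg.loc[(intron, "mutant")]
                wt = agg.loc[(intron, "wt")]
                acc.append((mut["intron_reads"] / wt["intron_reads"],
                            mut["eij_reads"] / max(wt["eij_reads"], 1)))
        sd_int, sd_eij = np.mean([x for x, _ in r_sd]), np.mean([y for _, y in r_sd])
        to_int, to_eij = np.mean([x for x, _ in r_to]), np.mean([y for _, y in r_to])
        assert sd_int == pytest.approx(4.0, rel=0.35)
        assert sd_eij == pytest.approx(4.0, rel=0.35)
        assert to_int == pytest.approx(4.0, rel=0.35)
        assert to_eij == pytest.approx(1.0, abs=0.5)

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            SplicingRegime("splicing_defect", 0.5)
        with pytest.raises(ValueError, match="regime"):
            SplicingRegime("exotic", 2.0)


class TestGenUtrSequences:
    def test_embedded_motif_present(self):
        motif = "UUAAAC"
        targets, background, truth = simulate.gen_utr_sequences(
            n_target=30, n_background=30, motif=motif, embed_rate=1.0, length=200, seed=9
        )
        spec = validation.MotifSpec(motif)
        assert all(validation.count_motif(seq, spec) >= 1 for seq in targets.values())
        assert truth["embedded"].all()

    def test_zero_embed_rate_matches_background(self):
        targets, background, truth = simulate.gen_utr_sequences(
            n_target=200, n_background=200, motif="UUAAAC", embed_rate=0.0, length=200, seed=10
        )
        spec = validation.MotifSpec("UUAAAC")
        t_rate = np.mean([validation.count_motif(s, spec) > 0 for s in targets.values()])
        b_rate = np.mean([validation.count_motif(s, spec) > 0 for s in background.values()])
        assert not truth["embedded"].any()
        assert abs(t_rate - b_rate) < 0.1

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            simulate.gen_utr_sequences(motif="UUAAAC", length=4, seed=0)

    def test_fasta_round_trip_uses_rna_alphabet(self, tmp_path):
        targets, _, _ = simulate.gen_utr_sequences(n_target=5, n_background=1, length=50, seed=11)
        path = tmp_path / "targets.fa"
        simulate.write_fasta(targets, path)
        back = simulate.read_fasta(path)
        assert back == targets
        assert "T" not in "".join(back.values())


class TestScreenTruth:
    def test_partition_and_sizes(self):
        specs = simulate.gen_screen_truth(seed=1)
        affected = [s for s in specs if s.target_gene_ids]
        assert len(specs) == 74
        assert len(affected) == 25
        up = set().union(*(s.target_gene_ids for s in affected if s.direction == "up"))
        down = set().union(*(s.target_gene_ids for s in affected if s.direction == "down"))
        assert len(up | down) == 816
        assert len(up & down) == 46
        assert len(up - down) == 483
        assert len(down - up) == 287
        for s in affected:
            assert 4 <= len(s.target_gene_ids) <= 104
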