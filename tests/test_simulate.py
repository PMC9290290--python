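import numpy as np
import pandas as pd
import pytest

import triadseq as tq


class TestDeterminism:
    def test_triad_byte_identical_for_same_seed(self):
        cfg = tq.SimConfig(n_genes=150, seed=42)
        a = tq.simulate_triad(cfg)
        b = tq.simulate_triad(cfg)
        assert (a[0].counts == b[0].counts).all().all()
        assert (a[2] == b[2]).all().all()

    def test_different_seeds_differ(self):
        a = tq.simulate_triad(tq.SimConfig(n_genes=150, seed=1))
        b = tq.simulate_triad(tq.SimConfig(n_genes=150, seed=2))
        assert not (a[0].counts == b[0].counts).all().all()

    def test_ase_deterministic(self):
        cfg = tq.SimConfig(n_genes_ase=50, seed=5)
        a, ta = tq.simulate_ase(cfg)
        b, tb = tq.simulate_ase(cfg)
        assert (a == b).all().all() and (ta == tb).all().all()


class TestConfigValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.SimConfig(class_fractions={"additive": 0.9, "over_dominant": 0.2})

    def test_unknown_class_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.SimConfig(class_fractions={"sideways_dominant": 0.1})

    def test_invalid_allelic_fraction_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.SimConfig(allelic_fractions=(0.0, 0.8))
        with pytest.raises(tq.ValidationError):
            tq.SimConfig(allelic_fractions=(1.2,))

    def test_fold_change_must_exceed_one(self):
        with pytest.raises(tq.ValidationError):
            tq.SimConfig(fold_change=1.0)


class TestTriadSemantics:
    def test_class_counts_match_fractions(self):
        cfg = tq.SimConfig(n_genes=1000, seed=0)
        _, _, truth = tq.simulate_triad(cfg)
        counts = truth["class"].value_counts()
        assert counts["additive"] == 500
        for cls in ("over_dominant", "under_dominant", "conserved"):
            assert counts[cls] == 100

    def test_counts_match_relative_means_within_3se(self):
        cfg = tq.SimConfig(n_genes=400, dispersion=0.0, seed=8)
        cm, design, truth = tq.simulate_triad(cfg)
        pooled, lib = tq.pooled_counts(cm, design, "P1")
        expected = truth["mean_p1"] / truth["mean_p1"].sum() * lib
        z = (pooled - expected) / np.sqrt(expected)
        assert (np.abs(z) <= 3).mean() > 0.99

    def test_additive_truth_sits_at_relative_midparent(self):
        cfg = tq.SimConfig(n_genes=300, seed=3)
        _, _, truth = tq.simulate_triad(cfg)
        add = truth[truth["class"] == "additive"]
        assert np.allclose(add["mean_f1"], (add["mean_p1"] + add["mean_p2"]) / 2)

    def test_dominant_truth_matches_parent(self):
        cfg = tq.SimConfig(n_genes=300, seed=3)
        _, _, truth = tq.simulate_triad(cfg)
        p1d = truth[truth["class"] == "parent1_dominant"]
        assert np.allclose(p1d["mean_f1"], p1d["mean_p1"])
        odo = truth[truth["class"] == "over_dominant"]
        assert (
            odo["mean_f1"] >= np.maximum(odo["mean_p1"], odo["mean_p2"]) * 1.99
        ).all()

    def test_noiseless_limit_ratios_converge(self):
        # dispersion 0 at high depth: pooled ratios approach configured folds
        cfg = tq.SimConfig(
            n_genes=200, depth=2_000_000, dispersion=0.0, seed=4,
            class_fractions={"over_dominant": 1.0}, fold_change=2.0,
        )
        cm, design, truth = tq.simulate_triad(cfg)
        f1, libf = tq.pooled_counts(cm, design, "F1")
        p1, libp = tq.pooled_counts(cm, design, "P1")
        big = truth["mean_p1"] > truth["mean_p1"].median()
        ratio = (f1[big] / libf) / (p1[big] / libp)
        # a uniform renormalisation factor applies; the *relative* spread is tiny
        assert ratio.std() / ratio.mean() < 0.05


class TestAseSimulator:
    def test_extreme_fraction_gives_pure_snps(self):
        cfg = tq.SimConfig(
            n_genes_ase=20, ase_fraction=1.0, allelic_fractions=(0.999999,),
            reads_per_snp=50, seed=0,
        )
        snps, truth = tq.simulate_ase(cfg)
        assert (snps["reads_allele1"] == 50).all()

    def test_gene_universe_can_be_supplied(self):
        cfg = tq.SimConfig(n_genes_ase=10, seed=0)
        snps, truth = tq.simulate_ase(cfg, gene_ids=["a", "b", "c"])
        assert set(snps["gene_id"]) == {"a", "b", "c"}
        assert list(truth.index) == ["a", "b", "c"]

    def test_null_fraction_half_everywhere(self):
        cfg = tq.SimConfig(n_genes_ase=50, ase_fraction=0.0, seed=1)
        _, truth = tq.simulate_ase(cfg)
        assert (truth["allelic_fraction"] == 0.5).all()
        assert not truth["is_ase"].any()


class TestEvaluateRecovery:
    def test_perfect_calls(self):
        truth = pd.Series(["additive", "conserved"], index=["g1", "g2"])
        rep = tq.evaluate_recovery(truth.copy(), truth)
        assert rep.accuracy == 1.0
        assert (rep.per_class["precision"].dropna() == 1.0).all()

    def test_all_ambiguous_zero_recall(self):
        truth = pd.Series(["additive", "conserved"], index=["g1", "g2"])
        calls = pd.Series(["ambiguous", "ambiguous"], index=["g1", "g2"])
        rep = tq.evaluate_recovery(calls, truth)
        assert rep.accuracy == 0.0 and rep.n_ambiguous == 2
        assert (rep.per_class["recall"].dropna() == 0.0).all()

    def test_universe_mismatch_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.evaluate_recovery(
                pd.Series(["additive"], index=["g1"]),
                pd.Series(["additive"], index=["g2"]),
            )

    def test_random_calls_near_chance_level(self):
        rng = np.random.default_rng(0)
        classes = [
            "additive", "over_dominant", "under_dominant",
            "parent1_dominant", "parent2_dominant", "conserved",
        ]
        idx = [f"g{i}" for i in range(3000)]
        truth = pd.Series(rng.choice(classes, 3000), index=idx)
        calls = pd.Series(rng.choice(classes, 3000), index=idx)
        assert tq.evaluate_recovery(calls, truth).accuracy == pytest.approx(
            1 / 6, abs=0.03
        )


class TestStudySimulator:
    def test_layout_and_roles(self):
        cfg = tq.SimConfig(n_genes=120, n_genes_ase=40, seed=2)
        study = tq.simulate_study(cfg)
        assert study["counts"].counts.shape == (120, 15)
        assert len(study["design"].genotypes) == 5
        assert set(study["snps"]) == {"hyb1", "hyb2"}
        # ASE gene ids drawn from the count-matrix universe
        assert set(study["snps"]["hyb1"]["gene_id"]) <= set(
            study["counts"].gene_ids
        )

    def test_line_difference_flags(self):
        cfg = tq.SimConfig(n_genes=200, seed=2)
        study = tq.simulate_study(cfg, line_diff_fraction=0.1)
        truth = study["truth"]
        assert truth["line_diff"].sum() == 20
        # unchanged genes keep the lineA profile up to one uniform factor
        same = truth[~truth["line_diff"]]
        ratio = same["mean_line1"] / same["mean_line2"]
        assert np.allclose(ratio, ratio.iloc[0])
        changed = truth[truth["line_diff"]]
        changed_ratio = changed["mean_line1"] / changed["mean_line2"]
        assert not np.any(np.isclose(changed_ratio, ratio.iloc[0]))
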