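import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import triadseq as tq
from triadseq.expression import genotype_mean_fpkm


def _matrix(counts, lengths, libs=None):
    idx = pd.Index([f"g{i}" for i in range(len(lengths))], name="gene_id")
    df = pd.DataFrame(counts, index=idx)
    return tq.CountMatrix(
        df, pd.Series(lengths, index=idx),
        None if libs is None else pd.Series(libs, index=df.columns),
    )


class TestComputeFpkm:
    def test_direct_formula(self):
        cm = _matrix({"s1": [100, 0]}, [1000, 500], libs=[1_000_000])
        fpkm = tq.compute_fpkm(cm)
        assert fpkm.values.loc["g0", "s1"] == pytest.approx(100.0)
        assert fpkm.values.loc["g1", "s1"] == 0.0

    def test_doubling_library_halves_column(self):
        cm1 = _matrix({"s1": [30, 70]}, [500, 900], libs=[10_000])
        cm2 = _matrix({"s1": [30, 70]}, [500, 900], libs=[20_000])
        assert np.allclose(
            tq.compute_fpkm(cm1).values, 2 * tq.compute_fpkm(cm2).values
        )

    def test_zero_iff_zero_count(self):
        cm = _matrix({"s1": [0, 5], "s2": [3, 0]}, [100, 100])
        fpkm = tq.compute_fpkm(cm)
        assert (fpkm.values.to_numpy() == 0) == pytest.approx(
            cm.counts.to_numpy() == 0
        )

    def test_round_trip_recovers_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5000, size=(50, 4))
        cm = _matrix(
            {f"s{i}": counts[:, i] for i in range(4)},
            rng.integers(200, 3000, size=50),
        )
        back = tq.invert_fpkm(tq.compute_fpkm(cm), cm.library_sizes)
        assert (back.to_numpy() == cm.counts.to_numpy()).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(tq.ValidationError):
            _matrix({"s1": [1]}, [0])
        with pytest.raises(tq.ValidationError):
            _matrix({"s1": [1]}, [100], libs=[0])
        with pytest.raises(tq.ValidationError):
            _matrix({"s1": [-1]}, [100])
        with pytest.raises(tq.ValidationError):
            _matrix({"s1": [1.5]}, [100])


class TestExpressedGenes:
    def _fixture(self):
        # replicate FPKMs per gene for genotype A: rows scaled via counts
        counts = pd.DataFrame(
            {
                "A_r1": [15, 3, 0, 30],
                "A_r2": [15, 3, 0, 0],
                "A_r3": [15, 3, 0, 0],
            },
            index=pd.Index(["hi", "lo", "zero", "burst"], name="gene_id"),
        )
        cm = tq.CountMatrix(
            counts,
            pd.Series([1000] * 4, index=counts.index),
            pd.Series([10_000_000] * 3, index=counts.columns),
        )
        design = tq.SampleDesign(
            pd.DataFrame(
                {"genotype": ["A"] * 3, "role": ["other"] * 3, "replicate": [1, 2, 3]},
                index=counts.columns,
            )
        )
        return tq.compute_fpkm(cm), design

    def test_mean_rule(self):
        fpkm, design = self._fixture()
        # hi: 1.5 FPKM each rep -> in; lo: 0.3 each -> out; zero -> out
        got = tq.expressed_genes(fpkm, design, "A")
        assert got == {"hi", "burst"}  # burst mean = 1.0 >= 1

    def test_any_rule_flag(self):
        fpkm, design = self._fixture()
        got = tq.expressed_genes(fpkm, design, "A", how="any")
        assert "burst" in got and "lo" not in got

    def test_unknown_genotype_named_in_error(self):
        fpkm, design = self._fixture()
        with pytest.raises(tq.ValidationError, match="Zheng58"):
            tq.expressed_genes(fpkm, design, "Zheng58")

    def test_mean_fpkm_helper(self):
        fpkm, design = self._fixture()
        assert genotype_mean_fpkm(fpkm, design, "A")["hi"] == pytest.approx(1.5)


class TestExpressionBins:
    def test_boundaries_left_closed(self):
        bins = tq.expression_bins([50.0, 20.0, 1.0])
        assert (bins.high, bins.medium, bins.low) == (1, 1, 1)

    def test_reported_low_share(self):
        values = np.concatenate(
            [np.full(2143, 60.0), np.full(4009, 30.0), np.full(14783, 5.0)]
        )
        bins = tq.expression_bins(values)
        assert (bins.high, bins.medium, bins.low) == (2143, 4009, 14783)
        assert bins.low_pct == 70.61

    def test_empty_input_flagged(self):
        bins = tq.expression_bins([])
        assert bins.total == 0 and bins.low_pct is None

    def test_below_threshold_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.expression_bins([0.5, 30.0])

    @given(st.lists(st.floats(1.0, 200.0), min_size=1, max_size=200))
    def test_bins_partition_expressed_set(self, values):
        bins = tq.expression_bins(values)
        assert bins.total == len(values)


class TestDesignAndIO:
    def test_duplicate_genotype_replicate_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.SampleDesign(
                pd.DataFrame(
                    {
                        "genotype": ["A", "A"],
                        "role": ["other", "other"],
                        "replicate": [1, 1],
                    },
                    index=["s1", "s2"],
                )
            )

    def test_unknown_role_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.SampleDesign(
                pd.DataFrame(
                    {"genotype": ["A"], "role": ["clone"], "replicate": [1]},
                    index=["s1"],
                )
            )

    def test_counts_tsv_round_trip(self, tmp_path, small_counts):
        path = tmp_path / "counts.tsv"
        tq.write_counts(small_counts, path)
        back = tq.read_counts(path)
        assert (back.counts == small_counts.counts).all().all()
        assert (back.gene_lengths == small_counts.gene_lengths).all()

    def test_design_tsv_round_trip(self, tmp_path, small_design):
        path = tmp_path / "design.tsv"
        tq.write_design(small_design, path)
        back = tq.read_design(path)
        assert (back.table == small_design.table).all().all()

    def test_comment_lines_ignored(self, tmp_path, small_counts):
        path = tmp_path / "counts.tsv"
        tq.write_counts(small_counts, path)
        text = "# generated fixture\n" + path.read_text()
        path.write_text(text)
        assert tq.read_counts(path).counts.shape == small_counts.counts.shape


def test_effective_library_corrects_uniform_scale():
    idx = pd.Index([f"g{i}" for i in range(100)])
    base = pd.Series(np.arange(10, 110), index=idx)
    scaled = (base * 3).astype(int)
    lib_x, lib_y = int(scaled.sum()), int(base.sum())
    eff = tq.expression.effective_library(scaled, lib_y, base, lib_y)
    # scaled profile pretending to share lib_y: effective library ~ 3x
    assert eff == pytest.approx(3 * lib_y, rel=0.01)
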