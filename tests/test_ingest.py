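"""Tests for file ingest, preprocessing and replicate QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prostasig import (
    batch_adjust,
    filter_probes,
    log2_transform,
    quantile_normalize,
    read_expression,
    read_phenotype,
    replicate_qc,
)
from prostasig.ingest import ExpressionMatrix, write_expression, write_phenotype

from conftest import make_expression, make_phenotype


class TestReaders:
    def test_round_trip_shapes_and_annotations(self, tmp_path):
        m = make_expression(np.arange(12.0).reshape(3, 4), is_log2=False)
        path = tmp_path / "expr.tsv"
        write_expression(m, path)
        back = read_expression(path)
        assert back.shape == (3, 4)
        assert list(back.probe_ids) == list(m.probe_ids)
        np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy())

    def test_duplicate_sample_column_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("probe_id\tS1\tS1\nP1\t1.0\t2.0\n")
        with pytest.raises(ValueError, match="S1"):
            # pandas mangles duplicate headers; constructing directly hits the guard
            df = pd.read_csv(path, sep="\t", index_col=0)
            df.columns = ["S1", "S1"]
            ExpressionMatrix(values=df)

    def test_non_numeric_intensity_names_coordinates(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("probe_id\tS1\tS2\nP1\t1.0\tbogus\n")
        with pytest.raises(ValueError, match="P1.*S2"):
            read_expression(path)

    def test_phenotype_missing_stage_level_is_legal(self, tmp_path):
        p = make_phenotype(["a", "b", "c", "d"], ["nonrecurrent"] * 3 + ["metastatic_lethal"])
        p.table.loc[0, "stage"] = "missing"
        path = tmp_path / "phen.tsv"
        write_phenotype(p, path)
        back = read_phenotype(path)
        assert (back.table["stage"] == "missing").sum() == 1

    def test_unknown_category_rejected_with_location(self, tmp_path):
        p = make_phenotype(["a", "b"], ["nonrecurrent", "metastatic_lethal"])
        p.table.loc[1, "gleason"] = "gleason9"
        path = tmp_path / "phen.tsv"
        p.table.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="gleason9"):
            read_phenotype(path)


def oracle_quantile_normalize(X):
    """Independent rank-then-substitute oracle (tie-free input)."""
    Xs = np.sort(X, axis=0)
    ref = Xs.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="ordinal").astype(int) - 1
        out[:, j] = ref[ranks]
    return out


class TestQuantileNormalize:
    def test_two_by_two_closed_form(self):
        m = make_expression([[1.0, 3.0], [2.0, 4.0]], is_log2=False)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[2.0, 2.0], [3.0, 3.0]])

    def test_column_means_equalized(self):
        rng = np.random.default_rng(0)
        m = make_expression(rng.lognormal(2, 1, size=(50, 6)), is_log2=False)
        out = quantile_normalize(m).values.to_numpy()
        means = out.mean(axis=0)
        np.testing.assert_allclose(means, means[0])

    def test_matches_rank_substitute_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 2, size=(4, 3))
        m = make_expression(X, is_log2=False)
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, oracle_quantile_normalize(X), atol=1e-12)

    def test_ties_get_mean_of_reference_at_tied_ranks(self):
        m = make_expression([[1.0, 2.0], [1.0, 4.0], [3.0, 6.0]], is_log2=False)
        out = quantile_normalize(m).values.to_numpy()
        # reference = [1.5, 2.5, 4.5]; tied bottom pair averages 1.5 and 2.5
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 2.5, 4.5])

    def test_idempotent_on_continuous_data(self):
        rng = np.random.default_rng(2)
        m = make_expression(rng.normal(8, 1, size=(40, 5)), is_log2=False)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-9
        )

    def test_single_sample_unchanged(self):
        m = make_expression([[1.0], [5.0]], is_log2=False)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_log2_input_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(make_expression([[1.0, 2.0]], is_log2=True))


class TestLog2Transform:
    def test_values(self):
        m = make_expression([[8.0, 0.0]], is_log2=False)
        out = log2_transform(m, offset=1.0)
        np.testing.assert_allclose(out.values.to_numpy(), [[np.log2(9.0), 0.0]])
        assert out.is_log2

    def test_exact_power(self):
        m = make_expression([[8.0]], is_log2=False)
        assert log2_transform(m).values.iloc[0, 0] == 3.0

    def test_already_log2_rejected(self):
        with pytest.raises(ValueError, match="already"):
            log2_transform(make_expression([[1.0]], is_log2=True))

    def test_nonpositive_entry_named(self):
        m = make_expression([[1.0], [0.0]], probe_ids=["P0", "Pz"], is_log2=False)
        with pytest.raises(ValueError, match="Pz"):
            log2_transform(m, offset=0.0)


class TestFilterProbes:
    def test_full_keep_list_is_identity(self):
        m = make_expression(np.eye(3))
        out = filter_probes(m, list(m.probe_ids))
        assert list(out.probe_ids) == list(m.probe_ids)

    def test_subset_preserves_matrix_order_and_is_idempotent(self):
        m = make_expression(np.arange(20.0).reshape(5, 4))
        keep = ["P3", "P1"]  # keep-list order must not matter
        out = filter_probes(m, keep)
        assert list(out.probe_ids) == ["P1", "P3"]
        again = filter_probes(out, keep)
        assert list(again.probe_ids) == ["P1", "P3"]

    def test_unknown_ids_ignored(self):
        m = make_expression(np.eye(2))
        out = filter_probes(m, ["P0", "NOT_A_PROBE"])
        assert list(out.probe_ids) == ["P0"]

    def test_disjoint_keep_list_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            filter_probes(make_expression(np.eye(2)), ["X1"])

    def test_empty_keep_list_rejected(self):
        with pytest.raises(ValueError):
            filter_probes(make_expression(np.eye(2)), [])


class TestBatchAdjust:
    def _matched_batches(self, rng, n_probes=30, per_batch=10):
        # batch B duplicates batch A's values so batch statistics agree exactly
        block = rng.normal(9, 1, size=(n_probes, per_batch))
        X = np.concatenate([block, block], axis=1)
        batches = ["A"] * per_batch + ["B"] * per_batch
        return X, batches

    def test_identical_batches_identity(self):
        rng = np.random.default_rng(3)
        X, batches = self._matched_batches(rng)
        m = make_expression(X)
        out = batch_adjust(m, batches)
        np.testing.assert_allclose(out.values.to_numpy(), X, atol=1e-9)

    def test_pure_location_offset_removed_up_to_global_shift(self):
        # a location offset confined to one batch is indistinguishable from a
        # global shift of those samples; adjustment equalizes batch means and
        # leaves at most a constant offset per probe
        rng = np.random.default_rng(4)
        X, batches = self._matched_batches(rng)
        pert = X.copy()
        pert[:, 10:] += 0.5
        out = batch_adjust(make_expression(pert), batches).values.to_numpy()
        shift = out - X
        np.testing.assert_allclose(shift, 0.25, atol=1e-9)  # 0.5 * n_B / n
        batch_mean_gap = out[:, :10].mean(axis=1) - out[:, 10:].mean(axis=1)
        np.testing.assert_allclose(batch_mean_gap, 0.0, atol=1e-6)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(5)
        X = rng.normal(10, 1, size=(40, 24))
        X[:, ::3] += rng.normal(0, 0.4, size=(40, 1))
        batches = [f"B{j % 3}" for j in range(24)]
        for shrink in (False, True):
            out = batch_adjust(make_expression(X), batches, shrink=shrink)
            np.testing.assert_allclose(
                out.values.to_numpy().mean(axis=1), X.mean(axis=1), atol=1e-9
            )

    def test_planted_batch_effect_suppressed(self):
        # per-probe one-way F for batch after adjustment under the 95th null pct
        rng = np.random.default_rng(6)
        n_probes, per_batch, n_batches = 300, 20, 3
        offsets = rng.normal(0, 0.4, size=(n_probes, n_batches))
        X = rng.normal(9, 0.7, size=(n_probes, per_batch * n_batches))
        batches = [f"B{j // per_batch}" for j in range(X.shape[1])]
        for b in range(n_batches):
            X[:, b * per_batch : (b + 1) * per_batch] += offsets[:, [b]]
        out = batch_adjust(make_expression(X), batches).values.to_numpy()
        groups = [out[:, b * per_batch : (b + 1) * per_batch] for b in range(n_batches)]
        f_stat = stats.f_oneway(*groups, axis=1).statistic
        f95 = stats.f.ppf(0.95, n_batches - 1, X.shape[1] - n_batches)
        assert (f_stat < f95).mean() >= 0.90

    def test_thin_batch_rejected(self):
        m = make_expression(np.arange(12.0).reshape(3, 4))
        with pytest.raises(ValueError, match="B2"):
            batch_adjust(m, ["B1", "B1", "B1", "B2"])

    def test_raw_scale_rejected(self):
        m = make_expression(np.ones((2, 4)), is_log2=False)
        with pytest.raises(ValueError):
            batch_adjust(m, ["A", "A", "B", "B"])


class TestReplicateQc:
    def test_exact_duplicate_has_correlation_one(self):
        rng = np.random.default_rng(7)
        base = rng.normal(9, 1, size=(100, 1))
        X = np.concatenate([base, base, rng.normal(9, 1, size=(100, 2))], axis=1)
        m = make_expression(X, sample_ids=["s1", "s1rep", "s2", "s3"])
        p = make_phenotype(
            ["s1", "s1rep", "s2", "s3"],
            ["nonrecurrent"] * 3 + ["metastatic_lethal"],
            replicate_of=[None, "s1", None, None],
        )
        qc = replicate_qc(m, p)
        assert len(qc) == 1
        assert qc.loc[0, "correlation"] == pytest.approx(1.0)
        assert not qc.loc[0, "flagged"]

    def test_noisy_duplicate_stays_above_platform_range(self):
        # duplicate + N(0, 0.1) noise over 2000 probes: r above the 0.98
        # floor observed for blind array duplicates
        rng = np.random.default_rng(8)
        base = rng.uniform(7, 14, size=(2000, 1))
        dup = base + rng.normal(0, 0.1, size=(2000, 1))
        X = np.concatenate([base, dup], axis=1)
        m = make_expression(X, sample_ids=["s1", "s1rep"])
        p = make_phenotype(
            ["s1", "s1rep"],
            ["nonrecurrent", "metastatic_lethal"],
            replicate_of=[None, "s1"],
        )
        qc = replicate_qc(m, p)
        assert qc.loc[0, "correlation"] > 0.98

    def test_no_pairs_gives_empty_result(self):
        m = make_expression(np.ones((3, 2)))
        p = make_phenotype(["S0", "S1"], ["nonrecurrent", "metastatic_lethal"])
        assert len(replicate_qc(m, p)) == 0

    def test_absent_replicate_target_rejected(self):
        with pytest.raises(ValueError, match="S9"):
            make_phenotype(
                ["S0", "S1"],
                ["nonrecurrent", "metastatic_lethal"],
                replicate_of=[None, "S9"],
            )

    def test_replicate_sample_missing_from_matrix(self):
        m = make_expression(np.ones((3, 1)), sample_ids=["S0"])
        p = make_phenotype(
            ["S0", "S1"], ["nonrecurrent", "metastatic_lethal"], replicate_of=[None, "S0"]
        )
        with pytest.raises(ValueError, match="S1"):
            replicate_qc(m, p)
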