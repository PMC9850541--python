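import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scvuln.core_io import ExpressionMatrix, ValidationError
from scvuln.label_transfer import (
    UNASSIGNED,
    align_cc_scores,
    composition_summary,
    diagonal_cca,
    discriminability_scores,
    knn_assign,
    select_shared_features,
)

from .conftest import make_matrix


def hvg_table(genes, selected):
    return pd.DataFrame({"selected": selected}, index=genes)


class TestSelectSharedFeatures:
    def test_identical_tables(self):
        t = hvg_table(["A", "B", "C"], [True, True, False])
        fs = select_shared_features(t, t)
        assert fs.genes == ["A", "B"]

    def test_disjoint_selection_errors(self):
        a = hvg_table(["A", "B"], [True, False])
        b = hvg_table(["A", "B"], [False, True])
        with pytest.raises(ValidationError, match="empty"):
            select_shared_features(a, b)

    def test_case_insensitive_intersection(self):
        a = hvg_table(["Sst", "Gad1"], [True, True])
        b = hvg_table(["SST", "PVALB"], [True, True])
        fs = select_shared_features(a, b)
        assert fs.genes == ["Sst"]

    def test_ranking_and_top_n(self):
        t = hvg_table(["A", "B", "C"], [True, True, True])
        ranking = pd.Series({"A": 1.0, "B": 9.0, "C": 5.0})
        fs = select_shared_features(t, t, ranking=ranking, top_n=2)
        assert fs.genes == ["B", "C"]

    def test_markers_rank_above_noise_genes(self, rng):
        # planted marker separates two types; noise gene does not
        n = 40
        x = np.abs(rng.normal(1, 0.3, size=(2, 2 * n)))
        x[0, :n] += 2.0
        m = make_matrix(x)
        labels = ["T1"] * n + ["T2"] * n
        scores = discriminability_scores(m, labels, ["G0", "G1"])
        assert scores["G0"] > scores["G1"]


def _norm_matrix(rng, n_genes, n_cells, prefix):
    return ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        cell_ids=[f"{prefix}{j}" for j in range(n_cells)],
        norm=np.abs(rng.normal(1, 1, size=(n_genes, n_cells))),
    )


class TestDiagonalCCA:
    def test_duplicate_dataset_gives_unit_correlation(self, rng):
        a = _norm_matrix(rng, 50, 30, "A")
        b = ExpressionMatrix(a.gene_ids, [f"B{j}" for j in range(30)],
                             norm=a.norm.copy())
        cca = diagonal_cca(a, b, a.gene_ids, n_cc=3)
        assert cca.correlations[0] == pytest.approx(1.0, abs=1e-6)

    def test_scores_match_svd_oracle(self, rng):
        a = _norm_matrix(rng, 12, 10, "A")
        b = _norm_matrix(rng, 12, 8, "B")
        cca = diagonal_cca(a, b, a.gene_ids, n_cc=4)

        def stdz(x):
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            return (x - mu) / np.where(sd > 0, sd, 1.0)

        u, s, vt = np.linalg.svd(stdz(a.norm).T @ stdz(b.norm),
                                 full_matrices=False)
        for j in range(4):  # compare up to sign
            uj = u[:, j]
            if uj[np.argmax(np.abs(uj))] < 0:
                uj, vj = -uj, -vt[j]
            else:
                vj = vt[j]
            assert np.allclose(cca.scores_a[:, j], uj, atol=1e-8)
            assert np.allclose(cca.scores_b[:, j], vj, atol=1e-8)
        assert np.allclose(cca.singular_values, s[:4])

    def test_independent_data_has_modest_correlations(self):
        # needs genes >> cells for the SVD not to overfit the variates
        rng = np.random.default_rng(3)
        a = _norm_matrix(rng, 1000, 100, "A")
        b = _norm_matrix(rng, 1000, 100, "B")
        cca = diagonal_cca(a, b, a.gene_ids, n_cc=4)
        assert (cca.correlations < 0.6).all()

    def test_singular_values_non_increasing(self, rng):
        a = _norm_matrix(rng, 40, 20, "A")
        b = _norm_matrix(rng, 40, 25, "B")
        cca = diagonal_cca(a, b, a.gene_ids, n_cc=5)
        assert (np.diff(cca.singular_values) <= 1e-9).all()

    def test_n_cc_exceeding_cells_rejected(self, rng):
        a = _norm_matrix(rng, 30, 5, "A")
        b = _norm_matrix(rng, 30, 20, "B")
        with pytest.raises(ValueError, match="n_cc"):
            diagonal_cca(a, b, a.gene_ids, n_cc=10)


class TestAlignCCScores:
    def _cca(self, scores_a, scores_b):
        from scvuln.label_transfer import CCAScores

        return CCAScores(scores_a=np.asarray(scores_a, dtype=float),
                         scores_b=np.asarray(scores_b, dtype=float),
                         correlations=np.ones(np.asarray(scores_a).shape[1]),
                         n_cc=np.asarray(scores_a).shape[1])

    def test_identical_distributions_near_identity(self, rng):
        x = rng.normal(size=(100, 2))
        aligned = align_cc_scores(self._cca(x, x.copy()))
        assert np.allclose(aligned.scores_a, aligned.scores_b)
        assert np.corrcoef(aligned.scores_a[:, 0], x[:, 0])[0, 1] > 0.999

    def test_shift_removed(self, rng):
        a = rng.normal(size=(200, 1))
        b = rng.normal(size=(200, 1)) + 5.0
        aligned = align_cc_scores(self._cca(a, b))
        pooled_sd = np.concatenate([aligned.scores_a, aligned.scores_b]).std()
        gap = abs(aligned.scores_a.mean() - aligned.scores_b.mean())
        assert gap < 0.05 * pooled_sd

    def test_within_dataset_order_preserved(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(60, 3)) * 2 + 1
        aligned = align_cc_scores(self._cca(a, b))
        for j in range(3):
            assert np.array_equal(np.argsort(a[:, j], kind="stable"),
                                  np.argsort(aligned.scores_a[:, j], kind="stable"))


def brute_force_assign(vote_counts, min_votes=5):
    """Oracle over the vote multiset: unique plurality with enough votes."""
    top = max(vote_counts.values())
    winners = [k for k, v in vote_counts.items() if v == top]
    if len(winners) > 1:
        return UNASSIGNED, "tie"
    if top < min_votes:
        return UNASSIGNED, "below_min_votes"
    return winners[0], "ok"


def coords_for_votes(vote_counts):
    """Reference coordinates whose 30-NN of the origin realize the votes."""
    ref, labels = [], []
    i = 0
    for label, count in vote_counts.items():
        for _ in range(count):
            angle = 2 * np.pi * i / 30
            ref.append([np.cos(angle), np.sin(angle)])
            labels.append(label)
            i += 1
    # pad with distant filler cells of a unique label
    for j in range(10):
        ref.append([100.0 + j, 100.0])
        labels.append("FILLER")
    return np.array(ref), labels


class TestKnnAssign:
    def test_clear_majority(self):
        ref, labels = coords_for_votes({"SST": 20, "PV": 6, "VIP": 3, "NG": 1})
        table = knn_assign(np.zeros((1, 2)), ref, labels, k=30, min_votes=5)
        assert table.iloc[0]["assigned"] == "SST"
        assert table.iloc[0]["reason"] == "ok"
        assert table.iloc[0]["SST"] == 20

    def test_below_min_votes_unassigned(self):
        # unique plurality of 4 sits below the 5-vote floor
        counts = {"T0": 4, **{f"T{i}": 3 for i in range(1, 9)}, "T9": 2}
        assert sum(counts.values()) == 30
        ref, labels = coords_for_votes(counts)
        table = knn_assign(np.zeros((1, 2)), ref, labels, k=30, min_votes=5)
        assert table.iloc[0]["assigned"] == UNASSIGNED
        assert table.iloc[0]["reason"] == "below_min_votes"

    def test_tie_unassigned(self):
        ref, labels = coords_for_votes({"SST": 12, "PV": 12, "VIP": 6})
        table = knn_assign(np.zeros((1, 2)), ref, labels, k=30, min_votes=5)
        assert table.iloc[0]["assigned"] == UNASSIGNED
        assert table.iloc[0]["reason"] == "tie"

    def test_too_few_reference_cells(self):
        with pytest.raises(ValidationError, match="fewer reference"):
            knn_assign(np.zeros((1, 2)), np.zeros((10, 2)), ["A"] * 10, k=30)

    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=3,
                    max_size=3).map(sorted))
    @settings(max_examples=60, deadline=None)
    def test_vote_multiset_matches_brute_force(self, cuts):
        # 3 sorted cut points partition 30 votes into 4 label counts
        bounds = [0, *cuts, 30]
        votes = [bounds[i + 1] - bounds[i] for i in range(4)]
        counts = {lbl: v for lbl, v in zip("ABCD", votes) if v > 0}
        ref, labels = coords_for_votes(counts)
        table = knn_assign(np.zeros((1, 2)), ref, labels, k=30, min_votes=5)
        assigned, reason = brute_force_assign(counts)
        assert table.iloc[0]["assigned"] == assigned
        assert table.iloc[0]["reason"] == reason

    def test_symmetric_construction_all_tied(self):
        # 15 left-mirrored by 15 right at identical radii: every query cell
        # sees a 15/15 split of its 30 nearest reference cells
        radii = np.linspace(1.0, 2.4, 15)
        left = np.stack([-radii, np.zeros(15)], axis=1)
        right = np.stack([radii, np.zeros(15)], axis=1)
        far = np.stack([np.zeros(6), np.full(6, 50.0)], axis=1)
        ref = np.vstack([left, right, far])
        labels = ["L"] * 15 + ["R"] * 15 + (["L"] * 3 + ["R"] * 3)
        query = np.zeros((8, 2))
        query[:, 1] = np.linspace(-0.2, 0.2, 8)
        table = knn_assign(query, ref, labels, k=30, min_votes=5)
        assert (table["assigned"] == UNASSIGNED).all()
        assert (table["reason"] == "tie").all()


class TestCompositionSummary:
    def test_single_type(self):
        transfer = pd.DataFrame({"assigned": ["SST"] * 6})
        comp = composition_summary(transfer, ["c1"] * 3 + ["c2"] * 3)
        assert comp.loc["c1", "frac_SST"] == 1.0
        assert comp.loc["c2", "n_SST"] == 3

    def test_proportions_sum_to_one(self, rng):
        transfer = pd.DataFrame(
            {"assigned": rng.choice(["SST", "PV", UNASSIGNED], size=40)})
        comp = composition_summary(transfer, rng.choice(["a", "b"], size=40))
        frac_cols = [c for c in comp.columns if c.startswith("frac_")]
        assert np.allclose(comp[frac_cols].sum(axis=1), 1.0)
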