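"""Markers, risk-allele DE, replication, module scores, permutation null."""

import numpy as np
import pandas as pd
import pytest

from clinesel.simulate import simulate_expression_cohort
from clinesel.trans_expr import (
    CellExpressionMatrix,
    find_cell_type_markers,
    log_normalize,
    module_group_test,
    module_score,
    permutation_module_test,
    replicate,
    risk_allele_de,
    sex_stratified_de,
    unique_markers,
)

TRANS = [f"g{i:04d}" for i in range(12)]


def small_matrix(counts, cell_types=None, carriers=(True, False)):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    donor_ids = [f"d{i}" for i in range(len(carriers))]
    cells = pd.DataFrame(
        {
            "cell_type": cell_types or ["adipocyte"] * n_cells,
            "donor_id": [donor_ids[i % len(donor_ids)] for i in range(n_cells)],
        },
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
    )
    donors = pd.DataFrame(
        {"risk_carrier": list(carriers), "sex": ["F"] * len(carriers),
         "age": [40] * len(carriers)},
        index=pd.Index(donor_ids, name="donor_id"),
    )
    return CellExpressionMatrix(
        counts=counts, genes=[f"g{i:04d}" for i in range(n_genes)], cells=cells,
        donors=donors,
    )


# ---------------------------------------------------------------- normalization


def test_log_normalize_arithmetic_and_invariance():
    counts = np.array([[1, 9999], [2, 19998]])
    mat = small_matrix(counts)
    norm = log_normalize(mat)
    assert norm[0, 0] == pytest.approx(np.log(2.0))  # count 1 of total 10,000
    # doubling all counts of a cell leaves normalized values unchanged
    np.testing.assert_allclose(norm[0], norm[1], atol=1e-12)


def test_log_normalize_all_zero_gene_stays_zero():
    counts = np.array([[5, 0], [7, 0], [2, 0]])
    norm = log_normalize(small_matrix(counts))
    np.testing.assert_array_equal(norm[:, 1], 0.0)


def test_log_normalize_zero_total_cell_rejected():
    with pytest.raises(ValueError, match="zero total"):
        log_normalize(small_matrix(np.array([[0, 0], [1, 2]])))


# ---------------------------------------------------------------- markers


def planted_marker_cohort(seed=0):
    return simulate_expression_cohort(
        n_donors=16, cells_per_donor=90, n_genes=120, effect=1.0, seed=seed,
        donor_sd=0.0, dispersion=8.0, base_mean=1.0,
        cell_type_props={"adipocyte": 0.45, "tcell": 0.3, "macrophage": 0.25},
        # each type gets three 8-fold genes so library sizes stay balanced
        # across types and fold changes are not compositional artifacts
        marker_spec={
            "adipocyte": {"g0100": 8.0, "g0101": 8.0, "g0102": 8.0},
            "tcell": {"g0103": 8.0, "g0102": 8.0, "g0105": 8.0},
            "macrophage": {"g0104": 8.0, "g0106": 8.0, "g0107": 8.0},
        },
    )


def test_markers_recover_planted_sets_and_unique_difference():
    mat = planted_marker_cohort()
    markers = find_cell_type_markers(mat, logfc_threshold=0.5)
    got = {t: set(df.query("is_marker").index) for t, df in markers.items()}
    assert got["adipocyte"] == {"g0100", "g0101", "g0102"}
    assert got["tcell"] == {"g0102", "g0103", "g0105"}
    assert got["macrophage"] == {"g0104", "g0106", "g0107"}
    # unique adipocyte markers exclude the shared g0102
    uniq = unique_markers(markers, "adipocyte")
    assert uniq == ["g0100", "g0101"]
    assert set(uniq) & got["tcell"] == set()


def test_uniform_gene_is_not_a_marker():
    mat = planted_marker_cohort()
    markers = find_cell_type_markers(mat)
    for df in markers.values():
        assert "g0000" not in df.query("is_marker").index


def test_unique_markers_set_operations():
    mk = {
        "adipocyte": pd.DataFrame({"is_marker": [True, True, True]},
                                  index=["A", "B", "C"]),
        "tcell": pd.DataFrame({"is_marker": [True]}, index=["B"]),
    }
    assert unique_markers(mk, "adipocyte") == ["A", "C"]
    mk["tcell"] = pd.DataFrame({"is_marker": [False]}, index=["B"])
    assert unique_markers(mk, "adipocyte") == ["A", "B", "C"]
    with pytest.raises(ValueError):
        unique_markers(mk, "bcell")
    with pytest.warns(UserWarning, match="shared"):
        shared = {
            "adipocyte": pd.DataFrame({"is_marker": [True]}, index=["A"]),
            "tcell": pd.DataFrame({"is_marker": [True]}, index=["A"]),
        }
        assert unique_markers(shared, "adipocyte") == []


# ---------------------------------------------------------------- risk DE


def test_risk_de_null_rarely_significant():
    total_sig = 0
    for seed in range(5):
        mat = simulate_expression_cohort(
            n_donors=30, cells_per_donor=60, n_genes=60, effect=1.0, seed=seed,
            donor_sd=0.0,
        )
        de, _ = risk_allele_de(mat, "adipocyte", [f"g{i:04d}" for i in range(40)])
        total_sig += int(de["significant"].sum())
    assert total_sig <= 2  # Bonferroni at 0.05 over 5 x 40 tests


def test_risk_de_planted_effect_recovered_with_direction():
    mat = simulate_expression_cohort(
        n_donors=60, cells_per_donor=200, n_genes=100, trans_set=TRANS,
        effect=2.0, seed=1,
    )
    de, skipped = risk_allele_de(mat, "adipocyte", TRANS + ["absent_gene"])
    assert skipped == ["absent_gene"]
    assert de.loc[TRANS, "significant"].all()
    assert (de.loc[TRANS, "direction"] == "up_in_carriers").all()


def test_replication_and_sign_flip():
    disc = simulate_expression_cohort(
        n_donors=40, cells_per_donor=120, n_genes=80, trans_set=TRANS,
        effect=2.0, seed=11,
    )
    de, _ = risk_allele_de(disc, "adipocyte", TRANS)
    rep_same = simulate_expression_cohort(
        n_donors=40, cells_per_donor=120, n_genes=80, trans_set=TRANS,
        effect=2.0, seed=12,
    )
    rep = replicate(de, rep_same, "adipocyte")
    assert rep["replicated"].all()
    # flipped effect direction: nothing replicates
    rep_flip = simulate_expression_cohort(
        n_donors=40, cells_per_donor=120, n_genes=80, trans_set=TRANS,
        effect=0.5, seed=13,
    )
    rep2 = replicate(de, rep_flip, "adipocyte")
    assert not rep2["replicated"].any()
    # empty discovery set -> empty output, no test run
    empty = de.copy()
    empty["significant"] = False
    assert len(replicate(empty, rep_same, "adipocyte")) == 0


# ---------------------------------------------------------------- module scores


def test_module_score_zero_when_all_genes_identical():
    counts = np.ones((30, 40), dtype=int)
    mat = small_matrix(counts)
    scores = module_score(mat, ["g0000", "g0001"], n_bins=4, n_ctrl=10, seed=0)
    np.testing.assert_allclose(scores, 0.0, atol=1e-12)


def test_module_score_shift_cancellation():
    mat = simulate_expression_cohort(
        n_donors=10, cells_per_donor=30, n_genes=80, effect=1.0, seed=2
    )
    s1 = module_score(mat, TRANS, seed=3)
    mat.normalized = mat.require_normalized() + 1.7  # constant shift
    s2 = module_score(mat, TRANS, seed=3)
    np.testing.assert_allclose(s1, s2, atol=1e-10)


def test_module_score_recovers_planted_offset(rng):
    # gene set shifted by +c against expression-matched controls
    n_cells, n_genes = 400, 200
    base = rng.normal(5.0, 0.01, size=(n_cells, n_genes))
    c = 0.8
    base[:, :10] += c
    mat = small_matrix(np.ones((n_cells, n_genes), dtype=int))
    mat.normalized = base
    scores = module_score(mat, [f"g{i:04d}" for i in range(10)], n_bins=4,
                          n_ctrl=50, seed=4)
    assert scores.mean() == pytest.approx(c, abs=0.05)


def test_module_score_deterministic_given_seed():
    mat = simulate_expression_cohort(n_donors=8, cells_per_donor=25, n_genes=60,
                                     effect=1.0, seed=5)
    a = module_score(mat, TRANS, seed=7)
    b = module_score(mat, TRANS, seed=7)
    np.testing.assert_array_equal(a, b)


def test_module_group_test_separated_scores():
    mat = simulate_expression_cohort(n_donors=20, cells_per_donor=50, n_genes=40,
                                     effect=1.0, seed=6)
    carrier = mat.carrier_mask()
    scores = np.where(carrier, 1.0, 0.0) + np.random.default_rng(0).normal(
        0, 1e-3, mat.n_cells
    )
    res = module_group_test(scores, mat.cells, mat.donors)
    assert res["p"] < 1e-30


def test_module_effect_monotone_in_size():
    ps = []
    for effect in (1.2, 1.8, 3.0):
        mat = simulate_expression_cohort(
            n_donors=30, cells_per_donor=60, n_genes=80, trans_set=TRANS,
            effect=effect, seed=8,
        )
        scores = module_score(mat, TRANS, seed=8)
        ps.append(module_group_test(scores, mat.cells, mat.donors)["p"])
    assert ps[0] > ps[1] > ps[2]


# ---------------------------------------------------------------- permutation


def test_permutation_p_floor_and_boundary():
    mat = simulate_expression_cohort(
        n_donors=30, cells_per_donor=40, n_genes=60, trans_set=TRANS, effect=3.0,
        seed=9,
    )
    res = permutation_module_test(mat, TRANS, B=200, seed=10)
    assert res["perm_p"] >= 1 / (res["B"] + 1)
    assert res["perm_p_raw"] == pytest.approx(0.0)
    # B = 1 and the single permutation beats the observed -> perm p = 1
    null_mat = simulate_expression_cohort(
        n_donors=8, cells_per_donor=10, n_genes=30, effect=1.0, risk_maf=0.5, seed=0,
    )
    res1 = permutation_module_test(null_mat, ["g0000"], B=1, seed=3)
    assert res1["perm_p"] <= 1.0 and res1["B"] >= 1


def test_permutation_fast_path_matches_scipy():
    """The rank-sum p computed from precalculated per-donor rank sums must
    equal scipy's asymptotic Mann-Whitney p on the same grouping."""
    from scipy.stats import mannwhitneyu

    mat = simulate_expression_cohort(n_donors=12, cells_per_donor=30, n_genes=50,
                                     trans_set=TRANS, effect=1.5, seed=14)
    res = permutation_module_test(mat, TRANS, B=5, seed=15)
    scores = module_score(mat, TRANS, seed=15)
    carrier = mat.carrier_mask()
    ref = mannwhitneyu(scores[carrier], scores[~carrier],
                       alternative="two-sided", method="asymptotic").pvalue
    assert res["observed_p"] == pytest.approx(ref, rel=1e-10)


def test_permutation_caps_at_distinct_assignments():
    mat = simulate_expression_cohort(n_donors=6, cells_per_donor=10, n_genes=30,
                                     effect=1.0, seed=16)
    k = int(mat.donors["risk_carrier"].sum())
    from math import comb

    res = permutation_module_test(mat, ["g0000", "g0001"], B=100000, seed=17)
    assert res["B"] == comb(6, k)


def test_permutation_shuffles_donors_not_cells():
    """All cells of one donor stay together: with one extreme donor the null
    p distribution takes few distinct values, impossible under cell-level
    shuffling."""
    mat = simulate_expression_cohort(n_donors=8, cells_per_donor=20, n_genes=30,
                                     effect=1.0, seed=18, donor_sd=1.5)
    res = permutation_module_test(mat, ["g0000"], B=10_000, seed=19)
    from math import comb

    assert len(np.unique(res["null_p"])) <= comb(8, int(mat.donors.risk_carrier.sum()))


# ---------------------------------------------------------------- sex strata


def test_sex_stratified_effect_in_one_sex_only():
    mat = simulate_expression_cohort(
        n_donors=60, cells_per_donor=120, n_genes=80, trans_set=TRANS,
        seed=21, sex_specific_effect={"F": 2.5, "M": 1.0},
    )
    res = sex_stratified_de(mat, TRANS)
    assert res["F"]["significant"].sum() >= 10
    assert res["M"]["significant"].sum() <= 2


def test_sex_stratified_concordant_directions_when_identical_model():
    agree = 0
    for seed in range(5):
        mat = simulate_expression_cohort(
            n_donors=60, cells_per_donor=100, n_genes=60, trans_set=TRANS,
            effect=2.0, seed=30 + seed,
        )
        res = sex_stratified_de(mat, TRANS)
        if len(res) == 2:
            signs_f = np.sign(res["F"].loc[TRANS, "logfc"])
            signs_m = np.sign(res["M"].loc[TRANS, "logfc"])
            agree += (signs_f == signs_m).mean() >= 0.9
    assert agree >= 4


def test_sex_with_single_carrier_group_skipped():
    mat = simulate_expression_cohort(n_donors=20, cells_per_donor=20, n_genes=30,
                                     effect=1.0, seed=40)
    # force every male donor to carrier status
    mat.donors.loc[mat.donors["sex"] == "M", "risk_carrier"] = True
    res = sex_stratified_de(mat, ["g0000"])
    assert "M" not in res


# ---------------------------------------------------------------- invariants


def test_bonferroni_monotone_and_capped():
    mat = simulate_expression_cohort(n_donors=20, cells_per_donor=40, n_genes=50,
                                     trans_set=TRANS, effect=1.5, seed=50)
    de, _ = risk_allele_de(mat, "adipocyte", [f"g{i:04d}" for i in range(30)])
    assert (de["p_adj"] >= de["p"] - 1e-15).all()
    assert (de["p_adj"] <= 1.0).all()
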