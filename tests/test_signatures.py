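"""Signature extraction, assignment, exposure fitting, attribution."""

import numpy as np
import pandas as pd
import pytest

from myelosig.catalog import CATEGORIES_96
from myelosig.signatures import (
    SignatureSet,
    assign_to_reference,
    attribute_mutations,
    collapse_flat,
    cosine_similarity,
    extract_de_novo,
    fit_exposures,
    major_signatures,
    normalize_exposures,
)
from myelosig.synthetic import block_signatures


class TestCosine:
    def test_identical_vectors_score_one(self):
        v = np.array([0.2, 0.5, 0.3])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_score_zero(self):
        assert cosine_similarity([1, 0, 0], [0, 1, 1]) == pytest.approx(0.0)

    def test_closed_form_value(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(
            1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


def _multinomial_catalog(sigs, exposures, rng):
    """Counts drawn category-wise from planted signature mixtures."""
    S = sigs.matrix()
    rows = []
    for e in exposures:
        row = np.zeros(S.shape[1], dtype=int)
        for k, n in enumerate(e):
            row += rng.multinomial(int(n), S[k])
        rows.append(row)
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(exposures))],
                        columns=list(sigs.categories))


class TestExtraction:
    def test_rank_one_truth_recovered(self):
        sigs = block_signatures(1)
        rng = np.random.default_rng(0)
        cat = _multinomial_catalog(sigs, [[500]] * 20, rng)
        s_hat, _, diag = extract_de_novo(cat, k_range=range(1, 4),
                                         n_restarts=5, seed=0)
        assert diag.chosen_k == 1
        assert cosine_similarity(s_hat.matrix()[0], sigs.matrix()[0]) > 0.99

    def test_three_signature_mixture_recovered(self):
        sigs = block_signatures(3)
        rng = np.random.default_rng(1)
        exp = rng.dirichlet([0.7] * 3, size=100) * 500
        cat = _multinomial_catalog(sigs, exp, rng)
        s_hat, _, diag = extract_de_novo(cat, k_range=range(2, 6),
                                         n_restarts=8, seed=1)
        assert diag.chosen_k == 3
        T, H = sigs.matrix(), s_hat.matrix()
        best = [max(cosine_similarity(t, h) for h in H) for t in T]
        assert min(best) > 0.95

    def test_sample_permutation_invariance(self):
        sigs = block_signatures(3)
        rng = np.random.default_rng(2)
        exp = rng.dirichlet([0.7] * 3, size=60) * 400
        cat = _multinomial_catalog(sigs, exp, rng)
        s1, _, _ = extract_de_novo(cat, k_range=[3], n_restarts=5, seed=3)
        perm = cat.sample(frac=1.0, random_state=9)
        s2, _, _ = extract_de_novo(perm, k_range=[3], n_restarts=5, seed=3)
        sim = np.array([[cosine_similarity(a, b) for b in s2.matrix()]
                        for a in s1.matrix()])
        assert sim.max(axis=1).min() > 0.98  # same signatures up to order

    def test_infeasible_rank_raises(self):
        cat = pd.DataFrame(np.ones((3, 96)), columns=list(CATEGORIES_96))
        with pytest.raises(ValueError, match="infeasible"):
            extract_de_novo(cat, k_range=range(2, 10), seed=0)


class TestAssignment:
    def test_identity_assignment(self):
        ref = block_signatures(4, prefix="R")
        dn = SignatureSet.from_matrix(["N1"], ref.matrix()[2:3],
                                      ref.categories)
        out = assign_to_reference(dn, ref)
        assert out["N1"] == ("R3", pytest.approx(1.0))

    def test_threshold_is_strict(self):
        ref = block_signatures(4, prefix="R")
        # a profile far from every reference stays novel at the default cut
        onehot = np.zeros(96)
        onehot[95] = 1.0  # off-block category for R1..R3, low mass for R4
        dn = SignatureSet.from_matrix(["N1"], onehot[None, :], ref.categories)
        scores = [cosine_similarity(onehot, r) for r in ref.matrix()]
        assert max(scores) < 0.75
        assert assign_to_reference(dn, ref)["N1"][0] == "novel"
        # cosine equal to the threshold does not assign (strict >)
        dn2 = SignatureSet.from_matrix(["N1"], ref.matrix()[:1], ref.categories)
        assert assign_to_reference(dn2, ref, threshold=1.0)["N1"][0] == "novel"

    def test_most_similar_reference_wins(self):
        ref = block_signatures(3, prefix="R")
        mix = 0.2 * ref.matrix()[0] + 0.8 * ref.matrix()[1]
        dn = SignatureSet.from_matrix(["N1"], mix[None, :], ref.categories)
        out = assign_to_reference(dn, ref, threshold=0.5)
        assert out["N1"][0] == "R2"

    def test_category_mismatch_raises(self):
        ref = block_signatures(2)
        dn = SignatureSet.from_matrix(
            ["N1"], np.full((1, 32), 1 / 32), range(32))
        with pytest.raises(ValueError):
            assign_to_reference(dn, ref)


class TestExposures:
    def test_planted_two_signature_mix_recovered(self):
        sigs = block_signatures(4)
        S = sigs.matrix()
        exact = pd.DataFrame((100 * S[0] + 50 * S[1])[None, :], index=["s"],
                             columns=sigs.categories)
        exp = fit_exposures(exact, sigs)
        assert exp.loc["s", "S1"] == pytest.approx(100, abs=1e-6)
        assert exp.loc["s", "S2"] == pytest.approx(50, abs=1e-6)
        # integer-rounded counts recover within rounding error
        rounded = pd.DataFrame(np.round(2000 * S[0] + 1000 * S[1])[None, :],
                               index=["s"], columns=sigs.categories)
        exp2 = fit_exposures(rounded, sigs)
        # rounding each of 96 cells by up to 0.5 can move ~25 counts of mass
        assert exp2.loc["s", "S1"] == pytest.approx(2000, abs=25)
        assert exp2.loc["s", "S2"] == pytest.approx(1000, abs=25)
        assert exp2.loc["s", ["S3", "S4"]].max() < 10

    def test_zero_row_gives_zero_exposures(self):
        sigs = block_signatures(3)
        cat = pd.DataFrame(np.zeros((1, 96)), index=["s"],
                           columns=sigs.categories)
        assert fit_exposures(cat, sigs).to_numpy().sum() == 0

    def test_single_active_signature_dominates(self):
        sigs = block_signatures(5)
        rng = np.random.default_rng(3)
        cat = pd.DataFrame(rng.multinomial(1000, sigs.matrix()[2])[None, :],
                           index=["s"], columns=sigs.categories)
        norm = normalize_exposures(fit_exposures(cat, sigs))
        assert norm.loc["s", "S3"] > 0.95

    def test_refit_on_reconstruction_is_idempotent(self):
        sigs = block_signatures(3)
        rng = np.random.default_rng(4)
        exp = rng.dirichlet([1] * 3, size=10) * 300
        recon = exp @ sigs.matrix()
        cat = pd.DataFrame(recon, columns=sigs.categories)
        e1 = fit_exposures(cat, sigs)
        recon2 = e1.to_numpy() @ sigs.matrix()
        e2 = fit_exposures(pd.DataFrame(recon2, columns=sigs.categories), sigs)
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-6)


class TestFlatCollapse:
    def _exposures(self):
        return pd.DataFrame(
            {"1": [5.0, 1.0], "3": [10.0, 2.0], "5": [5.0, 3.0],
             "8": [5.0, 4.0], "13": [2.0, 0.0]}, index=["a", "b"])

    def test_flat_sum_replaces_members(self):
        out = collapse_flat(self._exposures())
        assert out.loc["a", "flat"] == 20.0
        assert list(out.columns) == ["1", "13", "flat"]

    def test_total_exposure_conserved(self):
        exp = self._exposures()
        out = collapse_flat(exp)
        np.testing.assert_allclose(out.sum(axis=1), exp.sum(axis=1))

    def test_missing_flat_id_raises(self):
        with pytest.raises(KeyError):
            collapse_flat(self._exposures().drop(columns=["5"]))


class TestAttribution:
    def test_single_active_signature_gets_probability_one(self):
        sigs = block_signatures(3)
        exp = pd.DataFrame([[100.0, 0.0, 0.0]], index=["s"],
                           columns=sigs.ids)
        out = attribute_mutations(
            pd.Series([CATEGORIES_96[50]]), pd.Series(["s"]), exp, sigs)
        assert out.loc[0, "S1"] == pytest.approx(1.0)
        assert out.loc[0, "signature"] == "S1"

    def test_symmetric_tie_splits_half_and_breaks_to_first_id(self):
        cats = list(CATEGORIES_96)
        mat = np.vstack([np.full(96, 1 / 96), np.full(96, 1 / 96)])
        sigs = SignatureSet.from_matrix(["A", "B"], mat, cats)
        exp = pd.DataFrame([[50.0, 50.0]], index=["s"], columns=["A", "B"])
        out = attribute_mutations(pd.Series([cats[0]]), pd.Series(["s"]),
                                  exp, sigs)
        assert out.loc[0, "A"] == pytest.approx(0.5)
        assert out.loc[0, "signature"] == "A"

    def test_rows_sum_to_one(self, cohort):
        muts, true_exp = cohort
        sigs = block_signatures(5)
        out = attribute_mutations(muts["category"], muts["sample_id"],
                                  true_exp.astype(float), sigs)
        sums = out[list(sigs.ids)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_true_signature_has_highest_mean_probability(self, cohort):
        muts, true_exp = cohort
        sigs = block_signatures(5)
        out = attribute_mutations(muts["category"], muts["sample_id"],
                                  true_exp.astype(float), sigs)
        for sig in sigs.ids:
            sub = out[muts["true_signature"] == sig]
            if len(sub) < 100:
                continue
            means = sub[list(sigs.ids)].mean()
            assert means.idxmax() == sig

    def test_impossible_category_flagged_nan(self):
        cats = list(CATEGORIES_96)
        mat = np.zeros((1, 96))
        mat[0, :10] = 0.1
        sigs = SignatureSet.from_matrix(["A"], mat, cats)
        exp = pd.DataFrame([[10.0]], index=["s"], columns=["A"])
        out = attribute_mutations(pd.Series([cats[50]]), pd.Series(["s"]),
                                  exp, sigs)
        assert np.isnan(out.loc[0, "A"])
        assert out.loc[0, "signature"] is None


def test_major_signature_selection_uses_mean_contribution():
    exp = pd.DataFrame({"A": [97.0, 97.0], "B": [3.0, 3.0], "C": [0.0, 0.0]})
    assert major_signatures(exp) == ["A", "B"]  # strict > 1% mean
    assert major_signatures(exp, 0.05) == ["A"]
    assert major_signatures(pd.DataFrame({"A": [99.0], "B": [1.0]})) == ["A"]
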