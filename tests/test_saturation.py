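"""Distances, saturation regression, entropy index and gene flagging."""

import numpy as np
import pandas as pd
import pytest

from lbalens.alignment import Alignment
from lbalens.io import parse_tree
from lbalens.models import SubstitutionModel
from lbalens.saturation import (expected_full_saturation_entropy,
                                fit_substitution_model,
                                flag_saturated_genes, iss_index, iss_test,
                                ml_distance_matrix, p_distance_matrix,
                                patristic_matrix, saturation_regression)
from lbalens.simulate import simulate_alignment
from tests.conftest import random_alignment


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment.from_dict({"a": "ACGT", "b": "ACGT"})
        assert p_distance_matrix(aln).loc["a", "b"] == 0.0

    def test_quarter(self):
        aln = Alignment.from_dict({"a": "ACGT", "b": "ACGA"})
        assert p_distance_matrix(aln).loc["a", "b"] == 0.25

    def test_gap_column_excluded(self):
        aln = Alignment.from_dict({"a": "AC-T", "b": "ACGT"})
        assert p_distance_matrix(aln).loc["a", "b"] == 0.0

    def test_no_comparable_sites_is_nan(self):
        aln = Alignment.from_dict({"a": "A---", "b": "-CGT"})
        assert np.isnan(p_distance_matrix(aln).loc["a", "b"])


class TestMLDistance:
    def test_jc69_closed_form(self):
        # p = 0.25 over 4 sites
        aln = Alignment.from_dict({"a": "ACGT", "b": "ACGA"})
        d = ml_distance_matrix(aln, model="JC69").loc["a", "b"]
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * 0.25 / 3),
                                  abs=1e-12)

    def test_zero_distance(self):
        aln = Alignment.from_dict({"a": "ACGT", "b": "ACGT"})
        for model in ("JC69", "K80", "GTR"):
            assert ml_distance_matrix(aln, model=model).loc["a", "b"] == 0.0

    def test_jc_dominates_p_distance(self, rng):
        """JC correction expands distances whenever p > 0."""
        aln = random_alignment(rng, 5, 400)
        p = p_distance_matrix(aln).to_numpy()
        d = ml_distance_matrix(aln, model="JC69").to_numpy()
        iu = np.triu_indices(5, 1)
        assert (d[iu] >= p[iu]).all()

    def test_gtr_recovers_simulated_distance(self):
        model = SubstitutionModel(
            freqs=np.array([0.35, 0.15, 0.2, 0.3]),
            rates=np.array([1.0, 3.0, 0.6, 1.2, 3.6, 1.0]))
        tree = parse_tree("(a:0.4,b:0.0);", rooting="default-rooted")
        aln = simulate_alignment(tree, model, 100_000, seed=4)
        d = ml_distance_matrix(aln, model="GTR").loc["a", "b"]
        assert d == pytest.approx(0.4, abs=0.02)

    def test_saturated_pair_capped(self, rng):
        aln = random_alignment(rng, 2, 200)  # i.i.d. rows: beyond ceiling
        d = ml_distance_matrix(aln, model="JC69", d_max=5.0).loc["t0", "t1"]
        assert d <= 5.0

    def test_model_selection_prefers_generating_family(self):
        """BIC picks a transition-biased model for kappa >> 1 data."""
        model = SubstitutionModel.k80(kappa=8.0)
        tree = parse_tree("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.0);",
                          rooting="default-rooted")
        aln = simulate_alignment(tree, model, 20_000, seed=1)
        best, report = fit_substitution_model(
            aln, candidates=("JC69", "K80"))
        assert best.name == "K80"
        assert report["K80"]["bic"] < report["JC69"]["bic"]


class TestPatristic:
    def test_hand_example(self):
        t = parse_tree("((a:1,b:2):0.5,c:3);")
        pat = patristic_matrix(t)
        assert pat.loc["a", "b"] == 3.0
        assert pat.loc["a", "c"] == 4.5

    def test_star_tree(self):
        t = parse_tree("(a:2,b:2,c:2,d:2);")
        pat = patristic_matrix(t)
        iu = np.triu_indices(4, 1)
        assert (pat.to_numpy()[iu] == 4.0).all()

    def test_missing_length_rejected(self):
        t = parse_tree("((a:1,b),c:3);")
        with pytest.raises(ValueError):
            patristic_matrix(t)


class TestRegression:
    def _mat(self, arr, taxa="abcd"):
        return pd.DataFrame(arr, index=list(taxa), columns=list(taxa))

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0])
    def test_exact_linear(self, alpha, rng):
        X = rng.uniform(0.5, 2.0, (4, 4))
        X = (X + X.T) / 2
        np.fill_diagonal(X, 0)
        reg = saturation_regression(self._mat(X), self._mat(alpha * X))
        assert reg.slope == pytest.approx(alpha)
        assert reg.R2 == pytest.approx(1.0)

    def test_constant_response_zero_slope(self, rng):
        X = rng.uniform(0.5, 2.0, (4, 4))
        X = (X + X.T) / 2
        np.fill_diagonal(X, 0)
        C = np.full((4, 4), 0.3)
        np.fill_diagonal(C, 0)
        reg = saturation_regression(self._mat(X), self._mat(C))
        assert reg.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        C = np.full((4, 4), 0.3)
        np.fill_diagonal(C, 0)
        with pytest.raises(ValueError):
            saturation_regression(self._mat(C), self._mat(C))

    def test_saturation_flattens_slope(self):
        """The same gene at 10x tree depth regresses with smaller slope."""
        model = SubstitutionModel.jc69()
        nwk = "((a:{s},b:{s}):{s},(c:{s},d:{s}):0.0);"
        slopes = []
        for scale in (0.05, 0.5):
            tree = parse_tree(nwk.format(s=scale), rooting="default-rooted")
            aln = simulate_alignment(tree, model, 3000, seed=2)
            d = ml_distance_matrix(aln, model="JC69")
            from lbalens.trees import nj_tree
            fitted = nj_tree(d)
            reg = saturation_regression(patristic_matrix(fitted),
                                        p_distance_matrix(aln))
            slopes.append(reg.slope)
        assert slopes[1] < slopes[0]


class TestIssIndex:
    def test_invariant_alignment(self):
        aln = Alignment.from_dict({c: "AACCGGTT" for c in "abcd"})
        st = iss_index(aln)
        assert st.H == 0.0 and st.Iss == 0.0

    def test_engineered_half(self):
        # every site: two equifrequent states; global frequencies uniform
        aln = Alignment.from_dict({
            "a": "AG", "b": "AG", "c": "CT", "d": "CT"})
        st = iss_index(aln)
        assert st.H == pytest.approx(1.0)
        assert st.Iss == pytest.approx(
            1.0 / expected_full_saturation_entropy(np.full(4, 0.25), 4))

    def test_randomized_limit(self, rng):
        aln = random_alignment(rng, 32, 10_000)
        assert iss_index(aln).Iss == pytest.approx(1.0, abs=0.02)

    def test_order_invariance(self, rng):
        aln = random_alignment(rng, 6, 300)
        perm_t = rng.permutation(6)
        perm_c = rng.permutation(300)
        shuffled = Alignment([aln.taxa[i] for i in perm_t],
                             aln.matrix[perm_t][:, perm_c])
        assert iss_index(aln).Iss == pytest.approx(iss_index(shuffled).Iss)

    def test_monotone_in_tree_depth(self):
        """Deeper trees accumulate more per-site entropy."""
        model = SubstitutionModel.jc69(alpha=0.5)
        means = []
        for depth in (0.05, 0.3, 1.5):
            vals = []
            for seed in range(6):
                nwk = (f"((a:{depth},b:{depth}):{depth},"
                       f"(c:{depth},d:{depth}):0.0);")
                tree = parse_tree(nwk, rooting="default-rooted")
                aln = simulate_alignment(tree, model, 1000, seed=seed)
                vals.append(iss_index(aln).Iss)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestIssTest:
    def test_random_gene_flagged(self, rng):
        aln = random_alignment(rng, 6, 500)
        st = iss_test(aln, reps=150, seed=3)
        assert st.saturated
        assert st.p_sym < 0.05

    def test_conserved_gene_not_flagged(self):
        tree = parse_tree("((a:0.02,b:0.02):0.02,(c:0.02,d:0.02):0.0);",
                          rooting="default-rooted")
        aln = simulate_alignment(tree, SubstitutionModel.jc69(), 600,
                                 seed=5)
        st = iss_test(aln, reps=150, seed=3)
        assert not st.saturated
        assert st.Iss < st.Iss_c_sym

    def test_seed_determinism(self, rng):
        aln = random_alignment(rng, 5, 300)
        a = iss_test(aln, reps=120, seed=9)
        b = iss_test(aln, reps=120, seed=9)
        assert (a.Iss, a.Iss_c_sym, a.Iss_c_asym, a.p_sym) == \
            (b.Iss, b.Iss_c_sym, b.Iss_c_asym, b.p_sym)


class TestFlagging:
    def test_bimodal_left_shoulder(self, rng):
        vals = {f"g{i}": v for i, v in enumerate(
            np.concatenate([rng.normal(0.1, 0.01, 12),
                            rng.normal(0.9, 0.05, 70)]))}
        flagged, cut = flag_saturated_genes(vals, method="valley")
        assert flagged == {f"g{i}" for i in range(12)}
        assert 0.15 < cut < 0.85

    def test_unimodal_falls_back_to_percentile(self, rng):
        vals = {f"g{i}": v for i, v in enumerate(rng.normal(0.5, 0.01, 80))}
        flagged, cut = flag_saturated_genes(vals, method="valley", param=15)
        assert 0 < len(flagged) <= 0.2 * 80

    def test_percentile_method(self, rng):
        vals = {f"g{i}": float(i) for i in range(100)}
        flagged, cut = flag_saturated_genes(vals, method="percentile",
                                            param=15)
        assert flagged == {f"g{i}" for i in range(15)}

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            flag_saturated_genes({"a": 1.0, "b": 2.0}, "percentile", 50)
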