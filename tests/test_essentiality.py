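"""Insertion-index essentiality: filter, II, gamma mixture, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from necalloc import essentiality as ess, synth
from necalloc.synth import InsertionTable


def table_from_counts(lengths, positions):
    genes = pd.DataFrame({
        "gene": [f"g{i}" for i in range(len(lengths))],
        "order": np.arange(len(lengths)),
        "length_bp": lengths,
    })
    pos = {f"g{i}": np.asarray(p, dtype=float) for i, p in enumerate(positions)}
    return InsertionTable(genes=genes, positions=pos)


class TestCentralFilter:
    def test_boundary_arithmetic(self):
        t = table_from_counts([1000], [[0.05, 0.5, 0.95]])
        filtered = ess.central_orf_filter(t)
        assert len(filtered.positions["g0"]) == 1

    def test_all_central_unchanged(self):
        t = table_from_counts([1000], [[0.2, 0.5, 0.8]])
        filtered = ess.central_orf_filter(t)
        np.testing.assert_array_equal(filtered.positions["g0"],
                                      t.positions["g0"])

    def test_out_of_range_positions_rejected(self):
        t = table_from_counts([1000], [[1.5]])
        with pytest.raises(ValueError, match="outside"):
            ess.central_orf_filter(t)

    def test_uniform_positions_retain_expected_fraction(self):
        rng = np.random.default_rng(0)
        t = table_from_counts([1000], [rng.uniform(0, 1, 20000)])
        filtered = ess.central_orf_filter(t)
        frac = len(filtered.positions["g0"]) / 20000
        assert frac == pytest.approx(0.8, abs=0.01)


class TestInsertionIndex:
    def test_zero_insertions_give_zero_ii(self):
        t = table_from_counts([1000] * 10, [[0.5]] * 9 + [[]])
        ii = ess.insertion_index(t, window_genes=10)
        assert ii["g9"] == 0.0

    def test_average_gene_has_unit_ii(self):
        # identical genes, identical counts: every gene matches its region
        t = table_from_counts([1000] * 20, [[0.5, 0.6]] * 20)
        ii = ess.insertion_index(t, window_genes=10)
        assert np.allclose(ii.to_numpy(), 1.0)

    def test_matches_brute_force_recomputation(self):
        lib, _ = synth.gen_insertion_library(n_genes=500, seed=11)
        ii = ess.insertion_index(lib, window_genes=100)
        # explicit-loop oracle with truncated windows
        genes = lib.genes.sort_values("order").reset_index(drop=True)
        n = [len(lib.positions[g]) for g in genes["gene"]]
        k = genes["length_bp"].tolist()
        for i, gene in enumerate(genes["gene"]):
            lo = max(0, i - 50)
            hi = min(len(genes), lo + 100)
            lo = max(0, hi - 100)
            nr = sum(n[lo:hi])
            kr = sum(k[lo:hi])
            expected = (n[i] / k[i]) / (nr / kr) if nr else np.nan
            assert ii[gene] == pytest.approx(expected, rel=1e-12), gene

    def test_scale_invariance_of_counts(self):
        """Tripling every gene's insertion count leaves II unchanged."""
        lib, _ = synth.gen_insertion_library(n_genes=200, seed=12)
        tripled = InsertionTable(
            genes=lib.genes.copy(),
            positions={g: np.concatenate([p, p, p]) for g, p in
                       lib.positions.items()})
        ii1 = ess.insertion_index(lib)
        ii3 = ess.insertion_index(tripled)
        pd.testing.assert_series_equal(ii1, ii3)

    def test_empty_window_flagged_nan(self):
        t = table_from_counts([1000] * 5, [[]] * 5)
        ii = ess.insertion_index(t, window_genes=5)
        assert ii.isna().all()


class TestGammaMixture:
    def test_parameter_recovery_from_known_mixture(self):
        """Component means of a 0.1/0.9 mixture of gamma(0.3, 0.1) and
        gamma(8, 0.15) are recovered within 15% at n = 5000."""
        rng = np.random.default_rng(42)
        n = 5000
        labels = rng.uniform(size=n) < 0.1
        x = np.where(labels, rng.gamma(0.3, 0.1, n), rng.gamma(8.0, 0.15, n))
        fit = ess.fit_gamma_mixture(pd.Series(x))
        assert fit.mean_low == pytest.approx(0.3 * 0.1, rel=0.15)
        assert fit.mean_high == pytest.approx(8.0 * 0.15, rel=0.15)
        assert fit.weight_low == pytest.approx(0.1, abs=0.03)

    def test_single_component_flags_degenerate(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(5.0, 0.2, 2000)
        fit = ess.fit_gamma_mixture(pd.Series(x))
        # either the weights collapse or the components coincide
        close_means = abs(fit.mean_low - fit.mean_high) < 0.5 * fit.mean_high
        assert fit.degenerate or close_means

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.gamma(0.3, 0.1, 500), rng.gamma(8, 0.15, 4500)])
        f1 = ess.fit_gamma_mixture(pd.Series(x))
        f2 = ess.fit_gamma_mixture(pd.Series(x[::-1].copy()))
        assert f1.mean_low == pytest.approx(f2.mean_low, rel=1e-9)
        assert f1.weight_low == pytest.approx(f2.weight_low, rel=1e-9)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ess.fit_gamma_mixture(pd.Series([-1.0, 1.0]))


@pytest.fixture(scope="module")
def fitted():
    lib, truth = synth.gen_insertion_library(seed=0)
    filt = ess.central_orf_filter(lib)
    ii = ess.insertion_index(filt)
    fit = ess.fit_gamma_mixture(ii)
    return ii, fit, truth


class TestClassification:
    def test_zero_ii_called_essential(self, fitted):
        ii, fit, _ = fitted
        calls = ess.classify_essentiality(ii, fit)
        zero_calls = calls[calls["II"] == 0.0]["class"]
        assert (zero_calls == ess.ESSENTIAL).all()

    def test_classification_monotone_in_ii(self, fitted):
        ii, fit, _ = fitted
        calls = ess.classify_essentiality(ii, fit).dropna(subset=["II"])
        ess_max = calls.loc[calls["class"] == ess.ESSENTIAL, "II"].max()
        non_min = calls.loc[calls["class"] == ess.NON_ESSENTIAL, "II"].min()
        assert ess_max < non_min

    def test_fold_one_leaves_no_ambiguous_zone(self, fitted):
        ii, fit, _ = fitted
        lower, upper = ess.density_ratio_thresholds(fit, fold=1.0)
        assert upper - lower <= 2e-4  # single crossover up to grid resolution

    def test_recovery_across_seeds(self):
        """500 genes, 10% essential, rate ratio 0.02: mean accuracy >= 95%,
        essential recall >= 90%, ambiguous fraction < 10% over 10 seeds."""
        accs, recalls, ambiguous = [], [], []
        for seed in range(10):
            lib, truth = synth.gen_insertion_library(seed=seed)
            calls = ess.classify_library(lib)
            is_ess = calls["gene"].isin(truth.essential_genes)
            pred = calls["class"]
            correct = ((pred == ess.ESSENTIAL) & is_ess) | \
                      ((pred == ess.NON_ESSENTIAL) & ~is_ess)
            accs.append(correct.mean())
            recalls.append(((pred == ess.ESSENTIAL) & is_ess).sum() / is_ess.sum())
            ambiguous.append((pred == ess.PROBABLY).mean())
        assert np.mean(accs) >= 0.95
        assert np.mean(recalls) >= 0.90
        assert np.mean(ambiguous) < 0.10


class TestReactionPropagation:
    @pytest.fixture()
    def calls(self):
        return pd.DataFrame({
            "gene": ["edd", "eda", "tcaL", "fdsA", "fdhS"],
            "class": [ess.ESSENTIAL, ess.NON_ESSENTIAL, ess.PROBABLY,
                      ess.NON_ESSENTIAL, ess.NON_ESSENTIAL],
        })

    def test_any_essential_gene_dominates(self, toy_network, calls):
        out = ess.propagate_to_reactions(calls, toy_network).set_index("reaction")
        assert out.loc["ED", "class"] == ess.ESSENTIAL  # edd essential, eda not

    def test_probably_essential_propagates(self, toy_network, calls):
        out = ess.propagate_to_reactions(calls, toy_network).set_index("reaction")
        assert out.loc["TCA", "class"] == ess.PROBABLY

    def test_all_non_essential(self, toy_network, calls):
        out = ess.propagate_to_reactions(calls, toy_network).set_index("reaction")
        assert out.loc["FDH", "class"] == ess.NON_ESSENTIAL

    def test_reactions_without_genes_excluded(self, toy_network, calls):
        out = ess.propagate_to_reactions(calls, toy_network)
        assert "BIOMASS" not in set(out["reaction"])
        assert "EX_fru" not in set(out["reaction"])
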