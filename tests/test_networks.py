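import numpy as np
import pandas as pd
import pytest

import soilheat as sh
from soilheat.design import DesignSpec
from soilheat.networks import (
    AssociationModel,
    AssociationSubset,
    SignedBipartiteNetwork,
    connectance,
    connectance_difference_test,
    extract_network,
    fit_association_model,
    make_subsets,
)


def toy_subset(nC, nF, n=20, beta=None, delta=None, sigma=0.5, seed=0,
               presence=None):
    """Standalone association subset with known planted slopes."""
    r = np.random.default_rng(seed)
    Z = r.normal(size=(n, nC))
    Z = (Z - Z.mean(0)) / Z.std(0)
    heat = np.array([0, 1] * (n // 2), float)
    B = np.zeros((nC, nF)) if beta is None else np.asarray(beta, float)
    D = np.zeros((nC, nF)) if delta is None else np.asarray(delta, float)
    Y = Z @ B + heat[:, None] * (Z @ D) + r.normal(0, sigma, size=(n, nF))
    if presence is not None:
        Y = np.where(presence, Y, np.nan)
    resp = pd.DataFrame(Y, columns=[f"F{j}" for j in range(nF)])
    pred = pd.DataFrame(Z, columns=[f"C{i}" for i in range(nC)])
    meta = pd.DataFrame({"treatment": np.where(heat > 0, "extreme_heat", "control")})
    return AssociationSubset("low", "spring", "H3", resp, pred, heat, meta)


class TestMakeSubsets:
    def test_study_scale_gives_6_subsets_of_20(self, study_scale_study):
        subsets = make_subsets(study_scale_study, harvest="H3")
        assert len(subsets) == 6
        assert all(s.n_samples == 20 for s in subsets)
        assert {(s.elevation, s.season) for s in subsets} == {
            (e, s) for e in ("high", "low") for s in ("spring", "summer", "autumn")
        }

    def test_single_season_design_gives_2_subsets(self):
        spec = DesignSpec(seasons=("spring",))
        cp = sh.default_collembola_params(spec)
        fp = sh.default_fungal_params(spec, n_taxa=12)
        ap = sh.AssociationParams.zeros(cp.species, fp.taxa)
        study = sh.simulate_study(cp, fp, ap, spec, seed=3)
        subsets = make_subsets(study, harvest="H3")
        assert len(subsets) == 2

    def test_subset_rows_equal_sites_times_plots_times_treatments(self):
        spec = DesignSpec(plots_per_site_season=3, seasons=("spring", "summer"))
        cp = sh.default_collembola_params(spec)
        fp = sh.default_fungal_params(spec, n_taxa=10)
        ap = sh.AssociationParams.zeros(cp.species, fp.taxa)
        study = sh.simulate_study(cp, fp, ap, spec, seed=4)
        for sub in make_subsets(study, harvest="H2"):
            assert sub.n_samples == 2 * 3 * 2  # sites x plots x treatments

    def test_low_prevalence_subset_skipped(self, study_scale_study):
        # wipe out Collembola in one elevation x season cell at H3
        study = study_scale_study
        units = study.units
        mask = (
            (units["harvest"] == "H3")
            & (units["elevation"] == "low")
            & (units["season"] == "summer")
        )
        counts = study.collembola.copy()
        counts.loc[mask] = 0
        import dataclasses

        crippled = dataclasses.replace(study, collembola=counts)
        subsets = make_subsets(crippled, harvest="H3")
        assert len(subsets) == 5
        assert ("low", "summer") not in {(s.elevation, s.season) for s in subsets}


class TestExtractNetwork:
    def test_ci_filter_sign_examples(self):
        # strong negative pair -> negative edge; noisy pair -> no edge
        D = np.zeros((3, 5))
        B = np.zeros((3, 5))
        B[0, 0] = -2.0
        sub = toy_subset(3, 5, beta=B, delta=D, sigma=0.5, seed=1)
        nets = extract_network(fit_association_model(sub))
        for treatment in ("control", "extreme_heat"):
            edges = nets[treatment].edges
            hit = edges[(edges.collembola == "C0") & (edges.fungus == "F0")]
            assert len(hit) == 1
            assert hit["sign"].iloc[0] == "negative"

    def test_edge_counts_match_bruteforce_recount(self):
        sub = toy_subset(4, 8, seed=2)
        res = fit_association_model(sub)
        tab = res.coefficient_table(0.95)
        for treatment in ("control", "extreme_heat"):
            sel = tab[tab.treatment == treatment]
            expected = int(((sel.ci_lo > 0) | (sel.ci_hi < 0)).sum())
            net = res.network(treatment, 0.95)
            assert net.n_edges() == expected

    def test_raising_ci_level_never_adds_edges(self):
        sub = toy_subset(5, 10, seed=3, beta=np.full((5, 10), 0.3))
        res = fit_association_model(sub)
        for treatment in ("control", "extreme_heat"):
            e95 = res.network(treatment, 0.95).edges
            e99 = res.network(treatment, 0.99).edges
            pairs95 = set(map(tuple, e95[["collembola", "fungus"]].to_numpy()))
            pairs99 = set(map(tuple, e99[["collembola", "fungus"]].to_numpy()))
            assert pairs99 <= pairs95


class TestConnectance:
    def _net(self, edges, nC=3, nF=5):
        frame = pd.DataFrame(edges, columns=["collembola", "fungus", "sign", "weight"])
        return SignedBipartiteNetwork(
            collembola=[f"C{i}" for i in range(nC)],
            fungi=[f"F{j}" for j in range(nF)],
            edges=frame,
            treatment="control",
        )

    def test_two_negative_edges_over_15_pairs(self):
        net = self._net([("C0", "F0", "negative", -1.0), ("C1", "F2", "negative", -0.5)])
        assert connectance(net, "negative") == pytest.approx(2 / 15)
        assert connectance(net, "positive") == 0.0

    def test_complete_single_sign_network(self):
        edges = [(f"C{i}", f"F{j}", "positive", 1.0) for i in range(3) for j in range(5)]
        assert connectance(self._net(edges), "positive") == 1.0

    def test_invariant_to_node_relabelling(self):
        edges = [("C0", "F0", "negative", -1.0), ("C2", "F4", "negative", -0.3)]
        net = self._net(edges)
        relabelled = self._net(
            [("C2", "F4", "negative", -0.3), ("C0", "F0", "negative", -1.0)]
        )
        assert connectance(net, "negative") == connectance(relabelled, "negative")

    def test_empty_node_set_rejected(self):
        net = SignedBipartiteNetwork([], ["F0"], pd.DataFrame(columns=["collembola", "fungus", "sign", "weight"]), "control")
        with pytest.raises(ValueError):
            connectance(net, "negative")


class TestNullModel:
    def test_identical_arms_give_zero_difference(self):
        # the same response/predictor rows in both arms: interactions vanish
        r = np.random.default_rng(5)
        half = r.normal(size=(10, 4))
        Z_half = r.normal(size=(10, 2))
        resp = pd.DataFrame(np.vstack([half, half]), columns=list("abcd"))
        pred = pd.DataFrame(np.vstack([Z_half, Z_half]), columns=["C0", "C1"])
        pred = (pred - pred.mean()) / pred.std(ddof=0)
        heat = np.array([0.0] * 10 + [1.0] * 10)
        meta = pd.DataFrame({"treatment": np.where(heat > 0, "extreme_heat", "control")})
        sub = AssociationSubset("low", "spring", "H3", resp, pred, heat, meta)
        res = fit_association_model(sub)
        signs_c = res.edge_signs("control")
        signs_h = res.edge_signs("extreme_heat")
        np.testing.assert_array_equal(signs_c, signs_h)

    def test_power_against_heat_only_associations(self):
        # four planted heat-only negative pairs among 15: the test should
        # reject in most replicates
        ps = []
        for s in range(20):
            D = np.zeros((3, 5))
            D[0, 0] = D[1, 1] = D[2, 2] = D[0, 3] = -2.0
            sub = toy_subset(3, 5, delta=D, seed=100 + s)
            nt = connectance_difference_test(sub, "negative", n_null=199, seed=s)
            ps.append(nt.p_value)
        assert np.median(ps) < 0.05

    def test_null_world_supported_edge_rate_near_nominal(self):
        # no associations anywhere: CI filtering should flag roughly 5% of
        # pair x treatment coefficients (shrinkage keeps it at or below)
        total, hits = 0, 0
        for s in range(10):
            sub = toy_subset(3, 10, seed=300 + s)
            res = fit_association_model(sub)
            for treatment in ("control", "extreme_heat"):
                signs = res.edge_signs(treatment)
                hits += int((signs != 0).sum())
                total += signs.size
        rate = hits / total
        assert 0.0 < rate <= 0.08

    def test_degenerate_null_distribution_flagged(self):
        resp = pd.DataFrame(np.zeros((20, 2)) + np.nan, columns=["a", "b"])
        resp.iloc[:6] = 0.0  # constant where present
        pred = pd.DataFrame(np.random.default_rng(6).normal(size=(20, 1)), columns=["C0"])
        heat = np.array([0, 1] * 10, float)
        meta = pd.DataFrame({"treatment": np.where(heat > 0, "extreme_heat", "control")})
        sub = AssociationSubset("low", "spring", "H3", resp, pred, heat, meta)
        with pytest.warns(UserWarning, match="zero spread"):
            nt = connectance_difference_test(sub, "negative", n_null=99, seed=1)
        assert nt.degenerate
        assert np.isnan(nt.z)
        assert 0 < nt.p_value <= 1

    def test_n_null_floor(self):
        sub = toy_subset(2, 3, seed=7)
        with pytest.raises(ValueError):
            connectance_difference_test(sub, "negative", n_null=10, seed=0)
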