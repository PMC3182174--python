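"""Peptide filtering, protein averaging, reference bridging, z-transform."""
import numpy as np
import pandas as pd
import pytest

from fatbody import (
    Comparison,
    Design,
    RatioExperiment,
    SimConfig,
    bridge_to_reference,
    filter_peptides,
    peptides_to_protein,
    presence_filter,
    simulate_ratio_experiment,
    z_transform,
)
from fatbody.label_quant import PEPTIDE_COLUMNS, RATIO_COLUMNS


def peptide_frame(rows):
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def ratio_frame(rows):
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)


class TestFilterPeptides:
    def test_boundary_is_kept_strictly_above_removed(self):
        df = peptide_frame(
            [
                ("c1", "A", "ref", "P1", "pep1", 0.5, 5.0),
                ("c1", "A", "ref", "P1", "pep2", 0.5, 5.1),
                ("c1", "A", "ref", "P1", "pep3", 0.5, -5.0),
                ("c1", "A", "ref", "P1", "pep4", 0.5, -5.2),
            ]
        )
        kept = filter_peptides(df)
        assert list(kept["peptide"]) == ["pep1", "pep3"]
        assert kept.attrs["n_removed"] == 2

    def test_counts_on_constructed_set(self, rng):
        ppm = np.concatenate([rng.uniform(-4.9, 4.9, 83), rng.uniform(5.01, 9, 17)])
        rng.shuffle(ppm)
        df = peptide_frame(
            [("c1", "A", "ref", "P1", f"pep{i}", 0.0, ppm[i]) for i in range(100)]
        )
        assert len(filter_peptides(df)) == 83


class TestPeptidesToProtein:
    def test_mean_of_peptide_ratios(self):
        df = peptide_frame(
            [
                ("c1", "A", "ref", "P1", "p1", 0.0, 0.0),
                ("c1", "A", "ref", "P1", "p2", 2.0, 0.0),
                ("c1", "A", "ref", "P2", "q1", 1.0, 0.0),
                ("c1", "A", "ref", "P2", "q2", 1.0, 0.0),
                ("c1", "A", "ref", "P2", "q3", 1.0, 0.0),
            ]
        )
        out = peptides_to_protein(df).set_index("protein")
        assert out.at["P1", "log2_ratio"] == 1.0
        assert out.at["P2", "log2_ratio"] == 1.0
        assert out.at["P2", "n_peptides"] == 3

    def test_single_peptide_protein_eliminated(self):
        df = peptide_frame(
            [
                ("c1", "A", "ref", "P1", "only", 1.0, 0.0),
                ("c1", "A", "ref", "P2", "q1", 1.0, 0.0),
                ("c1", "A", "ref", "P2", "q2", 1.0, 0.0),
            ]
        )
        out = peptides_to_protein(df)
        assert set(out["protein"]) == {"P2"}

    def test_matches_independent_mean(self, rng):
        rows = []
        for c in range(10):
            for k in range(rng.integers(2, 6)):
                rows.append((f"c{c}", "A", "ref", "P", f"pep{c}_{k}", rng.normal(), 0.0))
        df = peptide_frame(rows)
        out = peptides_to_protein(df).set_index("comparison")
        for c, sub in df.groupby("comparison"):
            assert out.at[c, "log2_ratio"] == pytest.approx(sub["log2_ratio"].mean())


def build_experiment(edge_rows, comparisons, refs):
    return RatioExperiment(
        comparisons=comparisons,
        ratios=ratio_frame(edge_rows),
        reference_samples=refs,
    )


class TestBridging:
    def test_direct_edge(self):
        exp = build_experiment(
            [("c1", "A", "ref", "P1", 1.0, 2)],
            [Comparison("c1", ("ref", "A"))],
            ["ref"],
        )
        out = bridge_to_reference(exp)
        assert out.values.at["P1", "A"] == pytest.approx(1.0)
        assert out.values.at["P1", "ref"] == 0.0

    def test_chain_additivity_in_log_space(self):
        exp = build_experiment(
            [
                ("c1", "A", "B", "P1", 1.0, 2),
                ("c2", "B", "ref", "P1", 2.0, 2),
            ],
            [Comparison("c1", ("B", "A")), Comparison("c2", ("ref", "B"))],
            ["ref"],
        )
        out = bridge_to_reference(exp)
        assert out.values.at["P1", "A"] == pytest.approx(3.0)

    def test_inconsistent_triangle_matches_normal_equations(self):
        # edges: A-B = 1, B-ref = 1, A-ref = 2.3 with unit weights
        exp = build_experiment(
            [
                ("c1", "A", "B", "P1", 1.0, 1),
                ("c2", "B", "ref", "P1", 1.0, 1),
                ("c3", "A", "ref", "P1", 2.3, 1),
            ],
            [
                Comparison("c1", ("B", "A")),
                Comparison("c2", ("ref", "B")),
                Comparison("c3", ("ref", "A")),
            ],
            ["ref"],
        )
        out = bridge_to_reference(exp, weights="unit")
        # unknowns (A, B); rows: A-B=1, B=1, A=2.3
        a = np.array([[1.0, -1.0], [0.0, 1.0], [1.0, 0.0]])
        b = np.array([1.0, 1.0, 2.3])
        sol = np.linalg.solve(a.T @ a, a.T @ b)
        assert out.values.at["P1", "A"] == pytest.approx(sol[0], abs=1e-12)
        assert out.values.at["P1", "B"] == pytest.approx(sol[1], abs=1e-12)

    def test_unbridged_component_marked_absent(self):
        exp = build_experiment(
            [
                ("c1", "A", "ref", "P1", 1.0, 2),
                ("c2", "X", "Y", "P1", 0.5, 2),
            ],
            [Comparison("c1", ("ref", "A")), Comparison("c2", ("Y", "X"))],
            ["ref"],
        )
        out = bridge_to_reference(exp)
        assert np.isnan(out.values.at["P1", "X"])
        assert ("P1", "X") in out.unbridged and ("P1", "Y") in out.unbridged

    def test_noise_free_simulation_recovered_exactly(self):
        cfg = SimConfig(seed=20, n_proteins=25, n_replicates=3, ratio_sd=0.0, missing_rate=0.0)
        exp, _, truth = simulate_ratio_experiment(cfg)
        out = bridge_to_reference(exp)
        sv = truth.sample_values.loc[out.values.index, out.values.columns]
        assert np.nanmax(np.abs(out.values.to_numpy() - sv.to_numpy())) < 1e-10

    def test_spanning_trees_agree_on_consistent_data(self):
        # consistent values: A=1, B=2, C=3 relative to ref
        edges_t1 = [
            ("c1", "A", "ref", "P1", 1.0, 2),
            ("c2", "B", "A", "P1", 1.0, 2),
            ("c3", "C", "B", "P1", 1.0, 2),
        ]
        comps_t1 = [
            Comparison("c1", ("ref", "A")),
            Comparison("c2", ("A", "B")),
            Comparison("c3", ("B", "C")),
        ]
        edges_t2 = [
            ("d1", "A", "ref", "P1", 1.0, 2),
            ("d2", "B", "ref", "P1", 2.0, 2),
            ("d3", "C", "ref", "P1", 3.0, 2),
        ]
        comps_t2 = [
            Comparison("d1", ("ref", "A")),
            Comparison("d2", ("ref", "B")),
            Comparison("d3", ("ref", "C")),
        ]
        v1 = bridge_to_reference(build_experiment(edges_t1, comps_t1, ["ref"])).values
        v2 = bridge_to_reference(build_experiment(edges_t2, comps_t2, ["ref"])).values
        pd.testing.assert_frame_equal(v1[["A", "B", "C", "ref"]], v2[["A", "B", "C", "ref"]])


class TestZTransform:
    def test_simple_example(self):
        z, constant = z_transform(pd.DataFrame([[1.0, 2.0, 3.0]], index=["P"]))
        assert list(z.loc["P"]) == [-1.0, 0.0, 1.0]
        assert not constant.loc["P"]

    def test_constant_flagged_and_excluded(self):
        z, constant = z_transform(pd.DataFrame([[2.0, 2.0, 2.0]], index=["P"]))
        assert constant.loc["P"]
        assert z.loc["P"].isna().all()

    def test_mean_zero_unit_sd(self, rng):
        values = pd.DataFrame(rng.normal(size=(30, 8)))
        z, constant = z_transform(values)
        assert not constant.any()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestPresenceFilter:
    def _design(self):
        return Design.from_groups(n_replicates=4, ages=(7, 9, 11))

    def test_one_group_suffices(self):
        d = self._design()
        cols = d.samples_in_group("CL", 9) + d.samples_in_group("CL", 11)
        row = [1.0, 1.0, 1.0, np.nan] + [1.0, np.nan, np.nan, np.nan]
        values = pd.DataFrame([row], index=["P"], columns=cols)
        elig = presence_filter(values, d, groups=[("CL", 9), ("CL", 11)])
        assert elig.loc["P", ("CL", 9)]
        assert not elig.loc["P", ("CL", 11)]
        assert elig.loc["P"].any()

    def test_two_of_four_everywhere_ineligible(self):
        d = self._design()
        cols = d.samples_in_group("CL", 9) + d.samples_in_group("CL", 11)
        row = [1.0, 1.0, np.nan, np.nan] * 2
        values = pd.DataFrame([row], index=["P"], columns=cols)
        elig = presence_filter(values, d, groups=[("CL", 9), ("CL", 11)])
        assert not elig.loc["P"].any()

    def test_eligibility_matches_binomial_expectation(self):
        cfg = SimConfig(seed=21, n_proteins=2000, n_replicates=4, missing_rate=0.25)
        exp, d, _ = simulate_ratio_experiment(cfg)
        from fatbody import bridge_to_reference

        out = bridge_to_reference(exp)
        elig = presence_filter(out.values, d, min_present=3, groups=[("CL", 9), ("CL", 11)])
        # per cell: 4 replicates present independently; an age-9 value needs
        # only its own triplex run, so presence ~ Bernoulli(1 - 0.25)
        p_keep = 0.75
        p_cell = p_keep**4 + 4 * p_keep**3 * 0.25
        frac = elig[("CL", 9)].mean()
        sd = np.sqrt(p_cell * (1 - p_cell) / 2000)
        assert abs(frac - p_cell) < 4 * sd
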