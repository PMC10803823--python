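import numpy as np
import pandas as pd
import pytest

from bvitpath import complement as comp
from bvitpath import simulate as sim
from bvitpath import taxa
from bvitpath.catalog import default_pathway_definitions


def two_group_scenario(seed, n=100, cores=(), n_species=100):
    return sim.CohortScenario(
        groups=(sim.GroupSpec("A", n), sim.GroupSpec("B", n)),
        n_species=n_species,
        core_species=tuple(cores),
        seed=seed,
    )


class TestCohort:
    def test_determinism(self):
        sc = two_group_scenario(5, n=20, n_species=40)
        t1, g1 = sim.simulate_cohort(sc)
        t2, g2 = sim.simulate_cohort(sc)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_full_prevalence_species_always_present(self):
        core = sim.CoreSpeciesSpec("Always here", 0.01, 1.0)
        table, truth = sim.simulate_cohort(two_group_scenario(3, n=50, cores=[core]))
        assert (table.values.loc["Always here"] > 0).all()
        assert truth.table.loc["Always here", "realized_prevalence"] == 1.0

    def test_prevalence_concentrates_at_target(self):
        core = sim.CoreSpeciesSpec("Half timer", 0.01, 0.5)
        sc = two_group_scenario(7, n=1000, cores=[core], n_species=30)
        _, truth = sim.simulate_cohort(sc)
        assert truth.table.loc["Half timer", "realized_prevalence"] == pytest.approx(
            0.5, abs=0.03
        )

    def test_group_effects_shift_prevalence_and_abundance(self):
        core = sim.CoreSpeciesSpec("Shifty sp", 0.01, 0.4)
        sc = sim.CohortScenario(
            groups=(sim.GroupSpec("A", 400), sim.GroupSpec("B", 400)),
            n_species=50,
            core_species=(core,),
            group_effects=(
                sim.GroupEffect("Shifty sp", "B", prevalence_shift=0.4,
                                abundance_fold=4.0),
            ),
            seed=11,
        )
        table, _ = sim.simulate_cohort(sc)
        a_cols = [c for c in table.values.columns if c.startswith("A_")]
        b_cols = [c for c in table.values.columns if c.startswith("B_")]
        row = table.values.loc["Shifty sp"]
        prev_a = (row[a_cols] > 0).mean()
        prev_b = (row[b_cols] > 0).mean()
        assert prev_b - prev_a == pytest.approx(0.4, abs=0.08)
        mean_a = row[a_cols][row[a_cols] > 0].mean()
        mean_b = row[b_cols][row[b_cols] > 0].mean()
        assert mean_b / mean_a == pytest.approx(4.0, rel=0.3)

    def test_metadata_carried(self):
        sc = sim.default_cohort_scenario(0)
        table, _ = sim.simulate_cohort(sc)
        assert set(table.sample_metadata["cohort"]) == {"Bhopal", "Kasargod", "Tribal"}
        assert len(table.sample_metadata) == 141

    def test_background_is_heavy_tailed(self):
        table, truth = sim.simulate_cohort(two_group_scenario(1, n=100, n_species=300))
        bg = truth.table[~truth.table.planted]
        # most background species are rare and sparse
        assert (bg.realized_prevalence < 0.25).mean() > 0.5
        rel = taxa.to_relative(table)
        mras = [taxa.mean_relative_abundance(rel, s) for s in bg.index]
        g1, p = taxa.skewness_test(mras, n_boot=500, seed=0)
        assert g1 > 1 and p < 0.05


class TestEndToEndRecovery:
    def test_core_selection_recovers_planted_species(self):
        keep = [
            sim.CoreSpeciesSpec(f"Keep sp{i}", 0.002 * (i + 1), 0.6 + 0.05 * i)
            for i in range(4)
        ]
        reject = [
            sim.CoreSpeciesSpec(f"Reject sp{i}", 0.0004, 0.2) for i in range(3)
        ]
        for seed in range(3):
            sc = sim.CohortScenario(
                groups=(sim.GroupSpec("A", 200), sim.GroupSpec("B", 200)),
                n_species=300,
                core_species=tuple(keep + reject),
                seed=seed,
            )
            table, _ = sim.simulate_cohort(sc)
            rel = taxa.to_relative(table)
            results = taxa.select_core_biosynthesizers(
                rel, {c.name for c in keep + reject}
            )
            selected = {r.species for r in results if r.selected}
            assert selected == {c.name for c in keep}


class TestMagCommunity:
    @pytest.fixture
    def defs(self):
        return default_pathway_definitions()

    def enumerate_all(self, records, gene_sets, defs, samples):
        by_id = {g.mag_id: g for g in gene_sets}
        pairs = []
        for s in samples:
            ids = comp.mags_in_sample(records, s)
            mags = [by_id[i] for i in ids]
            for d in defs:
                pairs.extend(comp.enumerate_complementary_pairs(mags, d, s))
        return pairs

    def test_planted_pairs_recovered_exactly(self, defs):
        scenario = sim.default_mag_scenario(defs, seed=4, k_pairs=5,
                                            n_samples=3, n_background_mags=10)
        records, gene_sets, truth = sim.simulate_mag_community(scenario)
        kept = comp.filter_mags(records)
        assert len(kept) == len(records)  # default qualities pass the gate
        pairs = self.enumerate_all(kept, gene_sets, defs, ["S000", "S001", "S002"])
        strict = {(p.vitamin_code, p.mag_a, p.mag_b) for p in pairs if p.strict}
        loose = {(p.vitamin_code, p.mag_a, p.mag_b) for p in pairs if not p.strict}
        assert strict == set(truth.planted)
        assert loose == set()

    def test_full_retention_saturates(self, defs):
        scenario = sim.MagScenario(
            n_samples=1, n_background_mags=6, pathway_defs=tuple(defs),
            background_retention=1.0, seed=9,
        )
        records, gene_sets, _ = sim.simulate_mag_community(scenario)
        for d in defs:
            for g in gene_sets:
                assert comp.pathway_completeness(g, d) == 1.0
            pairs = comp.enumerate_complementary_pairs(gene_sets, d, "S000")
            assert len(pairs) == 6 * 5 // 2
            assert not any(p.strict for p in pairs)

    def test_quality_injection_is_filtered(self, defs):
        scenario = sim.MagScenario(
            n_samples=1, n_background_mags=4, pathway_defs=tuple(defs),
            quality_overrides={"mag_000": (95.0, 6.0)}, seed=2,
        )
        records, _, _ = sim.simulate_mag_community(scenario)
        kept_ids = {r.mag_id for r in comp.filter_mags(records)}
        assert "mag_000" not in kept_ids
        assert len(kept_ids) == 3

    def test_coverage_mask(self, defs):
        scenario = sim.MagScenario(
            n_samples=2, n_background_mags=3, pathway_defs=tuple(defs),
            coverage_mask=frozenset({("mag_001", "S000")}), seed=2,
        )
        records, _, _ = sim.simulate_mag_community(scenario)
        assert "mag_001" not in comp.mags_in_sample(records, "S000")
        assert "mag_001" in comp.mags_in_sample(records, "S001")

    def test_transporters_assigned_consistently(self, defs):
        from bvitpath.catalog import default_transporters, get_pathway

        scenario = sim.default_mag_scenario(defs, seed=6, k_pairs=8,
                                            n_samples=1, n_background_mags=10,
                                            background_retention=0.5)
        _, gene_sets, _ = sim.simulate_mag_community(scenario)
        b5 = get_pathway(defs, "B5")
        trans = default_transporters()
        saw_transporter = False
        for g in gene_sets:
            res = comp.transporter_consistency(g, b5, trans)
            assert all(v == "consistent" for v in res["flags"].values())
            saw_transporter = saw_transporter or bool(res["flags"])
        assert saw_transporter

    def test_non_disjoint_partition_rejected(self, defs):
        d = defs[0]
        with pytest.raises(ValueError, match="disjoint"):
            sim.MagScenario(
                n_samples=1, n_background_mags=0, pathway_defs=tuple(defs),
                planted_pairs=(
                    sim.PlantedPair(d.vitamin_code, d.gene_refs[:3], d.gene_refs[2:]),
                ),
            )

    def test_undersized_partition_rejected(self, defs):
        d = defs[0]  # threshold 1.0: dropping a gene breaks coverage
        with pytest.raises(ValueError, match="threshold"):
            sim.MagScenario(
                n_samples=1, n_background_mags=0, pathway_defs=tuple(defs),
                planted_pairs=(
                    sim.PlantedPair(d.vitamin_code, d.gene_refs[:3], d.gene_refs[4:]),
                ),
            )

    def test_determinism(self, defs):
        scenario = sim.default_mag_scenario(defs, seed=13, k_pairs=3)
        r1, g1, _ = sim.simulate_mag_community(scenario)
        r2, g2, _ = sim.simulate_mag_community(scenario)
        assert r1 == r2 and g1 == g2


class TestPlantPairs:
    def test_requested_count_and_safety(self):
        defs = default_pathway_definitions()
        for k in (1, 4, 10):
            pairs = sim.plant_pairs(defs, k)
            assert len(pairs) == k
            # scenario validation double-checks cross-pair safety
            sim.MagScenario(
                n_samples=1, n_background_mags=0, pathway_defs=tuple(defs),
                planted_pairs=pairs,
            )

    def test_infeasible_request_rejected(self):
        defs = default_pathway_definitions()[:1]
        with pytest.raises(ValueError, match="plant"):
            sim.plant_pairs(defs, 50)


class TestGeneCounts:
    def test_zero_abundance_gives_zero_counts(self, defs=None):
        defs = default_pathway_definitions()
        truth = pd.DataFrame(0.0, index=["s0", "s1"],
                             columns=[d.vitamin_code for d in defs])
        m = sim.simulate_gene_counts(defs, truth, seed=0)
        assert (m.counts.to_numpy() == 0).all()

    def test_poisson_concentration_recovers_abundance(self):
        from bvitpath.quant import pathway_abundance

        defs = default_pathway_definitions()
        lam = 1000.0
        truth = pd.DataFrame(lam, index=["s0"],
                             columns=[d.vitamin_code for d in defs])
        m = sim.simulate_gene_counts(defs, truth, seed=1)
        assignments = sim.identity_assignments(defs)
        for d in defs:
            prof = pathway_abundance(m, assignments, d, "s0")
            assert abs(prof.abundance - lam) <= 3 * np.sqrt(lam)

    def test_negative_abundance_rejected(self):
        defs = default_pathway_definitions()
        truth = pd.DataFrame(-1.0, index=["s0"],
                             columns=[d.vitamin_code for d in defs])
        with pytest.raises(ValueError):
            sim.simulate_gene_counts(defs, truth)

    def test_determinism(self):
        defs = default_pathway_definitions()
        truth = pd.DataFrame(50.0, index=["s0"],
                             columns=[d.vitamin_code for d in defs])
        a = sim.simulate_gene_counts(defs, truth, seed=3)
        b = sim.simulate_gene_counts(defs, truth, seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestCuratedList:
    def test_truth_matches_summary(self):
        df, truth = sim.simulate_curated_list(seed=0)
        summary = taxa.summarize_curated_list(df)
        for key in ("n_species", "n_all_eight_vitamins", "n_computational_only",
                    "n_experimental_only", "n_both"):
            assert summary[key] == truth[key], key
        assert summary["share_all_eight_vitamins"] == pytest.approx(
            truth["share_all_eight_vitamins"]
        )

    def test_strain_rows_present(self):
        df, truth = sim.simulate_curated_list(seed=1)
        assert truth["n_rows"] > truth["n_species"]
        assert df["species"].str.contains("str\\.").any()
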