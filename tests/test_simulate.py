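import numpy as np
import pandas as pd
import pytest

from gnrhtraj.io import STAGES, GeneSetCollection, validate_variants
from gnrhtraj.simulate import (
    FILTER_NAMES,
    SimulationParams,
    code_to_tuple,
    simulate_counts,
    simulate_lr_pairs,
    simulate_trait_list,
    simulate_variants,
)
from gnrhtraj.burden import FilterConfig, filter_variants
from gnrhtraj.ccc import stage_profiles


def _stage_means(m, fraction="GFP+"):
    frac = m.subset_samples(m.fraction_mask(fraction))
    labels = frac.samples["stage"].astype(str).to_numpy()
    return np.column_stack(
        [frac.counts[:, labels == s].mean(axis=1) for s in STAGES]
    )


class TestCounts:
    def test_same_seed_is_bit_identical(self):
        p = SimulationParams(seed=1, n_genes=200)
        m1, _ = simulate_counts(p, trajectory_mix={"+0-": 20})
        m2, _ = simulate_counts(p, trajectory_mix={"+0-": 20})
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_flat_simulation_ratios_concentrate_near_one(self):
        p = SimulationParams(seed=2, n_genes=500)
        m, truth = simulate_counts(p, trajectory_mix={})
        assert all(c == "000" for c in truth.gene_codes.values())
        means = _stage_means(m)
        keep = means.min(axis=1) > 20  # ratios of tiny means are noise-dominated
        ratios = means[keep, 1:] / means[keep, :-1]
        assert abs(np.median(ratios) - 1.0) < 0.1

    def test_planted_fold_is_realized(self):
        # library_size_cv = 0 so raw stage-mean ratios are not confounded by
        # per-sample depth factors
        p = SimulationParams(seed=3, n_genes=1000, library_size_cv=0.0)
        m, truth = simulate_counts(p, trajectory_mix={"+00": 20})
        means = _stage_means(m)
        planted = [m.genes.index(g) for g in truth.planted_genes()]
        realized = means[planted, 1] / means[planted, 0]
        assert abs(np.mean(realized) - p.planted_fold) < 0.25

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(SimulationParams(seed=0, n_genes=10), {"++": 2})
        with pytest.raises(ValueError, match="flat code"):
            simulate_counts(SimulationParams(seed=0, n_genes=10), {"000": 2})

    def test_mix_larger_than_gene_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_counts(SimulationParams(seed=0, n_genes=10), {"+00": 11})

    def test_empirical_dispersion_matches_nominal(self):
        # generative faithfulness: 1000 flat genes x 8 replicates per cell
        p = SimulationParams(
            seed=4, n_genes=1000, replicates_per_condition=8, library_size_cv=0.0
        )
        m, _ = simulate_counts(p, trajectory_mix={})
        frac = m.subset_samples(m.fraction_mask("GFP+"))
        labels = frac.samples["stage"].astype(str).to_numpy()
        num = np.zeros(m.n_genes)
        den = np.zeros(m.n_genes)
        for s in STAGES:
            y = frac.counts[:, labels == s]
            mu, v = y.mean(axis=1), y.var(axis=1, ddof=1)
            ok = mu > 30
            num[ok] += (v - mu)[ok] / mu[ok] ** 2 * 7
            den[ok] += 7
        phi = num[den > 0] / den[den > 0]
        assert abs(np.mean(phi) - p.dispersion) / p.dispersion < 0.2


class TestLigandReceptorPairs:
    def test_planted_classes_reach_extreme_strengths(self, study):
        pairs, m = study["pairs"], study["matrix"]
        lig = stage_profiles(m, "GFP-")
        rec = stage_profiles(m, "GFP+")
        strengths = {
            cls: [
                float(lig.profiles.loc[r.ligand] @ rec.profiles.loc[r.receptor])
                for r in pairs[pairs.planted_class == cls].itertuples()
            ]
            for cls in ("parallel", "anti-parallel")
        }
        assert np.mean(strengths["parallel"]) > 0.8
        assert np.mean(strengths["anti-parallel"]) < -0.8

    def test_independent_pairs_center_at_zero_across_seeds(self):
        # Monte Carlo over seeds: per-seed means are correlated through the
        # shared stage noise, so only the across-seed average should vanish.
        means = []
        for seed in range(200):
            p = SimulationParams(seed=seed, n_genes=120)
            m, truth = simulate_counts(p, trajectory_mix={"+00": 10, "0-0": 10})
            pairs, m = simulate_lr_pairs(
                m, truth, p, n_pairs=10, parallel_fraction=0.0, anti_fraction=0.0
            )
            lig = stage_profiles(m, "GFP-")
            rec = stage_profiles(m, "GFP+")
            means.append(
                np.mean(
                    [
                        float(lig.profiles.loc[r.ligand] @ rec.profiles.loc[r.receptor])
                        for r in pairs.itertuples()
                    ]
                )
            )
        assert abs(np.mean(means)) < 0.1

    def test_too_many_pairs_rejected(self):
        p = SimulationParams(seed=0, n_genes=50)
        m, truth = simulate_counts(p, trajectory_mix={"+00": 5})
        with pytest.raises(ValueError, match="exceeds"):
            simulate_lr_pairs(m, truth, p, n_pairs=6, ligands_per_receptor=1)


class TestVariants:
    def test_same_seed_identical(self, trajectory_sets):
        v1, _ = simulate_variants(trajectory_sets, {"T00": 5.0}, seed=7)
        v2, _ = simulate_variants(trajectory_sets, {"T00": 5.0}, seed=7)
        pd.testing.assert_frame_equal(v1, v2)

    def test_null_or_gives_equal_carrier_rates(self, trajectory_sets):
        rates_case, rates_ctrl = [], []
        for seed in range(30):
            _, truth = simulate_variants(
                trajectory_sets, {}, n_cases=4000, n_controls=4000,
                base_carrier_rate=0.02, seed=seed,
            )
            t = truth.variant_truth
            rates_case.append(t["case_carriers"].mean() / 4000)
            rates_ctrl.append(t["control_carriers"].mean() / 4000)
        assert abs(np.mean(rates_case) - np.mean(rates_ctrl)) < 0.002

    def test_decoys_cover_filter_vocabulary_and_fail_exactly_one(self, trajectory_sets):
        v, _ = simulate_variants(
            trajectory_sets, {"T00": 3.0}, n_cases=400, n_controls=5000,
            qc_fail_fraction=1.0, seed=1,
        )
        v = validate_variants(v)
        decoys = v[v.variant_id.str.startswith("decoy")]
        passing = v[~v.variant_id.str.startswith("decoy")]
        assert len(decoys) == len(passing)
        violated = {d.split("_", 2)[2] for d in decoys.variant_id}
        assert violated == set(FILTER_NAMES)
        cfg = FilterConfig()
        for vclass in ("PTV", "synonymous"):
            kept = filter_variants(v, cfg, vclass)
            assert not kept.variant_id.str.startswith("decoy").any()
        # each decoy passes again once its single violated filter is disabled
        relax = {
            "popmax": {"popmax_max": 1.0}, "qual": {"qual_min": -1e9},
            "mq": {"mq_min": -1e9}, "mq_rank_sum": {"mqrs_min": -1e9},
            "ad_ratio": {"ad_ratio_min": 0.0}, "segdup": {"exclude_segdup": False},
            "local_db": {"local_db_max": 10**9}, "pedigree": {"pedigree_max": 10**9},
            "flagged": {"exclude_flagged": False}, "indel_len": {"indel_len_max": 10**9},
        }
        for name, override in relax.items():
            loose = FilterConfig(**override)
            kept = pd.concat(
                [filter_variants(v, loose, vc) for vc in ("PTV", "synonymous")]
            )
            decoy_kept = kept[kept.variant_id.str.startswith("decoy")]
            expected = decoys[decoys.variant_id.str.contains(f"_{name}$")]
            assert set(decoy_kept.variant_id) == set(expected.variant_id)

    def test_case_rate_solves_the_planted_odds_ratio(self):
        from gnrhtraj.simulate import _case_rate_for_or

        p1 = _case_rate_for_or(8.0, 0.01)
        odds0, odds1 = 0.01 / 0.99, p1 / (1 - p1)
        assert odds1 / odds0 == pytest.approx(8.0, rel=1e-12)
        assert 0 < p1 < 1

    def test_degenerate_base_rate_rejected(self, trajectory_sets):
        with pytest.raises(ValueError):
            simulate_variants(trajectory_sets, {"T00": 2.0}, base_carrier_rate=1.0, seed=0)

    def test_unknown_set_rejected(self, trajectory_sets):
        with pytest.raises(ValueError, match="unknown sets"):
            simulate_variants(trajectory_sets, {"nope": 2.0}, seed=0)


class TestTraitList:
    def test_zero_overlap_is_disjoint_from_all_sets(self, trajectory_sets):
        background = {f"BG{i}" for i in range(500)} | trajectory_sets.all_genes()
        lst = simulate_trait_list(trajectory_sets, "T00", 0.0, 50, background, seed=0)
        assert len(lst) == 50
        assert not set(lst) & trajectory_sets.all_genes()

    def test_full_overlap_equals_the_set(self, trajectory_sets):
        background = {f"BG{i}" for i in range(500)} | trajectory_sets.all_genes()
        size = len(trajectory_sets["T00"])
        lst = simulate_trait_list(trajectory_sets, "T00", 1.0, size, background, seed=0)
        assert set(lst) == trajectory_sets["T00"]

    def test_background_too_small_rejected(self, trajectory_sets):
        with pytest.raises(ValueError, match="background"):
            simulate_trait_list(trajectory_sets, "T00", 0.5, 50, {"A", "B"}, seed=0)


def test_code_parsing_rejects_garbage():
    assert code_to_tuple("+0-") == (1, 0, -1)
    for bad in ("++", "ab c", "+0x"):
        with pytest.raises(ValueError):
            code_to_tuple(bad)
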