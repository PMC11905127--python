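import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_one_sided_p
from gnrhtraj.io import GeneSetCollection, validate_variants
from gnrhtraj.burden import (
    BurdenResult,
    ContingencyTable,
    FilterConfig,
    build_contingency,
    compare_or_z,
    filter_variants,
    fisher_or_ci,
    log_or_se,
    one_sided_fisher_p,
    run_burden,
)
from gnrhtraj.simulate import simulate_variants


def _passing_row(variant_id, consequence="stop_gain", cohort="case", subject="P1",
                 gene="ANOS1", **overrides):
    row = {
        "variant_id": variant_id, "gene": gene, "cohort": cohort,
        "subject_id": subject, "consequence": consequence,
        "popmax_af": 5e-5, "qual": 80.0, "mq": 60.0, "mq_rank_sum": 0.0,
        "ad_ratio": 0.45, "in_segdup": False, "local_db_count": 1,
        "pedigree_count": 2, "flagged_control_db": False, "indel_len": 0,
        "allele_count": 1, "spliceai_score": np.nan,
    }
    row.update(overrides)
    return row


VIOLATIONS = {
    "popmax": {"popmax_af": 2e-4},
    "qual": {"qual": 30.0},
    "mq": {"mq": 40.0},
    "mq_rank_sum": {"mq_rank_sum": -5.0},
    "ad_ratio": {"ad_ratio": 0.1},
    "segdup": {"in_segdup": True},
    "local_db": {"local_db_count": 5},
    "pedigree": {"pedigree_count": 7},
    "flagged": {"flagged_control_db": True},
    "indel_len": {"indel_len": 5, "consequence": "frameshift"},
}

RELAX = {
    "popmax": {"popmax_max": 1.0},
    "qual": {"qual_min": -1e9},
    "mq": {"mq_min": -1e9},
    "mq_rank_sum": {"mqrs_min": -1e9},
    "ad_ratio": {"ad_ratio_min": 0.0},
    "segdup": {"exclude_segdup": False},
    "local_db": {"local_db_max": 10**9},
    "pedigree": {"pedigree_max": 10**9},
    "flagged": {"exclude_flagged": False},
    "indel_len": {"indel_len_max": 10**9},
}


@pytest.fixture()
def cascade_fixture():
    """10 passing PTVs plus 10 decoys, each violating exactly one filter."""
    rows = [_passing_row(f"pass_{i}", subject=f"P{i}") for i in range(10)]
    for i, (name, bad) in enumerate(VIOLATIONS.items()):
        rows.append(_passing_row(f"decoy_{name}", subject=f"D{i}", **bad))
    return validate_variants(pd.DataFrame(rows))


class TestFilterCascade:
    def test_retains_exactly_the_passing_set(self, cascade_fixture):
        kept = filter_variants(cascade_fixture, FilterConfig(), "PTV")
        assert sorted(kept["variant_id"]) == sorted(f"pass_{i}" for i in range(10))

    @pytest.mark.parametrize("name", list(VIOLATIONS))
    def test_disabling_one_filter_readmits_exactly_its_decoy(self, cascade_fixture, name):
        kept = filter_variants(cascade_fixture, FilterConfig(**RELAX[name]), "PTV")
        assert len(kept) == 11
        assert f"decoy_{name}" in set(kept["variant_id"])

    def test_idempotent(self, cascade_fixture):
        cfg = FilterConfig()
        once = filter_variants(cascade_fixture, cfg, "PTV")
        twice = filter_variants(once, cfg, "PTV")
        pd.testing.assert_frame_equal(once, twice)

    def test_class_selection(self):
        rows = [
            _passing_row("syn", consequence="synonymous"),
            _passing_row("ptv", consequence="stop_gain"),
            _passing_row("sai_hi", consequence="spliceai_predicted", spliceai_score=0.9),
            _passing_row("sai_lo", consequence="spliceai_predicted", spliceai_score=0.2),
            _passing_row("sai_na", consequence="spliceai_predicted"),
            _passing_row("other", consequence="other"),
        ]
        v = validate_variants(pd.DataFrame(rows))
        ptv = set(filter_variants(v, FilterConfig(), "PTV")["variant_id"])
        syn = set(filter_variants(v, FilterConfig(), "synonymous")["variant_id"])
        assert ptv == {"ptv", "sai_hi"}
        assert syn == {"syn"}

    def test_missing_qc_value_fails_except_popmax(self):
        rows = [
            _passing_row("no_popmax", popmax_af=np.nan),
            _passing_row("no_qual", qual=np.nan),
        ]
        v = validate_variants(pd.DataFrame(rows))
        kept = set(filter_variants(v, FilterConfig(), "PTV")["variant_id"])
        assert kept == {"no_popmax"}

    def test_popmax_boundary(self):
        rows = [
            _passing_row("at", popmax_af=1e-4),
            _passing_row("above", popmax_af=2e-4),
        ]
        v = validate_variants(pd.DataFrame(rows))
        kept = set(filter_variants(v, FilterConfig(), "PTV")["variant_id"])
        assert kept == {"at"}

    def test_unknown_class_rejected(self, cascade_fixture):
        with pytest.raises(ValueError, match="variant class"):
            filter_variants(cascade_fixture, FilterConfig(), "missense")


class TestContingency:
    def test_subject_with_several_variants_counts_once(self):
        rows = [_passing_row(f"v{i}", subject="P1") for i in range(3)]
        rows.append(_passing_row("v9", subject="P2"))
        v = validate_variants(pd.DataFrame(rows))
        t = build_contingency(v, {"ANOS1"}, n_cases=100, n_controls=1000)
        assert (t.a, t.b) == (2, 98)

    def test_control_alleles_ceiling_at_n_controls(self):
        rows = [
            _passing_row("c1", cohort="control", subject=None, allele_count=40),
            _passing_row("c2", cohort="control", subject=None, allele_count=20),
        ]
        v = validate_variants(pd.DataFrame(rows))
        t = build_contingency(v, {"ANOS1"}, n_cases=100, n_controls=50)
        assert (t.c, t.d) == (50, 0)

    def test_no_passing_variants_gives_empty_margins(self):
        v = validate_variants(pd.DataFrame([_passing_row("v", gene="OTHER")]))
        t = build_contingency(v, {"ANOS1"}, n_cases=10, n_controls=20)
        assert (t.a, t.b, t.c, t.d) == (0, 10, 0, 20)

    def test_genes_outside_set_ignored(self):
        rows = [_passing_row("v1", gene="ANOS1"), _passing_row("v2", gene="FGFR1",
                subject="P2")]
        v = validate_variants(pd.DataFrame(rows))
        t = build_contingency(v, {"ANOS1"}, n_cases=10, n_controls=20)
        assert t.a == 1

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=2, c=3, d=4)


class TestFisherOrCi:
    def test_balanced_table_is_null(self):
        or_hat, lo, hi, p = fisher_or_ci(ContingencyTable(10, 10, 10, 10))
        assert or_hat == pytest.approx(1.0)
        assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-12)
        assert p > 0.5

    def test_zero_case_carriers_give_p_one(self):
        *_, p = fisher_or_ci(ContingencyTable(0, 100, 5, 995))
        assert p == 1.0

    def test_matches_bruteforce_tail_and_woolf_formula(self):
        t = ContingencyTable(5, 95, 10, 9990)
        or_hat, lo, hi, p = fisher_or_ci(t)
        assert p == pytest.approx(fisher_one_sided_p(5, 95, 10, 9990), rel=1e-12)
        expect_or = (5 * 9990) / (95 * 10)
        se = np.sqrt(1 / 5 + 1 / 95 + 1 / 10 + 1 / 9990)
        assert or_hat == pytest.approx(expect_or, rel=1e-12)
        assert lo == pytest.approx(np.exp(np.log(expect_or) - 1.96 * se), rel=1e-12)
        assert hi == pytest.approx(np.exp(np.log(expect_or) + 1.96 * se), rel=1e-12)

    def test_haldane_applied_only_with_zero_cells(self):
        t0 = ContingencyTable(0, 100, 5, 995)
        or_hat, lo, hi, p = fisher_or_ci(t0)
        prim = (0.5 * 995.5) / (100.5 * 5.5)
        assert or_hat == pytest.approx(prim, rel=1e-12)
        # exact test still uses the raw zero-cell table
        assert p == pytest.approx(fisher_one_sided_p(0, 100, 5, 995), rel=1e-12)
        # and no correction without zeros
        t1 = ContingencyTable(5, 95, 10, 9990)
        assert fisher_or_ci(t1)[0] == pytest.approx((5 * 9990) / (95 * 10), rel=1e-12)

    def test_agrees_with_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            ours = float(one_sided_fisher_p(a, b, c, d))
            ref = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            fisher_or_ci(ContingencyTable(0, 0, 5, 5))


def _result(a, b, c, d, name="T", vclass="PTV"):
    t = ContingencyTable(a, b, c, d)
    or_hat, lo, hi, p = fisher_or_ci(t)
    return BurdenResult(
        set_name=name, variant_class=vclass, table=t, or_hat=or_hat,
        ci_low=lo, ci_high=hi, fisher_p=p, log_se=log_or_se(t),
    )


class TestCompareOrZ:
    def test_identical_tables_give_zero(self):
        z, z_p = compare_or_z(_result(20, 380, 50, 49950),
                              _result(20, 380, 50, 49950, vclass="synonymous"))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert z_p == pytest.approx(0.5, abs=1e-12)

    def test_direct_arithmetic_example(self):
        z, z_p = compare_or_z(_result(20, 380, 50, 49950),
                              _result(5, 395, 50, 49950, vclass="synonymous"))
        or_p = (20 * 49950) / (380 * 50)
        or_s = (5 * 49950) / (395 * 50)
        se_p = np.sqrt(1 / 20 + 1 / 380 + 1 / 50 + 1 / 49950)
        se_s = np.sqrt(1 / 5 + 1 / 395 + 1 / 50 + 1 / 49950)
        expect = (np.log(or_p) - np.log(or_s)) / np.sqrt(se_p**2 + se_s**2)
        assert z == pytest.approx(expect, rel=1e-12)
        from scipy.stats import norm

        assert z_p == pytest.approx(norm.sf(expect), rel=1e-12)

    def test_swapping_classes_negates_z(self):
        ptv = _result(20, 380, 50, 49950)
        syn = _result(5, 395, 50, 49950, vclass="synonymous")
        z1, _ = compare_or_z(ptv, syn)
        z2, _ = compare_or_z(syn, ptv)
        assert z2 == pytest.approx(-z1, abs=1e-12)


class TestRunBurden:
    def test_empty_sets_give_empty_table(self):
        v = validate_variants(pd.DataFrame([_passing_row("v")]))
        out = run_burden(v, v.iloc[0:0], GeneSetCollection(), n_cases=10, n_controls=10)
        assert len(out) == 0

    def test_planted_or_recovered_and_nulls_quiet(self, trajectory_sets):
        hits, null_hits, covered = 0, 0, 0
        for seed in range(25):
            vt, _ = simulate_variants(
                trajectory_sets, {"T00": 8.0}, n_cases=400, n_controls=50000,
                base_carrier_rate=0.01, seed=seed,
            )
            vt = validate_variants(vt)
            res = run_burden(
                vt[vt.cohort == "case"], vt[vt.cohort == "control"],
                trajectory_sets, n_cases=400, n_controls=50000,
            )
            ptv = res[res["class"] == "PTV"].set_index("set")
            hits += bool(ptv.loc["T00", "retained"])
            covered += ptv.loc["T00", "ci_low"] <= 8.0 <= ptv.loc["T00", "ci_high"]
            null_hits += int(ptv.drop("T00")["retained"].sum())
        assert hits >= 23
        assert covered >= 22
        assert null_hits <= 5

    def test_synonymous_only_enrichment_never_retained(self, trajectory_sets):
        # negative control: the planted high OR is moved onto the synonymous
        # class by relabelling consequences, so the z gate must reject even
        # though the set's raw synonymous counts look enriched
        for seed in range(10):
            vt, _ = simulate_variants(
                trajectory_sets, {"T00": 8.0}, n_cases=400, n_controls=50000,
                base_carrier_rate=0.01, seed=seed,
            )
            was_syn = vt["consequence"] == "synonymous"
            was_ptv = vt["consequence"].isin(
                ["stop_gain", "frameshift", "splice_site", "spliceai_predicted"]
            )
            vt.loc[was_syn, "consequence"] = "stop_gain"
            vt.loc[was_ptv, "consequence"] = "synonymous"
            vt.loc[was_ptv, "indel_len"] = 0
            vt.loc[was_ptv, "spliceai_score"] = np.nan
            vt = validate_variants(vt)
            res = run_burden(
                vt[vt.cohort == "case"], vt[vt.cohort == "control"],
                trajectory_sets, n_cases=400, n_controls=50000,
            )
            assert not res[res["class"] == "PTV"]["retained"].any()

    def test_subphenotype_strata_are_reported(self, trajectory_sets):
        vt, _ = simulate_variants(
            trajectory_sets, {"T00": 6.0}, n_cases=400, n_controls=50000,
            base_carrier_rate=0.01, seed=3,
        )
        vt = validate_variants(vt)
        cases = vt[vt.cohort == "case"]
        labels = {f"CASE{i:05d}": ("KS" if i % 2 == 0 else "nCHH")
                  for i in range(400)}
        res = run_burden(
            cases, vt[vt.cohort == "control"], trajectory_sets,
            n_cases=400, n_controls=50000, subphenotypes=labels,
        )
        assert set(res["stratum"]) == {"all", "KS", "nCHH"}
        ks = res[(res.stratum == "KS") & (res["class"] == "PTV")].set_index("set")
        assert (ks["a"] + ks["b"] == 200).all()
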