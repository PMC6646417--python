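"""HLA covariates, scaling, logistic Wald fits and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from allopep.alloreactivity_scoring import MismatchEstimate
from allopep.association import (
    AssociationConfig,
    AssociationError,
    OutcomeRecord,
    PairCovariates,
    bh_adjust,
    build_design,
    compute_hla_covariates,
    count_hla_matches,
    fit_logistic_wald,
    run_association_suite,
    scale_center,
)

from conftest import make_typing


class TestCountHlaMatches:
    def test_identical_typings_give_twelve(self):
        assert count_hla_matches(make_typing("D"), make_typing("R")) == 12

    def test_one_allele_differs_gives_eleven(self):
        d = make_typing("D", A=("A*01:01", "A*03:01"))
        assert count_hla_matches(d, make_typing("R")) == 11

    def test_homozygous_vs_heterozygous_multiset(self):
        d = make_typing("D", A=("A*01:01", "A*01:01"))
        r = make_typing("R", A=("A*01:01", "A*02:01"))
        assert count_hla_matches(d, r) == 11  # the A locus contributes 1


class TestComputeHlaCovariates:
    def test_homozygous_everywhere_gives_six_unique(self):
        t = make_typing(
            "R",
            A=("A*01:01", "A*01:01"), B=("B*07:02", "B*07:02"),
            C=("C*04:01", "C*04:01"), DRB1=("DRB1*01:01", "DRB1*01:01"),
            DQB1=("DQB1*02:01", "DQB1*02:01"), DPB1=("DPB1*04:01", "DPB1*04:01"),
        )
        freq_sum, n_unique = compute_hla_covariates([t], t)
        assert n_unique == 6

    def test_cohort_of_one_freqs_all_one(self):
        t = make_typing("R")
        freq_sum, n_unique = compute_hla_covariates([t], t)
        assert freq_sum == pytest.approx(n_unique)
        assert n_unique == 12

    def test_three_recipient_hand_tabulated(self):
        # carrier counts done by hand over a 3-recipient toy cohort
        t1 = make_typing("R1")  # carries A*01:01 and A*02:01
        t2 = make_typing("R2", A=("A*01:01", "A*01:01"))
        t3 = make_typing("R3", A=("A*03:01", "A*24:02"))
        cohort = [t1, t2, t3]
        freq_sum, n_unique = compute_hla_covariates(cohort, t1)
        # A*01:01 in 2/3, A*02:01 in 1/3; the other ten alleles in all 3
        assert n_unique == 12
        assert freq_sum == pytest.approx(2 / 3 + 1 / 3 + 10 * 1.0)

    def test_allele_count_mode(self):
        t1 = make_typing("R1", A=("A*01:01", "A*02:01"))
        t2 = make_typing("R2", A=("A*01:01", "A*01:01"))
        freq_sum, _ = compute_hla_covariates([t1, t2], t2, mode="allele_count")
        # A*01:01 fills 3 of 24 allele slots; the other 10 loci alleles
        # carried by R2 each fill 2 or 4 of 24
        assert 0 < freq_sum < 12


class TestScaleCenter:
    def test_unit_spacing_already_scaled(self):
        assert scale_center([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_constant_raises(self):
        with pytest.raises(AssociationError, match="zero spread"):
            scale_center([5, 5, 5])

    def test_defining_property(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 7, size=40)
        z = scale_center(x)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def _sim_logistic(n, beta, seed, k_extra=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 1 + k_extra)),
        columns=["x0"] + [f"c{i}" for i in range(k_extra)],
    )
    eta = beta * X["x0"].to_numpy()
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return y.astype(float), X


class TestFitLogisticWald:
    def test_z_equals_estimate_over_se(self):
        y, X = _sim_logistic(200, 0.8, seed=1)
        table = fit_logistic_wald(y, X)
        assert np.allclose(
            table["z_value"], table["estimate"] / table["std_error"], atol=1e-10
        )

    def test_null_covariate_near_zero(self):
        y, X = _sim_logistic(4000, 0.0, seed=2)
        table = fit_logistic_wald(y, X)
        assert abs(table.loc["x0", "estimate"]) < 0.12

    def test_affine_rescaling_preserves_z_and_p(self):
        y, X = _sim_logistic(300, 0.7, seed=3)
        t1 = fit_logistic_wald(y, X)
        X2 = X.copy()
        X2["x0"] = 10 * X2["x0"] + 5
        t2 = fit_logistic_wald(y, X2)
        assert t2.loc["x0", "estimate"] == pytest.approx(
            t1.loc["x0", "estimate"] / 10, rel=1e-6
        )
        assert t2.loc["x0", "z_value"] == pytest.approx(
            t1.loc["x0", "z_value"], rel=1e-6
        )
        assert t2.loc["x0", "p_value"] == pytest.approx(
            t1.loc["x0", "p_value"], rel=1e-6
        )

    def test_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        X = pd.DataFrame({"x0": [-3, -2, -1, 1, 2, 3]})
        with pytest.raises(AssociationError):
            fit_logistic_wald(y, X)


class TestBhAdjust:
    def test_four_method_worked_example(self):
        # closed-form step-up on four nominal p-values
        adjusted = bh_adjust([0.00976, 0.0234, 0.0366, 0.36])
        assert adjusted == pytest.approx([0.03904, 0.0468, 0.0488, 0.36])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_output_dominates_input_and_max_preserved(self):
        rng = np.random.default_rng(9)
        p = rng.random(25)
        adj = np.array(bh_adjust(p))
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        assert adj[np.argmax(p)] == pytest.approx(p.max())

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _toy_cohort(n=120, beta=1.2, seed=5):
    rng = np.random.default_rng(seed)
    estimates, covariates, outcomes = [], {}, []
    counts = {m: rng.poisson(lam, size=n)
              for m, lam in zip(("m1", "m2", "m3", "m4"), (20, 6, 2, 4))}
    total = counts["m1"] + rng.poisson(300, size=n)
    filtered = counts["m2"] + rng.poisson(30, size=n)
    z = (counts["m1"] - counts["m1"].mean()) / counts["m1"].std(ddof=1)
    p_ext = 1 / (1 + np.exp(-(-0.2 + beta * z)))
    for i in range(n):
        pid = f"P{i:03d}"
        estimates.append(
            MismatchEstimate(
                pair_id=pid,
                m1=int(counts["m1"][i]),
                m2=int(min(counts["m2"][i], counts["m1"][i])),
                m3=int(counts["m3"][i]),
                m4=int(min(counts["m4"][i], filtered[i])),
                total_mismatched=int(total[i]),
                total_filtered=int(min(filtered[i], total[i])),
            )
        )
        covariates[pid] = PairCovariates(
            pair_id=pid,
            hla_freq_sum=float(rng.uniform(6, 12)),
            n_unique_hla=int(rng.integers(8, 13)),
            tr_year=float(rng.integers(2001, 2016)),
            donor_age=float(rng.uniform(20, 60)),
            f_to_m=bool(rng.random() < 0.2),
            hla_match_count=int(rng.choice([10, 11, 12], p=[0.1, 0.2, 0.7])),
        )
        grade = "limited" if rng.random() < 0.1 else (
            "extensive" if rng.random() < p_ext[i] else "no"
        )
        outcomes.append(
            OutcomeRecord(
                pair_id=pid, cgvhd_grade=grade,
                donor_age=covariates[pid].donor_age,
                tr_year=covariates[pid].tr_year,
                f_to_m=covariates[pid].f_to_m,
            )
        )
    return estimates, covariates, outcomes


class TestAssociationSuite:
    def test_limited_pairs_excluded_from_design(self):
        estimates, covariates, outcomes = _toy_cohort()
        est_by_pair = {e.pair_id: e for e in estimates}
        y, design = build_design(
            est_by_pair, covariates, outcomes, "m1", AssociationConfig()
        )
        n_limited = sum(o.cgvhd_grade == "limited" for o in outcomes)
        assert len(y) == len(outcomes) - n_limited

    def test_method_specific_mismatch_covariate(self):
        estimates, covariates, outcomes = _toy_cohort()
        est_by_pair = {e.pair_id: e for e in estimates}
        cfg = AssociationConfig()
        _, d1 = build_design(est_by_pair, covariates, outcomes, "m1", cfg)
        _, d2 = build_design(est_by_pair, covariates, outcomes, "m2", cfg)
        # m1 pairs with the raw mismatch total, m2 with the filtered total
        assert not np.allclose(
            d1["n_mismatched_peptides"], d2["n_mismatched_peptides"]
        )

    def test_planted_effect_recovered_with_consistent_direction(self):
        estimates, covariates, outcomes = _toy_cohort(beta=1.2, seed=6)
        result = run_association_suite(estimates, covariates, outcomes)
        assert not result.errors
        # the counts are correlated Poisson draws of the same pairs only
        # through m1; at least m1 itself must be strongly positive
        assert result.tables["m1"].loc["ligand_count", "estimate"] > 0
        assert result.ligand_p["m1"] < 0.01
        assert result.ligand_p_adjusted["m1"] >= result.ligand_p["m1"]

    def test_single_method_adjusted_equals_nominal(self):
        estimates, covariates, outcomes = _toy_cohort(seed=7)
        result = run_association_suite(
            estimates, covariates, outcomes,
            AssociationConfig(methods=("m1",)),
        )
        assert result.ligand_p_adjusted["m1"] == pytest.approx(
            result.ligand_p["m1"]
        )

    def test_single_outcome_class_reports_error(self):
        estimates, covariates, outcomes = _toy_cohort(seed=8)
        all_no = [
            OutcomeRecord(o.pair_id, "no", o.donor_age, o.tr_year, o.f_to_m)
            for o in outcomes
        ]
        result = run_association_suite(estimates, covariates, all_no)
        assert set(result.errors) == {"m1", "m2", "m3", "m4"}
        assert "one outcome class" in result.errors["m1"]

    def test_result_frame_shape(self):
        estimates, covariates, outcomes = _toy_cohort(seed=9)
        frame = run_association_suite(estimates, covariates, outcomes).to_frame()
        assert set(frame["method"]) == {"M1", "M2", "M3", "M4"}
        ligand_rows = frame[frame["variable"] == "ligand_count"]
        assert ligand_rows["p_adjusted"].notna().all()
        other_rows = frame[frame["variable"] != "ligand_count"]
        assert other_rows["p_adjusted"].isna().all()
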