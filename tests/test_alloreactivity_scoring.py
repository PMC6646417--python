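"""Immunogenicity scoring, expression filter, affinity ranks and M1-M4."""

import json
from importlib import resources as importlib_resources

import pytest

from allopep.alloreactivity_scoring import (
    AffinityConfig,
    ExpressionRecord,
    ImmunogenicityModel,
    PrecomputedRankTable,
    ScoringError,
    ToyPSSMPredictor,
    compute_method_counts,
    count_high_affinity,
    filter_by_expression,
    filter_by_immunogenicity,
    immunogenicity_score,
    predict_percentile_ranks,
)
from allopep.ligand_resources import LigandDatabase
from allopep.peptide_mismatch import MismatchedPeptide

from conftest import make_typing


def pep(seq, transcripts=("T1",), genes=("G1",)):
    return MismatchedPeptide(seq, frozenset(transcripts), frozenset(genes))


def flat_model(enrichment=1.0, weights=(1.0,) * 9, masked=(), threshold=0.2):
    return ImmunogenicityModel(
        residue_log_enrichment={aa: enrichment for aa in "ACDEFGHIKLMNPQRSTVWY"},
        position_weights=tuple(weights),
        masked_positions=frozenset(masked),
        threshold=threshold,
    )


class TestImmunogenicityScore:
    def test_homopolymer_closed_form(self):
        model = ImmunogenicityModel.load_default()
        e_w = model.residue_log_enrichment["W"]
        expected = e_w * sum(model.effective_weights)
        assert immunogenicity_score("W" * 9, model) == pytest.approx(expected)

    def test_all_zero_weights_give_zero(self):
        model = flat_model(weights=(0.0,) * 9)
        assert immunogenicity_score("ACDEFGHIK", model) == 0.0

    def test_fixed_peptide_hand_summed(self):
        # hand summation over the packaged v1.1 tables for AAGWKAAAA:
        # 0.1*e(G) + 0.31*e(W) + 0.30*e(K) + (0.29+0.26+0.18)*e(A)
        # = 0.1*0.110 + 0.31*0.719 + 0.30*(-0.700) + 0.73*0.127 = 0.11660
        model = ImmunogenicityModel.load_default()
        assert immunogenicity_score("AAGWKAAAA", model) == pytest.approx(
            0.11660, abs=1e-9
        )

    def test_masked_positions_contribute_zero(self):
        full = flat_model()
        masked = flat_model(masked=(1, 2, 9))
        assert immunogenicity_score("A" * 9, masked) == pytest.approx(
            immunogenicity_score("A" * 9, full) - 3.0
        )

    def test_linear_in_position_weights(self):
        model = ImmunogenicityModel.load_default()
        doubled = ImmunogenicityModel(
            residue_log_enrichment=model.residue_log_enrichment,
            position_weights=tuple(2 * w for w in model.position_weights),
            masked_positions=model.masked_positions,
        )
        for seq in ("AAGWKAAAA", "MKTAYIAKQ", "WWWWWWWWW"):
            assert immunogenicity_score(seq, doubled) == pytest.approx(
                2 * immunogenicity_score(seq, model)
            )

    def test_nonstandard_residue_raises(self):
        with pytest.raises(ScoringError):
            immunogenicity_score("AAAAXAAAA", ImmunogenicityModel.load_default())

    def test_length_mismatch_raises(self):
        with pytest.raises(ScoringError):
            immunogenicity_score("AAAA", ImmunogenicityModel.load_default())

    def test_packaged_table_complete(self):
        data = json.loads(
            importlib_resources.files("allopep.data")
            .joinpath("immunogenicity_v1_1.json")
            .read_text()
        )
        assert set(data["residue_log_enrichment"]) == set("ACDEFGHIKLMNPQRSTVWY")
        assert len(data["position_weights"]) == 9


class TestImmunogenicityFilter:
    def test_score_exactly_at_threshold_dropped(self):
        # one unmasked position of weight 1, enrichment 0.2 -> score 0.2
        model = flat_model(enrichment=0.2, weights=(1.0,) + (0.0,) * 8)
        assert filter_by_immunogenicity({pep("A" * 9)}, model) == set()

    def test_empty_input(self):
        assert filter_by_immunogenicity(set(), flat_model()) == set()

    def test_minus_infinite_threshold_is_identity(self):
        model = flat_model(threshold=float("-inf"))
        peps = {pep("A" * 9), pep("K" * 9)}
        assert filter_by_immunogenicity(peps, model) == peps


EXPR = [
    ExpressionRecord("G1", "skin", "Supportive"),
    ExpressionRecord("G2", "liver", "Uncertain"),
    ExpressionRecord("G3", "kidney", "Supportive"),  # wrong tissue
]


class TestExpressionFilter:
    def test_supportive_target_tissue_kept(self):
        assert filter_by_expression({pep("A" * 9, genes=("G1",))}, EXPR)

    def test_uncertain_only_dropped(self):
        assert filter_by_expression({pep("A" * 9, genes=("G2",))}, EXPR) == set()

    def test_wrong_tissue_dropped(self):
        assert filter_by_expression({pep("A" * 9, genes=("G3",))}, EXPR) == set()

    def test_any_source_gene_passing_keeps_peptide(self):
        p = pep("A" * 9, genes=("G2", "G1"))
        assert filter_by_expression({p}, EXPR) == {p}

    def test_transcript_level_override(self):
        # gene passes, but the transcript-level record says uncertain
        table = [
            ExpressionRecord("G1", "skin", "Supportive"),
            ExpressionRecord("G1", "skin", "Uncertain", transcript_id="T1"),
        ]
        p = pep("A" * 9, transcripts=("T1",), genes=("G1",))
        assert filter_by_expression({p}, table) == set()

    def test_empty_table_raises(self):
        with pytest.raises(ScoringError, match="empty expression table"):
            filter_by_expression({pep("A" * 9)}, [])


class TestPredictors:
    def test_precomputed_table_pass_through(self, tmp_path):
        path = tmp_path / "ranks.tsv"
        path.write_text(
            "peptide\tallele\tpercentile_rank\n"
            "AAAAAAAAA\tA*01:01\t3.5\n"
            "AAAAAAAAA\tB*08:01\t7.0\n"
        )
        predictor = PrecomputedRankTable(path)
        ranks, unsupported = predict_percentile_ranks(
            {"AAAAAAAAA"}, {"A*01:01", "B*08:01", "C*04:01"}, predictor
        )
        assert ranks[("AAAAAAAAA", "A*01:01")] == 3.5
        assert ranks[("AAAAAAAAA", "B*08:01")] == 7.0
        assert unsupported == {"C*04:01"}

    def test_toy_pssm_deterministic_and_complete(self):
        peptides = {"MKTAYIAKQ", "AAGWKAAAA"}
        alleles = {"A*01:01", "B*07:02"}
        r1 = ToyPSSMPredictor(seed=4).predict(peptides, alleles)
        r2 = ToyPSSMPredictor(seed=4).predict(peptides, alleles)
        assert r1 == r2
        assert set(r1) == {(p, a) for p in peptides for a in alleles}
        assert all(0 < v <= 100 for v in r1.values())
        # a different seed gives a different matrix
        assert ToyPSSMPredictor(seed=5).predict(peptides, alleles) != r1


class TestCountHighAffinity:
    RANKS = {
        ("P1AAAAAAA", "A*01:01"): 3.5,
        ("P1AAAAAAA", "B*08:01"): 7.0,
        ("P2AAAAAAA", "A*01:01"): 5.0,
    }

    def test_cutoff_four(self):
        assert count_high_affinity(self.RANKS, make_typing(), AffinityConfig(4)) == 1

    def test_cutoff_hundred_counts_all(self):
        assert count_high_affinity(self.RANKS, make_typing(), AffinityConfig(100)) == 2

    def test_monotone_in_cutoff(self):
        for lo, hi in [(2, 4), (4, 6), (6, 100)]:
            assert count_high_affinity(
                self.RANKS, make_typing(), AffinityConfig(lo)
            ) <= count_high_affinity(self.RANKS, make_typing(), AffinityConfig(hi))

    def test_other_subjects_alleles_ignored(self):
        ranks = {("P1AAAAAAA", "A*68:01"): 1.0}  # not carried by the recipient
        assert count_high_affinity(ranks, make_typing(), AffinityConfig(4)) == 0


def _db(kind, **ligands):
    return LigandDatabase(
        kind=kind, ligands={a: frozenset(s) for a, s in ligands.items()}
    )


class TestComputeMethodCounts:
    EXPR = [ExpressionRecord("G1", "skin", "Supportive")]

    def kwargs(self, **over):
        base = dict(
            recipient_typing=make_typing(),
            iedb=_db("iedb"),
            mha=_db("mha"),
            immunogenicity=flat_model(threshold=float("-inf")),
            expression=self.EXPR,
            predictor=ToyPSSMPredictor(seed=0),
            affinity=AffinityConfig(),
        )
        base.update(over)
        return base

    def test_allele_aware_iedb_intersection(self):
        peps = {pep("AAAAAAAAA"), pep("CCCCCCCCC")}
        iedb = _db("iedb", **{"A*01:01": {"CCCCCCCCC"}, "A*68:01": {"AAAAAAAAA"}})
        est = compute_method_counts("P1", peps, **self.kwargs(iedb=iedb))
        assert est.m1 == 1  # only the ligand under a carried allele
        assert est.total_mismatched == 2

    def test_unrestricted_mode_pools_whole_database(self):
        peps = {pep("AAAAAAAAA")}
        iedb = _db("iedb", **{"A*68:01": {"AAAAAAAAA"}})
        est = compute_method_counts(
            "P1", peps, restrict_to_recipient_hla=False, **self.kwargs(iedb=iedb)
        )
        assert est.m1 == 1

    def test_empty_databases_zero_m1_m3(self):
        peps = {pep("AAAAAAAAA")}
        est = compute_method_counts("P1", peps, **self.kwargs())
        assert est.m1 == 0 and est.m3 == 0

    def test_identical_proteomes_all_zero(self):
        est = compute_method_counts("P1", set(), **self.kwargs())
        assert (est.m1, est.m2, est.m3, est.m4) == (0, 0, 0, 0)
        assert est.total_mismatched == est.total_filtered == 0

    def test_missing_typing_raises(self):
        with pytest.raises(ScoringError, match="typing"):
            compute_method_counts(
                "P1", set(), **self.kwargs(recipient_typing=None)
            )

    def test_missing_expression_leaves_filtered_fields_none(self):
        peps = {pep("AAAAAAAAA")}
        iedb = _db("iedb", **{"A*01:01": {"AAAAAAAAA"}})
        est = compute_method_counts(
            "P1", peps, **self.kwargs(iedb=iedb, expression=[])
        )
        assert est.m1 == 1
        assert est.m2 is None and est.m4 is None and est.total_filtered is None

    def test_brute_force_oracle_on_random_universes(self):
        import numpy as np

        rng = np.random.default_rng(23)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        typing = make_typing()
        rec_class_i = typing.class_i_alleles()
        alleles = sorted(rec_class_i)[:3]
        for _ in range(30):
            universe = [
                "".join(rng.choice(aas, size=9)) for _ in range(int(rng.integers(5, 50)))
            ]
            peps = {pep(s, genes=("G1",) if rng.random() < 0.7 else ("G9",))
                    for s in universe}
            iedb = _db("iedb", **{
                a: set(rng.choice(universe, size=min(5, len(universe)), replace=False))
                for a in alleles[:2]
            })
            mha = _db("mha", **{
                alleles[2]: set(rng.choice(universe, size=3, replace=False))
            })
            model = flat_model(threshold=float("-inf"))
            est = compute_method_counts(
                "P", peps, **self.kwargs(iedb=iedb, mha=mha, immunogenicity=model)
            )
            u = {p.sequence for p in peps}
            f = {p.sequence for p in peps if "G1" in p.source_genes}
            iedb_pool = set().union(
                *(iedb.ligands.get(a, frozenset()) for a in rec_class_i)
            )
            mha_pool = set().union(
                *(mha.ligands.get(a, frozenset()) for a in rec_class_i)
            )
            assert est.m1 == len(u & iedb_pool)
            assert est.m2 == len(f & iedb_pool)
            assert est.m3 == len(u & mha_pool)
            assert est.total_mismatched == len(u)
            assert est.total_filtered == len(f)
            assert est.m2 <= est.m1 and est.m4 <= est.total_filtered
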