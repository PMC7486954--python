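import numpy as np
import pandas as pd
import pytest

from mutacc.filters import (FilterParams, PileupStats, classify_effect,
                            compute_callable_sites, filter_candidates,
                            score_calls, spectrum_table)
from mutacc.genome import GeneModel, Genome
from mutacc.io import CandidateTable
from mutacc.simulate import synthesize_variant_calls


def make_candidates(rows, samples=("MA_01", "MA_02", "ancestor"),
                    ancestor="ancestor"):
    """rows: dicts with core fields + optional per-sample DP/AD overrides."""
    full = []
    for r in rows:
        base = {"contig": "c1", "pos": 100, "ref": "A", "alt": "G",
                "mq": 60.0, "dist_indel": np.inf}
        for s in samples:
            base[f"DP:{s}"] = 30
            base[f"AD:{s}"] = 0
        base.update(r)
        full.append(base)
    return CandidateTable(table=pd.DataFrame(full), samples=list(samples),
                          ancestor=ancestor)


class TestCallableSites:
    def _stats(self, mq, line_depth, anc_depth):
        return PileupStats(
            mq={"c1": np.array(mq, dtype=float)},
            depth={"MA_01": {"c1": np.array(line_depth)},
                   "ancestor": {"c1": np.array(anc_depth)}})

    def test_basic_callable(self):
        stats = self._stats([60.0], [30], [30])
        masks, n = compute_callable_sites(stats, "MA_01", "ancestor")
        assert n == 1 and masks["c1"][0]

    @pytest.mark.parametrize("mq,dl,da,expect", [
        (60, 30, 30, True),
        (19.9, 30, 30, False),   # mapping quality below 20
        (60, 19, 30, False),     # line depth below the minimum
        (60, 30, 19, False),     # ancestor depth below the minimum
        (60, 151, 30, False),    # line depth above the repeat cap
        (60, 30, 151, False),    # ancestor depth above the cap
        (20, 20, 20, True),      # all thresholds inclusive
        (60, 150, 150, True),    # depth exactly 150 is callable
    ])
    def test_threshold_boundaries(self, mq, dl, da, expect):
        stats = self._stats([mq], [dl], [da])
        _, n = compute_callable_sites(stats, "MA_01", "ancestor")
        assert (n == 1) is expect

    def test_coordinate_mismatch(self):
        stats = PileupStats(mq={"c1": np.zeros(5)},
                            depth={"MA_01": {"c1": np.zeros(4)},
                                   "ancestor": {"c1": np.zeros(5)}})
        with pytest.raises(ValueError, match="length mismatch"):
            compute_callable_sites(stats, "MA_01", "ancestor")


class TestFilterCriteria:
    def test_clean_candidate_accepted(self):
        ct = make_candidates([{"DP:MA_01": 30, "AD:MA_01": 10}])
        acc, rej = filter_candidates(ct)
        assert len(acc) == 1 and len(rej) == 0
        assert acc.iloc[0]["line"] == "MA_01"

    @pytest.mark.parametrize("override,reason", [
        ({"mq": 19.0, "AD:MA_01": 15}, "low_mq"),
        ({"DP:MA_01": 19, "AD:MA_01": 10}, "low_depth"),
        ({"DP:ancestor": 19, "AD:MA_01": 15}, "low_depth"),
        ({"DP:MA_01": 151, "AD:MA_01": 75}, "high_depth"),
        ({"DP:MA_01": 30, "AD:MA_01": 9}, "low_alt_fraction"),
        ({"AD:MA_01": 15, "dist_indel": 5.0}, "near_indel"),
        ({"AD:MA_01": 15, "AD:ancestor": 12}, "ancestral"),
        ({"AD:MA_01": 15, "AD:MA_02": 14}, "shared_line"),
    ])
    def test_single_rejection_reason(self, override, reason):
        """Each candidate gets exactly the first failing criterion."""
        ct = make_candidates([override])
        acc, rej = filter_candidates(ct)
        assert (rej["reason"] == reason).all()
        carriers = (rej["line"] == "MA_01").sum()
        assert carriers == 1

    def test_alt_fraction_boundary_inclusive(self):
        # exactly one third of the depth passes ("minimal coverage of 1/3rd")
        ct = make_candidates([{"DP:MA_01": 30, "AD:MA_01": 10}])
        acc, _ = filter_candidates(ct)
        assert len(acc) == 1

    def test_indel_distance_boundary(self):
        ct = make_candidates([{"AD:MA_01": 15, "dist_indel": 6.0}])
        acc, _ = filter_candidates(ct)
        assert len(acc) == 1  # distance 6 clears the 5 bp window

    def test_shared_line_both_rejected(self):
        ct = make_candidates([{"AD:MA_01": 15, "AD:MA_02": 14}])
        _, rej = filter_candidates(ct)
        assert sorted(rej["line"]) == ["MA_01", "MA_02"]
        assert (rej["reason"] == "shared_line").all()

    def test_cross_line_uniqueness_can_be_disabled(self):
        ct = make_candidates([{"AD:MA_01": 15, "AD:MA_02": 14}])
        acc, _ = filter_candidates(ct, FilterParams(cross_line_unique=False))
        assert len(acc) == 2

    def test_unknown_position_with_genome(self):
        g = Genome(sequences={"c1": "ACGT"})
        ct = make_candidates([{"pos": 100, "AD:MA_01": 15}])
        with pytest.raises(ValueError, match="unknown position"):
            filter_candidates(ct, genome=g)


@pytest.fixture(scope="module")
def genome():
    # gene: 5'UTR [10,20), CDS [20,32)+[40,52), intron [32,40), 3'UTR [52,60)
    # spliced CDS: ATG TTT CAA TGG CAT GGG AAA TAA -> M F Q W H G K *
    seq = list("A" * 100)
    cds = "ATGTTTCAATGG" + "CATGGGAAATAA"
    seq[20:32] = cds[:12]
    seq[40:52] = cds[12:]
    g = GeneModel(gene_id="g1", contig="c1", strand="+",
                  cds=[(20, 32), (40, 52)], utr5=[(10, 20)],
                  utr3=[(52, 60)])
    genome = Genome(sequences={"c1": "".join(seq)}, genes=[g])
    genome.validate()
    return genome


class TestEffectClassification:

    @pytest.mark.parametrize("pos,ref,alt,effect", [
        (5, "A", "T", "intergenic"),
        (15, "A", "C", "UTR"),
        (37, "A", "C", "intron"),        # mid-intron, outside splice window
        (28, "A", "G", "missense"),      # CAA (Gln) -> CGA (Arg)
        (26, "T", "C", "synonymous"),    # TTT (Phe) -> TTC (Phe)
        (27, "C", "T", "stop_gained"),   # CAA (Gln) -> TAA mid-CDS
        (22, "T", "C", "start_lost"),    # ATG -> ACG in the first codon
        (34, "A", "C", "splice_region"), # first 3 bp of the intron
        (32, "G", "A", "splice_region"), # last CDS base before the junction
    ])
    def test_classes(self, genome, pos, ref, alt, effect):
        ref_actual = genome.sequences["c1"][pos - 1]
        assert ref_actual == ref, f"fixture ref at {pos} is {ref_actual}"
        assert classify_effect("c1", pos, ref, alt, genome) == effect

    def test_minus_strand_codon_effects(self):
        coding = "ATGGTTTAA"  # M V *
        genomic = coding.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        g = Genome(sequences={"c1": "AAAA" + genomic + "AAAA"},
                   genes=[GeneModel(gene_id="g", contig="c1", strand="-",
                                    cds=[(4, 13)])])
        g.validate()
        # coding GTT third base maps to genomic 0-based 7 (an A: complement T)
        assert g.sequences["c1"][7] == "A"
        assert classify_effect("c1", 8, "A", "G", g) == "synonymous"  # GTT->GTC
        # coding GTT first base maps to genomic 0-based 9 (a C: complement G)
        assert g.sequences["c1"][9] == "C"
        assert classify_effect("c1", 10, "C", "A", g) == "missense"   # GTT->TTT

    def test_ref_mismatch_raises(self, genome):
        with pytest.raises(ValueError):
            classify_effect("c1", 21, "G", "C", genome)


class TestSyntheticRecovery:
    def test_perfect_sensitivity_no_artifacts(self, sim_truth, sim_genome,
                                              sim_config):
        calls = synthesize_variant_calls(sim_truth, sim_genome, sim_config,
                                         np.random.default_rng(77),
                                         with_artifacts=False)
        acc, rej = filter_candidates(calls.candidates, genome=sim_genome)
        score = score_calls(acc, sim_truth.mutations)
        assert score["sensitivity"] == 1.0
        assert score["false_positives"] == 0

    def test_artifacts_all_rejected_with_matching_reasons(self, sim_calls,
                                                          filtered):
        accepted, rejected = filtered
        audit = sim_calls.audit.set_index(["line", "contig", "pos", "alt"])
        rej = rejected.set_index(["line", "contig", "pos", "alt"])
        assert len(audit) > 0
        for key, row in audit.iterrows():
            assert key in rej.index, f"artifact {key} was not rejected"
            assert rej.loc[key, "reason"] == row["klass"]

    def test_truth_recovered_with_artifacts_on(self, sim_calls, sim_truth,
                                               filtered):
        accepted, _ = filtered
        score = score_calls(accepted, sim_truth.mutations)
        assert score["sensitivity"] == 1.0
        assert score["false_positives"] == 0


class TestSpectrumTable:
    def test_conservation(self, filtered):
        accepted, _ = filtered
        table = spectrum_table(accepted)
        assert table["count"].sum() == len(accepted)

    def test_empty_input(self):
        table = spectrum_table(pd.DataFrame(columns=["effect"]))
        assert (table["count"] == 0).all()

    def test_planted_effects_exact(self):
        acc = pd.DataFrame({"effect": ["missense"] * 3 + ["synonymous"] * 2
                            + ["intergenic"]})
        t = spectrum_table(acc).set_index("effect")["count"]
        assert t["missense"] == 3 and t["synonymous"] == 2
        assert t["intergenic"] == 1 and t["intron"] == 0
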