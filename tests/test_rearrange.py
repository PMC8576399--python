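"""V(D)J rearrangement sampling, assembly and productivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import igsim
from igsim.germline import GermlineAllele
from igsim.rearrange import JUNCTION_ENTITIES, JunctionPlan, _revcomp


def _plan(n1="", n2="", **lengths):
    base = {e: 0 for e in JUNCTION_ENTITIES}
    base.update(lengths)
    base["N1"], base["N2"] = len(n1), len(n2)
    return JunctionPlan(lengths=base, n1=n1, n2=n2)


V = GermlineAllele("IGHV-t*01", "ACG", "V")
D = GermlineAllele("IGHD-t*01", "TT", "D")
J = GermlineAllele("IGHJ-t*01", "CAA", "J")


class TestAssembly:
    def test_zero_plan_is_concatenation(self):
        r = igsim.assemble_rearrangement(V, D, J, _plan())
        assert r.sequence == "ACGTTCAA"
        assert (r.v_end, r.d_start, r.d_end, r.j_start) == (3, 4, 5, 6)

    def test_v3p_is_reverse_complement_of_terminal_bases(self):
        v = GermlineAllele("IGHV-t*01", "AAAC", "V")
        d = GermlineAllele("IGHD-t*01", "G", "D")
        j = GermlineAllele("IGHJ-t*01", "T", "J")
        r = igsim.assemble_rearrangement(v, d, j, _plan(V3P=2))
        assert r.sequence.startswith("AAAC" + "GT")  # revcomp("AC") == "GT"

    def test_deletions_trim_correct_ends(self):
        v = GermlineAllele("IGHV-t*01", "ACGTT", "V")
        d = GermlineAllele("IGHD-t*01", "GGCC", "D")
        j = GermlineAllele("IGHJ-t*01", "ATATA", "J")
        r = igsim.assemble_rearrangement(
            v, d, j, _plan(V3D=2, D5D=1, D3D=1, J5D=2)
        )
        assert r.sequence == "ACG" + "GC" + "ATA"

    def test_excessive_deletion_raises(self):
        with pytest.raises(ValueError):
            igsim.assemble_rearrangement(V, D, J, _plan(D5D=1, D3D=1))

    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=40),
        st.text(alphabet="ACGT", min_size=2, max_size=16),
        st.text(alphabet="ACGT", min_size=4, max_size=30),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_length_formula(self, vseq, dseq, jseq, data):
        v = GermlineAllele("IGHV-t*01", vseq, "V")
        d = GermlineAllele("IGHD-t*01", dseq, "D")
        j = GermlineAllele("IGHJ-t*01", jseq, "J")
        v3d = data.draw(st.integers(0, min(3, len(vseq) - 1)))
        d5d = data.draw(st.integers(0, min(2, len(dseq) - 1)))
        d3d = data.draw(st.integers(0, min(2, len(dseq) - 1 - d5d)))
        j5d = data.draw(st.integers(0, min(3, len(jseq) - 1)))
        v3p = 0 if v3d else data.draw(st.integers(0, 3))
        d5p = 0 if d5d else data.draw(st.integers(0, 2))
        d3p = 0 if d3d else data.draw(st.integers(0, 2))
        j5p = 0 if j5d else data.draw(st.integers(0, 3))
        n1 = data.draw(st.text(alphabet="ACGT", max_size=5))
        n2 = data.draw(st.text(alphabet="ACGT", max_size=5))
        plan = _plan(
            n1=n1, n2=n2, V3D=v3d, V3P=v3p, D5D=d5d, D5P=d5p,
            D3D=d3d, D3P=d3p, J5D=j5d, J5P=j5p,
        )
        r = igsim.assemble_rearrangement(v, d, j, plan)
        expected = (
            len(vseq) - v3d + v3p + len(n1)
            + len(dseq) - d5d - d3d + d5p + d3p
            + len(n2) + len(jseq) - j5d + j5p
        )
        assert len(r.sequence) == expected

    def test_reassembly_reproduces_stored_sequence(self, toy_db, junction_model, rng):
        usage = igsim.UsageModel.uniform(toy_db)
        for r in igsim.simulate_rearrangements(
            toy_db, usage, junction_model, 50, None, seed=8
        ):
            redo = igsim.assemble_rearrangement(
                toy_db[r.v_allele], toy_db[r.d_allele], toy_db[r.j_allele],
                r.plan, r.id,
            )
            assert redo.sequence == r.sequence


class TestJunctionSampling:
    def test_degenerate_model_gives_all_zero_plan(self, rng):
        plan = igsim.sample_junction(igsim.JunctionModel.all_zero(), rng)
        assert all(v == 0 for v in plan.lengths.values())
        assert plan.n1 == "" and plan.n2 == ""

    def test_deletion_suppresses_palindrome(self, rng):
        pmfs = {e: {0: 1.0} for e in JUNCTION_ENTITIES}
        pmfs["V3D"] = {2: 1.0}
        pmfs["V3P"] = {3: 1.0}
        model = igsim.JunctionModel(pmfs)
        for _ in range(20):
            plan = igsim.sample_junction(model, rng)
            assert plan.lengths["V3D"] == 2 and plan.lengths["V3P"] == 0

    def test_n1_mean_length_matches_pmf_expectation(self, rng):
        pmfs = {e: {0: 1.0} for e in JUNCTION_ENTITIES}
        pmfs["N1"] = {0: 0.5, 3: 0.5}
        model = igsim.JunctionModel(pmfs)
        lengths = [
            igsim.sample_junction(model, rng).lengths["N1"] for _ in range(20_000)
        ]
        assert np.mean(lengths) == pytest.approx(1.5, abs=0.05)

    def test_inconsistent_plan_rejected(self):
        with pytest.raises(ValueError):
            _plan(V3D=1, V3P=2)

    def test_tsv_round_trip(self, junction_model, tmp_path):
        p = tmp_path / "junction.tsv"
        junction_model.to_tsv(p)
        back = igsim.JunctionModel.from_tsv(p)
        for e in JUNCTION_ENTITIES:
            assert back.pmfs[e] == pytest.approx(junction_model.pmfs[e])


class TestUsage:
    def test_degenerate_usage_always_hits(self, toy_db, rng):
        usage = igsim.UsageModel(
            {
                "V": {"IGHV1-S*01": 1.0},
                "D": {"IGHD1-S*01": 1.0},
                "J": {"IGHJ1-S*01": 1.0},
            }
        )
        assert all(
            igsim.sample_genes(usage, rng) == ("IGHV1-S*01", "IGHD1-S*01", "IGHJ1-S*01")
            for _ in range(100)
        )

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            igsim.UsageModel({"V": {}})

    def test_usage_vector_recovered(self, toy_db, rng):
        # 10-gene model with distinct weights: empirical TV distance < 0.01
        names = [a.name for a in toy_db.by_segment("V")[:10]]
        weights = np.arange(1, 11, dtype=float)
        weights /= weights.sum()
        usage = igsim.UsageModel(
            {
                "V": dict(zip(names, weights)),
                "D": {"IGHD1-S*01": 1.0},
                "J": {"IGHJ1-S*01": 1.0},
            }
        )
        draws = [usage.sample("V", rng) for _ in range(100_000)]
        emp = np.array([draws.count(n) / len(draws) for n in names])
        assert 0.5 * np.abs(emp - weights).sum() < 0.01

    def test_allele_ratio_recovered(self, toy_db, rng):
        usage = igsim.UsageModel(
            {
                "V": {"IGHV1-S*01": 0.5, "IGHV1-S*02": 0.5},
                "D": {"IGHD1-S*01": 1.0},
                "J": {"IGHJ1-S*01": 1.0},
            },
            allele_ratios={"IGHV1-S": ("IGHV1-S*01", "IGHV1-S*02", 0.5)},
        )
        n = 100_000
        minor = sum(usage.sample("V", rng) == "IGHV1-S*02" for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(minor - n / 2) < 3 * sigma

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            igsim.UsageModel(
                {"V": {"IGHV1-S*01": 1.0}},
                allele_ratios={"IGHV1-S": ("IGHV1-S*01", "IGHV1-S*02", 1.5)},
            )


class TestProductivity:
    def test_in_frame_no_stop_is_productive(self):
        v = GermlineAllele("IGHV-t*01", "ATGGCA", "V")
        d = GermlineAllele("IGHD-t*01", "GCA", "D")
        j = GermlineAllele("IGHJ-t*01", "GCA", "J")
        r = igsim.assemble_rearrangement(v, d, j, _plan())
        assert r.productive

    def test_in_frame_stop_is_nonproductive(self):
        v = GermlineAllele("IGHV-t*01", "ATGGCA", "V")
        d = GermlineAllele("IGHD-t*01", "TAA", "D")
        j = GermlineAllele("IGHJ-t*01", "GCA", "J")
        assert not igsim.assemble_rearrangement(v, d, j, _plan()).productive

    def test_frameshift_is_nonproductive(self):
        v = GermlineAllele("IGHV-t*01", "ATGGCA", "V")
        d = GermlineAllele("IGHD-t*01", "GCA", "D")
        j = GermlineAllele("IGHJ-t*01", "GCA", "J")
        r = igsim.assemble_rearrangement(v, d, j, _plan(n1="A"))
        assert not r.productive

    @pytest.mark.parametrize("fraction,expected", [(1.0, 100), (0.0, 0)])
    def test_exact_productive_counts(
        self, toy_db, junction_model, fraction, expected
    ):
        usage = igsim.UsageModel.uniform(toy_db)
        rs = igsim.simulate_rearrangements(
            toy_db, usage, junction_model, 100, fraction, seed=4
        )
        assert len(rs) == 100
        assert sum(r.productive for r in rs) == expected

    def test_intermediate_fraction_floor(self, toy_db, junction_model):
        usage = igsim.UsageModel.uniform(toy_db)
        rs = igsim.simulate_rearrangements(
            toy_db, usage, junction_model, 10, 0.55, seed=4
        )
        assert sum(r.productive for r in rs) == 5  # floor(10 * 0.55)
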