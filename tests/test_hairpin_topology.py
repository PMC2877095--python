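import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from astra.genome_io import Hairpin, SmallRNASignature
from astra.hairpin_topology import (
    LocusAnchor,
    SignatureMatch,
    assign_probe_region,
    averaged_strand_profile,
    assign_hairpin_probes,
    match_signature,
    normalize_position,
    region_signal_table,
    topology_profile,
    tpq,
)
from astra.synthetic_data import revcomp

from conftest import make_probe_table


def _hairpin(seq=None, mirna=(10, 31), mirstar=(70, 91), shift=0):
    seq = seq or ("AUGC" * 30)[:120]
    return Hairpin("hp", seq, mirna, mirstar,
                   ("chr1", 1000 + shift, 1000 + shift + len(seq), "+"))


def _sig(seq, genome_hits=1, counts=None, sizes=None, phos="mono"):
    return SmallRNASignature(seq, genome_hits, counts or {"FLR": 1},
                             sizes or {"FLR": 250000}, phos)


class TestMatchSignature:
    def test_periodic_sequence_yields_every_occurrence(self):
        # AUGC*30 repeats every 4 nt: a 21-mer starting at 10 recurs at
        # every later offset congruent to 10 mod 4
        hp = _hairpin()
        matches = match_signature(_sig(hp.seq[10:31]), hp)
        sense_starts = [m.start for m in matches
                        if m.orientation == "sense"]
        assert sense_starts == list(range(2, 120 - 21 + 1, 4))

    def test_unique_sense_and_antisense(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 120))
        hp = _hairpin(seq)
        (m,) = match_signature(_sig(seq[10:31]), hp)
        assert (m.orientation, m.start) == ("sense", 10)
        (m,) = match_signature(_sig(revcomp(seq[10:31])), hp)
        assert (m.orientation, m.start) == ("antisense", 10)

    def test_multiple_occurrences_all_returned(self):
        core = "ACGUACGUACGUACGUACGUA"
        seq = "GGGG" + core + "CCCCCCGGGGCC" + core + "GGGGCC"
        hp = Hairpin("hp", seq, (0, 4), (50, 54), ("chr1", 0, len(seq), "+"))
        matches = match_signature(_sig(core), hp)
        sense = [m for m in matches if m.orientation == "sense"]
        assert [m.start for m in sense] == [4, 37]

    def test_signature_longer_than_hairpin_empty(self):
        hp = Hairpin("hp", "ACGUACGUAC", (0, 3), (5, 8),
                     ("chr1", 0, 10, "+"))
        assert match_signature(_sig("A" * 17), hp) == []

    def test_t_u_unified(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 120))
        hp = _hairpin(seq)
        dna = seq[20:41].replace("U", "T")
        (m,) = match_signature(_sig(dna), hp)
        assert m.start == 20


class TestNormalizePosition:
    def test_mirna_start_maps_to_zero(self):
        hp = _hairpin(mirna=(20, 41), mirstar=(120 - 21, 120))
        m = SignatureMatch(_sig("A" * 4), hp, 20, "sense", 0, 1)
        assert normalize_position(m, hp) == 0.0

    def test_mirstar_start_maps_to_one(self):
        hp = _hairpin(mirna=(20, 41), mirstar=(99, 120))
        m = SignatureMatch(_sig("A" * 4), hp, 99, "sense", 0, 1)
        assert normalize_position(m, hp) == 1.0

    def test_midpoint(self):
        hp = Hairpin("hp", "A" * 200, (20, 41), (120, 141),
                     ("chr1", 0, 200, "+"))
        m = SignatureMatch(_sig("AAAA"), hp, 70, "sense", 0, 1)
        assert normalize_position(m, hp) == 0.5

    @given(shift=st.integers(min_value=0, max_value=400),
           start=st.integers(min_value=0, max_value=99))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, shift, start):
        """Shifting all hairpin-internal coordinates by a constant leaves
        the normalized position unchanged."""
        base = Hairpin("hp", "A" * 700, (100, 121), (200, 221),
                       ("chr1", 0, 700, "+"))
        moved = Hairpin("hp", "A" * 700, (100 + shift, 121 + shift),
                        (200 + shift, 221 + shift), ("chr1", 0, 700, "+"))
        m0 = SignatureMatch(_sig("AAAA"), base, start, "sense", 0, 1)
        m1 = SignatureMatch(_sig("AAAA"), moved, start + shift, "sense",
                            0, 1)
        assert normalize_position(m0, base) == pytest.approx(
            normalize_position(m1, moved))


class TestTPQ:
    @pytest.mark.parametrize("count,size,expected", [
        (1, 250000, 1.0),
        (4, 1000000, 1.0),
        (0, 123, 0.0),
    ])
    def test_definition(self, count, size, expected):
        assert tpq(count, size) == expected

    def test_invalid_library_size(self):
        with pytest.raises(ValueError):
            tpq(1, 0)

    @given(count=st.integers(0, 10**6), scale=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_count_inverse_in_size(self, count, scale):
        assert tpq(count * scale, 250000) == pytest.approx(
            scale * tpq(count, 250000))
        assert tpq(count, 250000 * scale) == pytest.approx(
            tpq(count, 250000) / scale)

    def test_sum_over_libraries_equals_pooled_only_for_equal_sizes(self):
        # equal sizes: TPQ is additive across libraries
        equal = tpq(3, 250000) + tpq(5, 250000)
        assert equal == pytest.approx(tpq(8, 250000))
        # unequal sizes: summing per-library TPQ differs from pooling
        unequal = tpq(3, 250000) + tpq(5, 500000)
        pooled = tpq(8, 750000)
        assert unequal != pytest.approx(pooled)


class TestTopologyProfile:
    def test_empty_input(self):
        table = topology_profile([])
        assert len(table) == 0

    def test_single_match_row(self):
        hp = _hairpin(mirna=(20, 41), mirstar=(99, 120))
        sig = _sig("X", counts={"FLR": 8}, sizes={"FLR": 250000})
        sig.seq = "AAAA"
        m = SignatureMatch(sig, hp, 20, "sense", 0.0, 8.0)
        table = topology_profile([m])
        assert table.iloc[0].tolist() == [0.0, 3.0, "sense"]

    def test_unique_only_filter(self):
        hp = _hairpin()
        multi = _sig("AAAA", genome_hits=3)
        uniq = _sig("CCCC", genome_hits=1)
        matches = [SignatureMatch(multi, hp, 0, "sense", 0.0, 2.0),
                   SignatureMatch(uniq, hp, 0, "sense", 0.0, 2.0)]
        assert len(topology_profile(matches, unique_only=True)) == 1
        assert len(topology_profile(matches, unique_only=False)) == 2

    def test_phosphate_class_bookkeeping(self):
        hp = _hairpin()
        matches = [SignatureMatch(_sig("AAAA", phos=ph), hp, 0, "sense",
                                  0.0, 2.0)
                   for ph in ["mono"] * 3 + ["tri"] * 2]
        table = topology_profile(matches, group_by="phosphate_class")
        assert table.phosphate_class.value_counts().to_dict() == {
            "mono": 3, "tri": 2}


class TestProbeRegionAssignment:
    HP = (1000, 1120)
    MIRNA = (1010, 1031)
    MIRSTAR = (1070, 1091)

    def _region(self, probe, mpss=()):
        return assign_probe_region(probe, self.HP, self.MIRNA, self.MIRSTAR,
                                   mpss)

    def test_full_mirna_coverage(self):
        assert self._region((1008, 1033)) == "miRNA"

    def test_ten_nt_overlap_insufficient(self):
        # probe ends 10 nt into the 21-nt miRNA site: below the 11-nt rule
        assert self._region((995, 1020)) == "no_smRNA"

    def test_eleven_nt_overlap_sufficient(self):
        assert self._region((996, 1021)) == "miRNA"

    def test_mpss_seven_nt_boundary(self):
        mpss = [(1095, 1112)]  # a 17-nt signature site
        assert self._region((1081, 1102), mpss) == "other_smRNA"
        # one nt less overlap (6 nt) and below the miRNA* threshold too
        assert self._region((1082, 1101), mpss) == "no_smRNA"

    def test_mirstar_assignment(self):
        assert self._region((1069, 1094)) == "miRNA*"

    def test_precedence_by_larger_overlap(self):
        mirna, mirstar = (1010, 1031), (1031, 1052)
        r = assign_probe_region((1015, 1040), self.HP, mirna, mirstar)
        assert r == "miRNA"  # 16 vs 9 nt

    def test_non_overlapping_probe_gets_none(self):
        assert self._region((2000, 2025)) is None

    def test_partition_over_tiling(self):
        """Every hairpin-overlapping probe receives exactly one region."""
        for start in range(960, 1120, 5):
            region = self._region((start, start + 25))
            if start + 25 <= 1000:
                assert region is None
            else:
                assert region in {"miRNA", "miRNA*", "other_smRNA",
                                  "no_smRNA"}


class TestRegionSignalTable:
    def _probes(self, values):
        rows = [(f"p{i}", "chr1", i * 30, i * 30 + 25, "+", "A" * 25, v)
                for i, v in enumerate(values)]
        return make_probe_table(rows)

    def _assignments(self, regions):
        return pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(regions))],
            "hairpin_id": "hp",
            "region": regions,
            "orientation": "sense",
        })

    def test_identical_groups_t_zero_p_one(self):
        probes = self._probes([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        asn = self._assignments(["miRNA"] * 3 + ["no_smRNA"] * 3)
        (mirna, base) = region_signal_table(asn, probes)
        row = mirna if mirna.region == "miRNA" else base
        assert row.t_statistic == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_pooled_t_against_closed_form(self):
        """{1,2,3} vs {4,5,6}: pooled-variance t = -3.674, p ~= 0.0213."""
        probes = self._probes([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        asn = self._assignments(["miRNA"] * 3 + ["no_smRNA"] * 3)
        rows = {r.region: r for r in region_signal_table(asn, probes)}
        assert rows["miRNA"].t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert rows["miRNA"].p_value == pytest.approx(0.0213, abs=1e-3)

    def test_single_probe_region_not_computable(self):
        probes = self._probes([1.0, 4.0, 5.0, 6.0])
        asn = self._assignments(["miRNA"] + ["no_smRNA"] * 3)
        rows = {r.region: r for r in region_signal_table(asn, probes)}
        assert rows["miRNA"].n_probes == 1
        assert rows["miRNA"].mean_log2_per_probe == pytest.approx(1.0)
        assert not rows["miRNA"].test_computable

    def test_mean_across_samples_then_probes(self):
        rows = [("p0", "chr1", 0, 25, "+", "A" * 25, 1.0, 3.0),
                ("p1", "chr1", 30, 55, "+", "A" * 25, 2.0, 4.0),
                ("p2", "chr1", 60, 85, "+", "A" * 25, 0.0, 0.0),
                ("p3", "chr1", 90, 115, "+", "A" * 25, 0.0, 0.0)]
        probes = make_probe_table(rows, samples=("s1", "s2"))
        asn = self._assignments(["miRNA", "miRNA", "no_smRNA", "no_smRNA"])
        rows = {r.region: r for r in region_signal_table(asn, probes)}
        assert rows["miRNA"].mean_log2_per_probe == pytest.approx(2.5)


class TestAveragedStrandProfile:
    def test_uniform_signal_gives_equal_shares(self):
        n = 8
        rows = [(f"p{i}", "chr1", 1000 + 25 * i, 1025 + 25 * i, "+",
                 "A" * 25, 2.0) for i in range(n)]
        probes = make_probe_table(rows)
        anchor = LocusAnchor("L", "chr1", 1100, "+")
        prof = averaged_strand_profile([anchor], probes, window=800)
        assert np.allclose(prof.value, 1 / n)
        assert (prof.strand == "sense").all()

    def test_two_identical_loci_double_the_profile(self):
        rows = [(f"p{i}", "chr1", 1000 + 25 * i, 1025 + 25 * i, "+",
                 "A" * 25, float(i + 1)) for i in range(8)]
        probes = make_probe_table(rows)
        a = LocusAnchor("L", "chr1", 1100, "+")
        single = averaged_strand_profile([a], probes)
        double = averaged_strand_profile([a, a], probes)
        assert np.allclose(double.value, 2 * single.value)

    def test_all_zero_window_sample_skipped(self):
        rows = [("p0", "chr1", 1000, 1025, "+", "A" * 25, 0.0, 2.0),
                ("p1", "chr1", 1050, 1075, "+", "A" * 25, 0.0, 2.0)]
        probes = make_probe_table(rows, samples=("s1", "s2"))
        prof = averaged_strand_profile(
            [LocusAnchor("L", "chr1", 1040, "+")], probes)
        # only s2 contributes; its normalized values sum to 1
        assert prof.value.sum() == pytest.approx(1.0)

    def test_minus_strand_locus_flipped(self):
        # single hot probe downstream (left of anchor) on a minus locus
        rows = [("p0", "chr1", 900, 925, "-", "A" * 25, 5.0),
                ("p1", "chr1", 1100, 1125, "-", "A" * 25, 1.0)]
        probes = make_probe_table(rows)
        prof = averaged_strand_profile(
            [LocusAnchor("L", "chr1", 1000, "-")], probes)
        hot = prof.loc[prof.value.idxmax()]
        assert hot.offset > 0 and hot.strand == "sense"

    def test_pingpong_recovered_on_simulation(self, sim):
        """Simulated target loci show the ping-pong topology: the sense
        maximum downstream of the site, the antisense maximum upstream."""
        anchors = []
        genes = {g.gene_id: g for g in sim.genes}
        for p in sim.gold:
            if p.group != "target":
                continue
            g = genes[p.gene_id]
            anchors.append(LocusAnchor(p.gene_id, g.chrom,
                                       sum(p.site_interval) // 2, g.strand))
        prof = averaged_strand_profile(anchors, sim.probes)
        sense = prof[prof.strand == "sense"]
        anti = prof[prof.strand == "antisense"]
        assert sense.loc[sense.value.idxmax(), "offset"] > 0
        assert anti.loc[anti.value.idxmax(), "offset"] < 0


class TestSimulatedHairpinTopology:
    def test_antisense_density_biased_upstream_of_mirstar(self, sim):
        """On synthetic hairpins with mirstar_bias > 1 the antisense match
        density upstream of the miRNA* exceeds downstream density."""
        matches = [m for s in sim.smrnas for hp in sim.hairpins
                   for m in match_signature(s, hp)]
        anti = [m for m in matches if m.orientation == "antisense"]
        up = sum(m.start < m.hairpin.mirstar_interval[0] for m in anti)
        assert up > len(anti) / 2

    def test_region_partition_on_simulation(self, sim):
        asn = assign_hairpin_probes(sim.probes, sim.hairpins)
        assert asn.probe_id.is_unique
        assert set(asn.region) <= {"miRNA", "miRNA*", "other_smRNA",
                                   "no_smRNA"}
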