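"""Sequence annotation: references, GC content, probes."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rampkit.pathway import Segment, build_default_mouse_pathway
from rampkit.seqannot import (
    AnnotationError,
    Probe,
    ReferenceAnnotation,
    default_probes,
    gc_content,
    probe_detects,
    read_reference,
    species_sequence,
    synthetic_mouse_reference,
    write_reference_fasta,
)

from conftest import TOY_LENGTHS, TOY_SITES


@pytest.fixture(scope="module")
def toy_annotation():
    """Random toy reference matching the toy segment lengths."""
    return synthetic_mouse_reference(seed=5, lengths=TOY_LENGTHS)


class TestReadReference:
    def test_toy_fasta_with_three_segments(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">toy\n" + "ACGT" * 25 + "\n")
        coords = {Segment.S18: (1, 40), Segment.ITS1: (41, 70), Segment.S5_8: (71, 100)}
        ann = read_reference(p, coords)
        assert len(ann.segments) == 3
        assert ann.segment_sequence(Segment.ITS1) == ("ACGT" * 25)[40:70]

    def test_segment_beyond_sequence_rejected(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">toy\nACGTACGT\n")
        with pytest.raises(AnnotationError, match="outside sequence"):
            read_reference(p, {Segment.S18: (1, 20)})

    def test_fasta_without_coords_rejected(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">toy\nACGT\n")
        with pytest.raises(AnnotationError, match="supply"):
            read_reference(p)

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(AnnotationError, match="non-nucleotide"):
            ReferenceAnnotation("ACGTXX", {Segment.S18: (1, 6)})

    def test_genbank_rrna_features_define_segments(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        seq = "A" * 10 + "C" * 40 + "G" * 30 + "T" * 10 + "GC" * 15 + "A" * 50 + "T" * 10
        rec = SeqRecord(Seq(seq), id="toyGB", annotations={"molecule_type": "DNA"})
        rec.features = [
            SeqFeature(SimpleLocation(10, 50), type="rRNA", qualifiers={"product": ["18S ribosomal RNA"]}),
            SeqFeature(SimpleLocation(80, 120), type="rRNA", qualifiers={"product": ["5.8S ribosomal RNA"]}),
            SeqFeature(SimpleLocation(130, 170), type="rRNA", qualifiers={"product": ["28S ribosomal RNA"]}),
        ]
        p = tmp_path / "toy.gb"
        SeqIO.write(rec, p, "genbank")
        ann = read_reference(p)
        assert ann.segments[Segment.S18] == (11, 50)
        assert ann.segments[Segment.ITS1] == (51, 80)
        assert ann.segments[Segment.ITS2] == (121, 130)
        assert ann.segments[Segment.FIVE_ETS] == (1, 10)

    def test_fasta_round_trip(self, tmp_path, toy_annotation):
        p = tmp_path / "ref.fa"
        write_reference_fasta(toy_annotation, p)
        back = read_reference(p, toy_annotation.segments)
        assert back.sequence == toy_annotation.sequence


class TestGCContent:
    def test_all_gc(self):
        ann = ReferenceAnnotation("GGCC", {Segment.ITS1: (1, 4)})
        assert gc_content(ann, Segment.ITS1) == 100.0

    def test_no_gc(self):
        ann = ReferenceAnnotation("ATAT", {Segment.ITS1: (1, 4)})
        assert gc_content(ann, Segment.ITS1) == 0.0

    def test_ambiguous_bases_excluded_from_both_counts(self):
        ann = ReferenceAnnotation("GCNNAT", {Segment.ITS1: (1, 6)})
        assert gc_content(ann, Segment.ITS1) == pytest.approx(50.0)

    def test_interval_string_spec(self, toy_annotation):
        s = toy_annotation.interval_sequence(Segment.ITS1, 10, 50)
        expected = 100.0 * sum(c in "GC" for c in s) / len(s)
        assert gc_content(toy_annotation, "ITS1:10-50") == pytest.approx(expected)

    def test_synthetic_mouse_its1_composition(self):
        """The synthetic stand-in reproduces the documented 70.1% mouse ITS1 G+C."""
        ann = synthetic_mouse_reference(seed=0)
        assert round(gc_content(ann, Segment.ITS1), 1) == 70.1

    @given(st.text(alphabet="ACGT", min_size=4, max_size=80))
    def test_reverse_complement_invariance(self, seq):
        from Bio.Seq import Seq

        rc = str(Seq(seq).reverse_complement())
        a1 = ReferenceAnnotation(seq, {Segment.ITS1: (1, len(seq))})
        a2 = ReferenceAnnotation(rc, {Segment.ITS1: (1, len(rc))})
        assert gc_content(a1, Segment.ITS1) == pytest.approx(gc_content(a2, Segment.ITS1))


class TestSpeciesSequence:
    def test_mature_18s_is_segment_string(self, toy_annotation, toy_graph):
        assert species_sequence(toy_annotation, toy_graph.species["18S"]) == (
            toy_annotation.segment_sequence(Segment.S18)
        )

    def test_18se_is_18s_plus_58_nt_of_its1(self, toy_annotation, toy_graph):
        seq = species_sequence(toy_annotation, toy_graph.species["18SE"])
        assert seq == toy_annotation.segment_sequence(Segment.S18) + (
            toy_annotation.segment_sequence(Segment.ITS1)[:58]
        )

    def test_lengths_match_species_length_for_all_species(self, toy_annotation, toy_graph):
        from rampkit.pathway import species_length

        for name, sp in toy_graph.species.items():
            if not sp.extent:
                continue
            assert len(species_sequence(toy_annotation, sp)) == species_length(
                sp, toy_graph.lengths
            ), name

    def test_ptp_rejected(self, toy_annotation, toy_graph):
        from rampkit.pathway import PathwayError

        with pytest.raises(PathwayError, match="pseudo"):
            species_sequence(toy_annotation, toy_graph.species["PTP"])


class TestProbes:
    def test_flanking_probes_discriminate_36s(self, graph):
        probes = default_probes()
        assert probe_detects(probes["ITS1-85"], graph.species["36S"])
        assert not probe_detects(probes["ITS1-54"], graph.species["36S"])

    def test_probe_inside_whole_segment_detects(self, graph):
        # 32S contains all of ITS2, so any ITS2 probe detects it
        assert probe_detects(default_probes()["ITS2-100"], graph.species["32S"])

    def test_monotone_in_extent_containment(self, graph):
        """If A's extent contains B's, every probe detecting B detects A."""
        def contains(a, b):
            return all(
                any(
                    ivb.segment is iva.segment
                    and iva.start <= ivb.start
                    and ivb.end <= iva.end
                    for iva in a.extent
                )
                for ivb in b.extent
            )

        probes = list(default_probes().values())
        species = [sp for sp in graph.species.values() if sp.extent]
        for a in species:
            for b in species:
                if a is b or not contains(a, b):
                    continue
                for pr in probes:
                    if probe_detects(pr, b):
                        assert probe_detects(pr, a), (pr.name, a.name, b.name)

    def test_default_design_species_follow_probe_detection(self, graph):
        """Blot species lists in the simulator match probe-target containment."""
        from rampkit.kinetics import LaneSpec, default_design

        design = default_design({1: LaneSpec("s", "E1", "reference")})
        probes = default_probes()
        measurable = [
            n for n, sp in graph.species.items()
            if sp.extent and not sp.is_fragment and n != "SSU-2b-pre" and n not in
            ("47S", "46S", "45S", "18S", "5.8S", "28S", "28.5S", "32.5S")
        ]
        for blot in design.blots:
            pr = probes[blot.probe]
            detected = {n for n in measurable if probe_detects(pr, graph.species[n])}
            declared = set(blot.species) - {"PTP"} - {"32.5S"}
            assert declared <= detected, blot.blot_id
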