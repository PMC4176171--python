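"""Reference-sequence utilities: segments, GC content, probes.

An rDNA reference annotation maps the seven transcript segments (5'ETS,
18S, ITS1, 5.8S, ITS2, 28S, 3'ETS) onto a nucleotide sequence.  On top of
it the module assembles species sequences from pathway extents, computes
G+C content of segments or arbitrary intervals (mammalian ITS1 is
strikingly G+C rich compared with yeast), and predicts which species an
oligonucleotide probe can detect.

Hybridization is modeled as exact interval containment: a probe detects a
species iff the probe's target interval lies entirely within the species
extent.  This is deliberately simple - no melting thermodynamics - but it
is exactly the logic that lets a probe pair flanking a cleavage site
discriminate the products: the probe 3' of site 2b detects 36S while a
probe 5' of the site does not.

The mouse reference named by the standard annotation (GenBank X82564) must
be supplied by the user as a FASTA or GenBank flat file;
:func:`synthetic_mouse_reference` builds a *synthetic* stand-in with the
documented segment lengths and base composition for tests and demos.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
import numpy as np

from .pathway import (
    DEFAULT_SEGMENT_LENGTHS,
    Interval,
    PathwayError,
    SEGMENT_ORDER,
    Segment,
    SpeciesDef,
)

__all__ = [
    "ReferenceAnnotation",
    "Probe",
    "AnnotationError",
    "read_reference",
    "write_reference_fasta",
    "gc_content",
    "species_sequence",
    "probe_detects",
    "default_probes",
    "synthetic_mouse_reference",
]

_VALID = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = _VALID - set("ACGTU")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceAnnotation:
    """A nucleotide sequence with 1-based inclusive segment coordinates."""

    sequence: str
    segments: dict[Segment, tuple[int, int]]
    source_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - _VALID
        if bad:
            raise AnnotationError(f"non-nucleotide characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        last_end = 0
        for seg in SEGMENT_ORDER:
            if seg not in self.segments:
                continue
            start, end = self.segments[seg]
            if not 1 <= start <= end <= len(seq):
                raise AnnotationError(
                    f"segment {seg.value} ({start}-{end}) outside sequence of length {len(seq)}"
                )
            if start <= last_end:
                raise AnnotationError(f"segment {seg.value} overlaps or reorders a predecessor")
            last_end = end

    def segment_lengths(self) -> dict[Segment, int]:
        return {seg: e - s + 1 for seg, (s, e) in self.segments.items()}

    def segment_sequence(self, segment: Segment) -> str:
        start, end = self._coords(segment)
        return self.sequence[start - 1 : end]

    def interval_sequence(self, segment: Segment, start: int, end: int) -> str:
        s0, e0 = self._coords(segment)
        if not 1 <= start <= end <= e0 - s0 + 1:
            raise AnnotationError(
                f"interval {start}-{end} outside segment {segment.value} "
                f"(length {e0 - s0 + 1})"
            )
        return self.sequence[s0 - 1 + start - 1 : s0 - 1 + end]

    def _coords(self, segment: Segment) -> tuple[int, int]:
        try:
            return self.segments[segment]
        except KeyError:
            raise AnnotationError(f"segment {segment.value} not annotated") from None


def _segments_from_features(record) -> dict[Segment, tuple[int, int]]:
    """Segment map from GenBank rRNA features, spacers inferred as gaps."""
    rrna: dict[Segment, tuple[int, int]] = {}
    wanted = {"18S": Segment.S18, "5.8S": Segment.S5_8, "28S": Segment.S28}
    for feat in record.features:
        if feat.type not in ("rRNA", "misc_RNA"):
            continue
        text = " ".join(str(v) for vals in feat.qualifiers.values() for v in vals)
        for key, seg in wanted.items():
            if key in text and seg not in rrna:
                rrna[seg] = (int(feat.location.start) + 1, int(feat.location.end))
    missing = [s.value for s in wanted.values() if s not in rrna]
    if missing:
        raise AnnotationError(f"GenBank record lacks rRNA features for {missing}")
    s18, s58, s28 = rrna[Segment.S18], rrna[Segment.S5_8], rrna[Segment.S28]
    segs = {
        Segment.S18: s18,
        Segment.S5_8: s58,
        Segment.S28: s28,
        Segment.ITS1: (s18[1] + 1, s58[0] - 1),
        Segment.ITS2: (s58[1] + 1, s28[0] - 1),
    }
    if s18[0] > 1:
        segs[Segment.FIVE_ETS] = (1, s18[0] - 1)
    if s28[1] < len(record.seq):
        segs[Segment.THREE_ETS] = (s28[1] + 1, len(record.seq))
    return segs


def read_reference(
    path, coords: dict[Segment, tuple[int, int]] | None = None
) -> ReferenceAnnotation:
    """Read a FASTA or GenBank reference.

    ``coords`` supplies or overrides segment coordinates; a GenBank record
    with rRNA features can stand alone (spacer segments are inferred as the
    gaps between 18S, 5.8S and 28S).
    """
    with open(path, encoding="utf-8") as fh:
        head = fh.read(1)
    fmt = "fasta" if head == ">" else "genbank"
    record = next(SeqIO.parse(path, fmt))
    segments: dict[Segment, tuple[int, int]] = {}
    if fmt == "genbank":
        try:
            segments = _segments_from_features(record)
        except AnnotationError:
            if coords is None:
                raise
    if coords:
        segments.update(coords)
    if not segments:
        raise AnnotationError("no segment coordinates: supply them for FASTA references")
    return ReferenceAnnotation(str(record.seq), segments, record.id)


def write_reference_fasta(annotation: ReferenceAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{annotation.source_id or 'reference'}\n")
        seq = annotation.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GC content


def _parse_interval(spec: str) -> tuple[Segment, int, int]:
    m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", spec)
    if not m:
        raise AnnotationError(f"bad interval spec {spec!r}; expected 'SEGMENT:start-end'")
    seg_name, start, end = m.groups()
    by_value = {s.value: s for s in Segment}
    if seg_name not in by_value:
        raise AnnotationError(f"unknown segment {seg_name!r}")
    return by_value[seg_name], int(start), int(end)


def gc_content(annotation: ReferenceAnnotation, where: Segment | str | tuple) -> float:
    """G+C percentage of a segment or interval.

    ``where`` may be a :class:`Segment`, a ``(segment, start, end)`` tuple
    or a ``"SEGMENT:start-end"`` string.  Ambiguity codes are excluded from
    both numerator and denominator.
    """
    if isinstance(where, Segment):
        seq = annotation.segment_sequence(where)
    elif isinstance(where, str):
        seq = annotation.interval_sequence(*_parse_interval(where))
    else:
        seq = annotation.interval_sequence(*where)
    if not seq:
        raise AnnotationError("empty interval")
    unambiguous = sum(1 for c in seq if c not in _AMBIGUOUS)
    if unambiguous == 0:
        raise AnnotationError("interval contains only ambiguous bases")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / unambiguous


# ---------------------------------------------------------------------------
# species sequences and probes


def species_sequence(annotation: ReferenceAnnotation, species: SpeciesDef) -> str:
    """Concatenated sequence of a species' extent, in transcript order."""
    if species.is_pseudo:
        raise PathwayError(
            f"{species.name} is a pseudo-species; assemble its members instead"
        )
    if not species.extent:
        raise PathwayError(f"species {species.name} has no extent")
    parts = [annotation.interval_sequence(iv.segment, iv.start, iv.end) for iv in species.extent]
    return "".join(parts)


@dataclass(frozen=True)
class Probe:
    """An oligonucleotide probe, named by its 3'-most target position.

    ``start``/``end`` delimit the probed target interval (1-based,
    inclusive) within ``segment``; the probe oligo itself is the reverse
    complement of that target.
    """

    name: str
    segment: Segment
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise AnnotationError(f"probe {self.name}: bad interval {self.start}-{self.end}")

    def oligo(self, annotation: ReferenceAnnotation) -> str:
        return str(Seq(annotation.interval_sequence(self.segment, self.start, self.end)).reverse_complement())


def probe_detects(probe: Probe, species: SpeciesDef) -> bool:
    """True iff the probe's target interval lies inside the species extent."""
    if species.is_pseudo:
        raise PathwayError("probe detection against PTP: query its members")
    for iv in species.extent:
        if iv.segment is probe.segment and iv.start <= probe.start and probe.end <= iv.end:
            return True
    return False


def default_probes() -> dict[str, Probe]:
    """Probes used throughout the package (20-mers, named by 3' position).

    ITS1-54 ends 5' of site 2b (+58) and therefore misses 36S; ITS1-85
    starts 3' of the site and detects it.  ITS2-100 lies 5' of site 4b
    and covers the LSU intermediates down to 12S; 5ETS-3000 lies between
    A0 and site 1 and covers 19S.
    """
    return {
        p.name: p
        for p in (
            Probe("ITS1-54", Segment.ITS1, 35, 54),
            Probe("ITS1-85", Segment.ITS1, 66, 85),
            Probe("ITS1-184", Segment.ITS1, 165, 184),
            Probe("ITS2-100", Segment.ITS2, 81, 100),
            Probe("5ETS-3000", Segment.FIVE_ETS, 2981, 3000),
        )
    }


# ---------------------------------------------------------------------------
# synthetic reference


_SEGMENT_GC = {
    Segment.FIVE_ETS: 0.650,
    Segment.S18: 0.560,
    Segment.ITS1: 0.701,
    Segment.S5_8: 0.570,
    Segment.ITS2: 0.730,
    Segment.S28: 0.670,
    Segment.THREE_ETS: 0.700,
}


def synthetic_mouse_reference(
    seed: int = 0, lengths: dict[Segment, int] | None = None
) -> ReferenceAnnotation:
    """A *synthetic* mouse-like rDNA reference.

    This is a stand-in, not the real GenBank X82564 record: segment lengths
    follow the documented mouse annotation and each segment is a random
    sequence with the documented base composition (ITS1 at exactly 70.1%
    G+C).  Use it for pipeline tests and demonstrations; supply the real
    record to :func:`read_reference` for sequence-faithful work.
    """
    lengths = dict(lengths or DEFAULT_SEGMENT_LENGTHS)
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    segments: dict[Segment, tuple[int, int]] = {}
    pos = 0
    for seg in SEGMENT_ORDER:
        n = lengths[seg]
        n_gc = round(_SEGMENT_GC[seg] * n)
        bases = np.array(["G"] * (n_gc // 2 + n_gc % 2) + ["C"] * (n_gc // 2)
                         + ["A"] * ((n - n_gc) // 2 + (n - n_gc) % 2) + ["T"] * ((n - n_gc) // 2))
        rng.shuffle(bases)
        parts.append("".join(bases))
        segments[seg] = (pos + 1, pos + n)
        pos += n
    return ReferenceAnnotation("".join(parts), segments, "synthetic-mouse-rDNA")
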