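"""Formal model of the mouse pre-rRNA processing pathway.

The 47S primary transcript made by Pol I contains the three mature rRNAs
(18S, 5.8S, 28S) embedded in four transcribed spacers (5'ETS, ITS1, ITS2,
3'ETS).  Processing removes the spacers through an ordered but branched set
of endo- and exonucleolytic reactions.  This module represents that pathway
as validated data: segments with lengths, cleavage sites with coordinates,
species (precursors, matures, discarded spacer fragments) with explicit
extents on the transcript, and reactions connecting them into a DAG.

Coordinates are 1-based offsets within each segment.  A cleavage "after
position p" splits the transcript between p and p+1, so the 5' product ends
at p and the 3' product starts at p+1: site 2b lies after ITS1 +58, which
puts the 5' end of 36S pre-rRNA at ITS1 +59.

The canonical mouse pathway built by :func:`build_default_mouse_pathway`
contains both ITS1 separation routes.  Cleavage at site 2c (fuzzy,
+837..+857) first yields 34S and 32.5S; cleavage at site 2b (+58) first
yields 36S and an SSU-side precursor that matures to 18SE.  The
co-migrating 47S/46S/45S pool is represented by the pseudo-species PTP
("primary transcript plus"), which acts as the single early node of the
kinetic network; its three members keep their individual extents for
sequence arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

__all__ = [
    "Segment",
    "SEGMENT_ORDER",
    "Interval",
    "CleavageSite",
    "SpeciesDef",
    "ReactionKind",
    "Reaction",
    "Violation",
    "PathwayGraph",
    "PathwayError",
    "DEFAULT_SEGMENT_LENGTHS",
    "DEFAULT_SITE_POSITIONS",
    "build_default_mouse_pathway",
    "apply_cleavage",
    "species_length",
    "read_pathway",
    "write_pathway",
]


class PathwayError(ValueError):
    """Invalid pathway construction or query."""


class Segment(str, enum.Enum):
    """Transcript segments in fixed 5'->3' order."""

    FIVE_ETS = "5'ETS"
    S18 = "18S"
    ITS1 = "ITS1"
    S5_8 = "5.8S"
    ITS2 = "ITS2"
    S28 = "28S"
    THREE_ETS = "3'ETS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SEGMENT_ORDER: tuple[Segment, ...] = tuple(Segment)

#: Mouse rDNA segment lengths (nt) from the standard annotation of the
#: X82564-region transcription unit.  Configurable per organism.
DEFAULT_SEGMENT_LENGTHS: dict[Segment, int] = {
    Segment.FIVE_ETS: 4007,
    Segment.S18: 1870,
    Segment.ITS1: 999,
    Segment.S5_8: 157,
    Segment.ITS2: 1089,
    Segment.S28: 4730,
    Segment.THREE_ETS: 565,
}

#: Default cleavage-site coordinates.  2b and 2c are the mapped mouse ITS1
#: sites (+58 and the heterogeneous +837..+857 interval).  A' and A0 lie in
#: the 5'ETS; site 1 sits at the 5'ETS/18S boundary (cleavage after the last
#: 5'ETS nucleotide forms the mature 18S 5' end); 4b splits ITS2.  Positions
#: inside the 5'ETS and ITS2 are adjustable defaults - only 2b/2c carry
#: mapped coordinates.
DEFAULT_SITE_POSITIONS: dict[str, object] = {
    "A'": 650,
    "A0": 2000,
    "1": None,  # resolved to len(5'ETS) at build time
    "2b": 58,
    "2c": (837, 857),
    "4b": 1000,
}


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive run of positions within one segment."""

    segment: Segment
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise PathwayError(
                f"bad interval {self.segment.value}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CleavageSite:
    """An endonucleolytic cut point: cleavage occurs *after* ``position``.

    Heterogeneous sites carry a ``fuzzy_range`` of observed offsets;
    ``position`` is then its midpoint (rounded down) and is used for all
    length arithmetic.
    """

    name: str
    segment: Segment
    position: int
    fuzzy_range: tuple[int, int] | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fuzzy_range is not None:
            lo, hi = self.fuzzy_range
            if not lo <= hi:
                raise PathwayError(f"site {self.name}: bad fuzzy range {self.fuzzy_range}")
            if self.position != (lo + hi) // 2:
                raise PathwayError(
                    f"site {self.name}: position {self.position} is not the "
                    f"midpoint of {self.fuzzy_range}"
                )


@dataclass(frozen=True)
class SpeciesDef:
    """A pre-rRNA species defined by the transcript intervals it contains.

    ``ptp_member`` marks 47S/46S/45S, whose pooled signal is measured as
    PTP.  The PTP pseudo-species itself has an empty extent and lists its
    members.  Discarded spacer pieces are ordinary species whose names start
    with ``frag:``; they make cleavage products partition exactly and are
    excluded from ratio panels.
    """

    name: str
    extent: tuple[Interval, ...] = ()
    is_mature: bool = False
    ptp_member: bool = False
    members: tuple[str, ...] = ()

    @property
    def is_fragment(self) -> bool:
        return self.name.startswith("frag:")

    @property
    def is_pseudo(self) -> bool:
        return bool(self.members)


class ReactionKind(str, enum.Enum):
    ENDONUCLEOLYTIC = "endonucleolytic"
    EXONUCLEOLYTIC = "exonucleolytic"
    TRANSCRIPTION = "transcription"
    TERMINAL = "terminal"


@dataclass(frozen=True)
class Reaction:
    """One processing step.

    Endonucleolytic reactions name the :class:`CleavageSite` and exactly two
    products that partition the substrate at that site.  Exonucleolytic
    reactions have one product strictly contained in the substrate.
    Transcription has no substrate; terminal reactions (disposal of
    fragments) have no products.  ``factor_tags`` label the trans-acting
    machineries operating at the step and are the handles perturbations
    grab.
    """

    id: str
    kind: ReactionKind
    substrate: str | None = None
    site: str | None = None
    products: tuple[str, ...] = ()
    factor_tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class Violation:
    rule: str
    subject: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.subject}: {self.message}"


# ---------------------------------------------------------------------------
# coordinate helpers


def _segment_offsets(lengths: dict[Segment, int]) -> dict[Segment, int]:
    """Absolute transcript coordinate preceding each segment's first base."""
    offsets: dict[Segment, int] = {}
    pos = 0
    for seg in SEGMENT_ORDER:
        offsets[seg] = pos
        pos += lengths[seg]
    return offsets


def _extent_to_abs(
    extent: tuple[Interval, ...], lengths: dict[Segment, int]
) -> list[tuple[int, int]]:
    off = _segment_offsets(lengths)
    return [(off[iv.segment] + iv.start, off[iv.segment] + iv.end) for iv in extent]


def _abs_to_extent(
    start: int, end: int, lengths: dict[Segment, int]
) -> tuple[Interval, ...]:
    """Convert an absolute run back to per-segment intervals."""
    off = _segment_offsets(lengths)
    out: list[Interval] = []
    for seg in SEGMENT_ORDER:
        s0, s1 = off[seg] + 1, off[seg] + lengths[seg]
        lo, hi = max(start, s0), min(end, s1)
        if lo <= hi:
            out.append(Interval(seg, lo - off[seg], hi - off[seg]))
    return tuple(out)


def species_length(species: SpeciesDef, lengths: dict[Segment, int]) -> int:
    """Total length of a species in nucleotides (sum over its intervals)."""
    if species.is_pseudo:
        raise PathwayError(
            f"{species.name} is a pseudo-species; query its members "
            f"{species.members} instead"
        )
    if not species.extent:
        raise PathwayError(f"species {species.name} has no extent")
    return sum(iv.length for iv in species.extent)


def apply_cleavage(
    species: SpeciesDef,
    site: CleavageSite,
    lengths: dict[Segment, int],
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    """Split a species extent at a cleavage site.

    Returns the (5', 3') product extents.  The cut point must lie strictly
    inside the species: the 5' product ends at the site position and the 3'
    product starts at position + 1.
    """
    if not species.extent:
        raise PathwayError(f"cannot cleave {species.name}: no extent")
    off = _segment_offsets(lengths)
    cut = off[site.segment] + site.position  # last base of the 5' product
    runs = _extent_to_abs(species.extent, lengths)
    first, last = runs[0][0], runs[-1][1]
    if not (first <= cut < last) or not any(lo <= cut <= hi for lo, hi in runs):
        raise PathwayError(
            f"site {site.name} ({site.segment.value} +{site.position}) is not "
            f"inside species {species.name}"
        )
    five: list[Interval] = []
    three: list[Interval] = []
    for iv in species.extent:
        lo = off[iv.segment] + iv.start
        hi = off[iv.segment] + iv.end
        if hi <= cut:
            five.append(iv)
        elif lo > cut:
            three.append(iv)
        else:
            five.extend(_abs_to_extent(lo, cut, lengths))
            three.extend(_abs_to_extent(cut + 1, hi, lengths))
    return tuple(five), tuple(three)


# ---------------------------------------------------------------------------
# the pathway graph


@dataclass
class PathwayGraph:
    """Segments, sites, species and reactions of one transcription unit."""

    lengths: dict[Segment, int]
    sites: dict[str, CleavageSite]
    species: dict[str, SpeciesDef]
    reactions: list[Reaction] = field(default_factory=list)

    # -- lookups ------------------------------------------------------------

    def species_def(self, name: str) -> SpeciesDef:
        try:
            return self.species[name]
        except KeyError:
            raise PathwayError(f"unknown species {name!r}") from None

    def substrate_extent(self, name: str) -> SpeciesDef:
        """Species whose extent stands for ``name`` in cleavage arithmetic.

        PTP delegates to its most-processed member (45S by convention, the
        last listed member).
        """
        sp = self.species_def(name)
        if sp.is_pseudo:
            return self.species_def(sp.members[-1])
        return sp

    def reactions_consuming(self, name: str) -> list[Reaction]:
        return [r for r in self.reactions if r.substrate == name]

    def reactions_producing(self, name: str) -> list[Reaction]:
        return [r for r in self.reactions if name in r.products]

    def factor_tags(self) -> set[str]:
        tags: set[str] = set()
        for r in self.reactions:
            tags.update(r.factor_tags)
        return tags

    def species_dag(self) -> "nx.DiGraph":
        """Directed substrate -> product graph over species."""
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for r in self.reactions:
            for p in r.products:
                if r.substrate is not None:
                    g.add_edge(r.substrate, p, reaction=r.id)
        return g

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[Violation]:
        """Check every structural invariant; violations are data, not errors."""
        out: list[Violation] = []
        for seg in SEGMENT_ORDER:
            if self.lengths.get(seg, 0) <= 0:
                out.append(Violation("segment-length", seg.value, "length must be > 0"))
        if any(v.rule == "segment-length" for v in out):
            return out  # coordinate checks below would be meaningless

        for site in self.sites.values():
            if not 1 <= site.position <= self.lengths[site.segment]:
                out.append(
                    Violation(
                        "site-position",
                        site.name,
                        f"position {site.position} outside {site.segment.value} "
                        f"(length {self.lengths[site.segment]})",
                    )
                )

        for sp in self.species.values():
            if sp.is_pseudo:
                for m in sp.members:
                    if m not in self.species:
                        out.append(Violation("pseudo-member", sp.name, f"unknown member {m}"))
                continue
            if not sp.extent:
                out.append(Violation("extent-empty", sp.name, "species has empty extent"))
                continue
            runs = _extent_to_abs(sp.extent, self.lengths)
            for iv in sp.extent:
                if iv.end > self.lengths[iv.segment]:
                    out.append(
                        Violation(
                            "extent-bounds",
                            sp.name,
                            f"{iv.segment.value}:{iv.start}-{iv.end} exceeds segment "
                            f"length {self.lengths[iv.segment]}",
                        )
                    )
            for (a0, a1), (b0, b1) in zip(runs, runs[1:]):
                if b0 != a1 + 1:
                    out.append(
                        Violation(
                            "extent-contiguity",
                            sp.name,
                            f"gap between transcript positions {a1} and {b0}",
                        )
                    )

        for r in self.reactions:
            out.extend(self._validate_reaction(r))

        dag = self.species_dag()
        if not nx.is_directed_acyclic_graph(dag):
            cyc = nx.find_cycle(dag)
            out.append(
                Violation("acyclicity", "->".join(e[0] for e in cyc), "species graph has a cycle")
            )

        transcription_products = {
            p for r in self.reactions if r.kind is ReactionKind.TRANSCRIPTION for p in r.products
        }
        for sp in self.species.values():
            if sp.ptp_member:
                continue  # subsumed in the PTP lump
            if not sp.is_mature and not self.reactions_consuming(sp.name):
                out.append(Violation("connectivity", sp.name, "non-mature species has no consumer"))
            if sp.name not in transcription_products and not self.reactions_producing(sp.name):
                out.append(Violation("connectivity", sp.name, "species has no producer"))
        return out

    def _validate_reaction(self, r: Reaction) -> list[Violation]:
        out: list[Violation] = []
        for name in (r.products if r.substrate is None else (r.substrate, *r.products)):
            if name not in self.species:
                out.append(Violation("reaction-species", r.id, f"unknown species {name}"))
                return out
        if r.kind is ReactionKind.ENDONUCLEOLYTIC:
            if r.site not in self.sites or len(r.products) != 2:
                out.append(
                    Violation("reaction-form", r.id, "endonucleolytic needs a site and 2 products")
                )
                return out
            sub = self.substrate_extent(r.substrate)
            try:
                five, three = apply_cleavage(sub, self.sites[r.site], self.lengths)
            except PathwayError as exc:
                out.append(Violation("partition", r.id, str(exc)))
                return out
            p5, p3 = (self.species_def(p) for p in r.products)
            if p5.extent != five or p3.extent != three:
                out.append(
                    Violation(
                        "partition",
                        r.id,
                        f"products {r.products} do not partition {sub.name} at site {r.site}",
                    )
                )
        elif r.kind is ReactionKind.EXONUCLEOLYTIC:
            if len(r.products) != 1:
                out.append(Violation("reaction-form", r.id, "exonucleolytic needs 1 product"))
                return out
            sub = self.substrate_extent(r.substrate)
            prod = self.species_def(r.products[0])
            sub_abs = set()
            for lo, hi in _extent_to_abs(sub.extent, self.lengths):
                sub_abs.add((lo, hi))
            # product runs must each be contained in some substrate run
            for lo, hi in _extent_to_abs(prod.extent, self.lengths):
                if not any(a <= lo and hi <= b for a, b in sub_abs):
                    out.append(
                        Violation(
                            "containment",
                            r.id,
                            f"product {prod.name} not contained in substrate {sub.name}",
                        )
                    )
                    break
            else:
                if species_length(prod, self.lengths) >= species_length(sub, self.lengths):
                    out.append(
                        Violation("containment", r.id, "exonucleolytic product not smaller")
                    )
        elif r.kind is ReactionKind.TRANSCRIPTION:
            if r.substrate is not None or len(r.products) != 1:
                out.append(Violation("reaction-form", r.id, "transcription: no substrate, 1 product"))
        elif r.kind is ReactionKind.TERMINAL:
            if r.products:
                out.append(Violation("reaction-form", r.id, "terminal reactions have no products"))
        return out

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": {seg.value: self.lengths[seg] for seg in SEGMENT_ORDER},
            "sites": [
                {
                    "name": s.name,
                    "segment": s.segment.value,
                    "position": s.position,
                    **({"fuzzy_range": list(s.fuzzy_range)} if s.fuzzy_range else {}),
                    **({"aliases": list(s.aliases)} if s.aliases else {}),
                }
                for s in self.sites.values()
            ],
            "species": [
                {
                    "name": sp.name,
                    "extent": [[iv.segment.value, iv.start, iv.end] for iv in sp.extent],
                    **({"is_mature": True} if sp.is_mature else {}),
                    **({"ptp_member": True} if sp.ptp_member else {}),
                    **({"members": list(sp.members)} if sp.members else {}),
                }
                for sp in self.species.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "kind": r.kind.value,
                    **({"substrate": r.substrate} if r.substrate else {}),
                    **({"site": r.site} if r.site else {}),
                    "products": list(r.products),
                    **({"factor_tags": list(r.factor_tags)} if r.factor_tags else {}),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayGraph":
        seg_by_value = {s.value: s for s in Segment}
        lengths = {seg_by_value[k]: int(v) for k, v in d["segments"].items()}
        sites = {
            s["name"]: CleavageSite(
                s["name"],
                seg_by_value[s["segment"]],
                int(s["position"]),
                tuple(s["fuzzy_range"]) if s.get("fuzzy_range") else None,
                tuple(s.get("aliases", ())),
            )
            for s in d["sites"]
        }
        species = {
            sp["name"]: SpeciesDef(
                sp["name"],
                tuple(Interval(seg_by_value[seg], int(a), int(b)) for seg, a, b in sp["extent"]),
                bool(sp.get("is_mature", False)),
                bool(sp.get("ptp_member", False)),
                tuple(sp.get("members", ())),
            )
            for sp in d["species"]
        }
        reactions = [
            Reaction(
                r["id"],
                ReactionKind(r["kind"]),
                r.get("substrate"),
                r.get("site"),
                tuple(r.get("products", ())),
                tuple(r.get("factor_tags", ())),
            )
            for r in d["reactions"]
        ]
        return cls(lengths, sites, species, reactions)


def write_pathway(graph: PathwayGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(graph.to_dict(), fh, sort_keys=False)


def read_pathway(path) -> PathwayGraph:
    with open(path, encoding="utf-8") as fh:
        return PathwayGraph.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# the canonical mouse pathway


def build_default_mouse_pathway(
    segment_lengths: dict[Segment, int] | None = None,
    site_positions: dict[str, object] | None = None,
) -> PathwayGraph:
    """Build the canonical mouse processing pathway.

    Both ITS1 routes are present: 2c-first (PTP -> 34S + 32.5S, with the
    SSU side maturing 34S -> 29S -> 20S -> 18SE) and 2b-first (PTP ->
    SSU-side precursor + 36S, with 36S cleaved at 2c to yield 32.5S).
    Both routes converge on 18SE (SSU) and 32.5S -> 32S (LSU); 32S is split
    at site 4b into 12S and 28.5S, which mature to 5.8S and 28S.

    ``segment_lengths`` and ``site_positions`` override the mouse defaults
    (toy builds must keep every site inside its segment).  Non-positive
    lengths are rejected.
    """
    lengths = dict(DEFAULT_SEGMENT_LENGTHS)
    if segment_lengths:
        lengths.update(segment_lengths)
    for seg, n in lengths.items():
        if int(n) <= 0:
            raise PathwayError(f"segment {seg.value}: length must be positive, got {n}")
        lengths[seg] = int(n)

    pos = dict(DEFAULT_SITE_POSITIONS)
    if site_positions:
        pos.update(site_positions)
    if pos.get("1") is None:
        pos["1"] = lengths[Segment.FIVE_ETS]

    fuzzy_2c = pos["2c"] if isinstance(pos["2c"], tuple) else None
    p2c = (fuzzy_2c[0] + fuzzy_2c[1]) // 2 if fuzzy_2c else int(pos["2c"])

    sites = {
        "A'": CleavageSite("A'", Segment.FIVE_ETS, int(pos["A'"])),
        "A0": CleavageSite("A0", Segment.FIVE_ETS, int(pos["A0"])),
        "1": CleavageSite("1", Segment.FIVE_ETS, int(pos["1"])),
        "2b": CleavageSite("2b", Segment.ITS1, int(pos["2b"]), aliases=("E", "2a")),
        "2c": CleavageSite("2c", Segment.ITS1, p2c, fuzzy_range=fuzzy_2c, aliases=("2",)),
        "4b": CleavageSite("4b", Segment.ITS2, int(pos["4b"])),
    }
    for s in sites.values():
        if not 1 <= s.position <= lengths[s.segment]:
            raise PathwayError(
                f"site {s.name} at {s.segment.value} +{s.position} exceeds segment "
                f"length {lengths[s.segment]}"
            )

    L = lengths
    a_prime, a0 = sites["A'"].position, sites["A0"].position
    p2b = sites["2b"].position
    p4b = sites["4b"].position
    if not a_prime < a0 < L[Segment.FIVE_ETS]:
        raise PathwayError("require A' < A0 < len(5'ETS)")
    if not p2b < p2c <= L[Segment.ITS1]:
        raise PathwayError("require 2b < 2c <= len(ITS1)")

    iv = Interval
    full = lambda seg: iv(seg, 1, L[seg])  # noqa: E731 - local shorthand
    ets_after = lambda p: iv(Segment.FIVE_ETS, p + 1, L[Segment.FIVE_ETS])  # noqa: E731

    species_list = [
        SpeciesDef("PTP", members=("47S", "46S", "45S")),
        SpeciesDef("47S", tuple(full(s) for s in SEGMENT_ORDER), ptp_member=True),
        SpeciesDef(
            "46S",
            (ets_after(a_prime),) + tuple(full(s) for s in SEGMENT_ORDER[1:]),
            ptp_member=True,
        ),
        SpeciesDef(
            "45S",
            (ets_after(a_prime),) + tuple(full(s) for s in SEGMENT_ORDER[1:-1]),
            ptp_member=True,
        ),
        SpeciesDef("34S", (ets_after(a_prime), full(Segment.S18), iv(Segment.ITS1, 1, p2c))),
        SpeciesDef(
            "SSU-2b-pre", (ets_after(a_prime), full(Segment.S18), iv(Segment.ITS1, 1, p2b))
        ),
        SpeciesDef(
            "36S",
            (
                iv(Segment.ITS1, p2b + 1, L[Segment.ITS1]),
                full(Segment.S5_8),
                full(Segment.ITS2),
                full(Segment.S28),
            ),
        ),
        SpeciesDef(
            "32.5S",
            (
                iv(Segment.ITS1, p2c + 1, L[Segment.ITS1]),
                full(Segment.S5_8),
                full(Segment.ITS2),
                full(Segment.S28),
            ),
        ),
        SpeciesDef("32S", (full(Segment.S5_8), full(Segment.ITS2), full(Segment.S28))),
        SpeciesDef("29S", (ets_after(a0), full(Segment.S18), iv(Segment.ITS1, 1, p2c))),
        SpeciesDef("19S", (ets_after(a0),)),
        SpeciesDef("20S", (full(Segment.S18), iv(Segment.ITS1, 1, p2c))),
        SpeciesDef("18SE", (full(Segment.S18), iv(Segment.ITS1, 1, p2b))),
        SpeciesDef("12S", (full(Segment.S5_8), iv(Segment.ITS2, 1, p4b))),
        SpeciesDef("28.5S", (iv(Segment.ITS2, p4b + 1, L[Segment.ITS2]), full(Segment.S28))),
        SpeciesDef("18S", (full(Segment.S18),), is_mature=True),
        SpeciesDef("5.8S", (full(Segment.S5_8),), is_mature=True),
        SpeciesDef("28S", (full(Segment.S28),), is_mature=True),
        # discarded spacer pieces, kept so every cleavage partitions exactly
        SpeciesDef("frag:5ETS-A0", (iv(Segment.FIVE_ETS, a_prime + 1, a0),)),
        SpeciesDef("frag:5ETS-A1", (ets_after(a_prime),)),
        SpeciesDef("frag:ITS1-internal", (iv(Segment.ITS1, p2b + 1, p2c),)),
    ]
    species = {sp.name: sp for sp in species_list}

    k = ReactionKind
    reactions = [
        Reaction("txn", k.TRANSCRIPTION, products=("PTP",)),
        Reaction("2c@PTP", k.ENDONUCLEOLYTIC, "PTP", "2c", ("34S", "32.5S"), ("2c",)),
        Reaction("2b@PTP", k.ENDONUCLEOLYTIC, "PTP", "2b", ("SSU-2b-pre", "36S"), ("2b",)),
        Reaction("A0@34S", k.ENDONUCLEOLYTIC, "34S", "A0", ("frag:5ETS-A0", "29S"), ("SSU-A0",)),
        Reaction("1@29S", k.ENDONUCLEOLYTIC, "29S", "1", ("19S", "20S"), ("site1",)),
        Reaction("2b@20S", k.ENDONUCLEOLYTIC, "20S", "2b", ("18SE", "frag:ITS1-internal"), ("2b",)),
        # lumped 5'ETS removal on the 2b-first route: same machineries as A0 + site 1
        Reaction(
            "1@SSU-2b-pre",
            k.ENDONUCLEOLYTIC,
            "SSU-2b-pre",
            "1",
            ("frag:5ETS-A1", "18SE"),
            ("SSU-A0", "site1"),
        ),
        Reaction("2c@36S", k.ENDONUCLEOLYTIC, "36S", "2c", ("frag:ITS1-internal", "32.5S"), ("2c",)),
        Reaction("xrn2@32.5S", k.EXONUCLEOLYTIC, "32.5S", None, ("32S",), ("xrn2",)),
        Reaction("4b@32S", k.ENDONUCLEOLYTIC, "32S", "4b", ("12S", "28.5S"), ("ITS2",)),
        Reaction("mat@18SE", k.EXONUCLEOLYTIC, "18SE", None, ("18S",), ("late-18SE",)),
        Reaction("mat@12S", k.EXONUCLEOLYTIC, "12S", None, ("5.8S",)),
        Reaction("mat@28.5S", k.EXONUCLEOLYTIC, "28.5S", None, ("28S",)),
        Reaction("decay@19S", k.TERMINAL, "19S"),
        Reaction("decay@frag:5ETS-A0", k.TERMINAL, "frag:5ETS-A0"),
        Reaction("decay@frag:5ETS-A1", k.TERMINAL, "frag:5ETS-A1"),
        Reaction("decay@frag:ITS1-internal", k.TERMINAL, "frag:ITS1-internal"),
    ]

    graph = PathwayGraph(lengths, sites, species, reactions)
    problems = graph.validate()
    if problems:  # construction bug, not user error
        raise PathwayError("default pathway failed validation: " + "; ".join(map(str, problems)))
    return graph


def mutate_for_test(graph: PathwayGraph, *, drop_producer_of: str | None = None) -> PathwayGraph:
    """Return a copy with a seeded defect (used by validation tests)."""
    reactions = list(graph.reactions)
    if drop_producer_of is not None:
        reactions = [r for r in reactions if drop_producer_of not in r.products]
    return replace_graph(graph, reactions=reactions)


def replace_graph(graph: PathwayGraph, **kw) -> PathwayGraph:
    d = {
        "lengths": dict(graph.lengths),
        "sites": dict(graph.sites),
        "species": dict(graph.species),
        "reactions": list(graph.reactions),
    }
    d.update(kw)
    return PathwayGraph(**d)
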