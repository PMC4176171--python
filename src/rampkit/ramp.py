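"""RAMP profiles: normalized log2 precursor-ratio panels.

RAMP (Ratio Analysis of Multiple Precursors) converts quantified northern
signals into an ordered set of precursor ratios.  Three ratio classes are
combined in one profile:

* level relative to the primary transcript pool (e.g. 34S/PTP),
* immediate substrate-product pairs (e.g. 18SE/20S, 12S/32S),
* mutually exclusive intermediates (34S/36S), which report which of the
  two ITS1 sites was cleaved first.

Each ratio is formed within a single lane of a single hybridization, which
makes profiles exactly invariant to per-lane loading differences and
per-blot probe efficiencies.  A knockdown profile is the difference of
log2 ratios against a matched reference sample; replicate profiles are
averaged with a sample standard deviation.  Below-detection signals are
flagged missing and never imputed.

Profiles are displayed as two tiles: tile 1 holds the /PTP ratios, tile 2
the substrate-product and mutually exclusive ratios, always in the same
order so that profiles remain visually comparable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .pathway import PathwayGraph
from .quantio import MissingMeasurementError, QuantTable

__all__ = [
    "RatioClass",
    "RatioDefinition",
    "RatioPanel",
    "ProfileEntry",
    "RAMPProfile",
    "RatioError",
    "ProvenanceError",
    "BelowDetectionError",
    "default_mouse_panel",
    "compute_ratio",
    "normalized_log_ratio",
    "build_profile",
    "aggregate_replicates",
    "write_profile_tsv",
    "read_profile_tsv",
]


class RatioError(ValueError):
    pass


class ProvenanceError(RatioError):
    """Numerator and denominator were not taken from one lane of one blot."""


class BelowDetectionError(RatioError):
    """A signal needed for a ratio is zero or absent."""

    def __init__(self, species: str, detail: str = ""):
        super().__init__(f"species {species!r} below detection{detail}")
        self.species = species


class RatioClass(str, enum.Enum):
    VS_PTP = "vs_ptp"
    SUBSTRATE_PRODUCT = "substrate_product"
    MUTUALLY_EXCLUSIVE = "mutually_exclusive"


@dataclass(frozen=True)
class RatioDefinition:
    numerator: str
    denominator: str
    ratio_class: RatioClass

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise RatioError(f"degenerate ratio {self.numerator}/{self.denominator}")

    @property
    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @property
    def tile(self) -> int:
        return 1 if self.ratio_class is RatioClass.VS_PTP else 2


@dataclass(frozen=True)
class RatioPanel:
    """Fixed, ordered list of ratios; tile 1 first, then tile 2."""

    definitions: tuple[RatioDefinition, ...]

    def __post_init__(self) -> None:
        labels = [d.label for d in self.definitions]
        if len(set(labels)) != len(labels):
            raise RatioError("duplicate ratio labels in panel")
        tiles = [d.tile for d in self.definitions]
        if tiles != sorted(tiles):
            raise RatioError("panel must list tile-1 ratios before tile-2 ratios")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def validate_against(self, graph: PathwayGraph) -> None:
        """Check class semantics against the pathway wiring."""
        dag = graph.species_dag()
        known = set(graph.species)
        for d in self.definitions:
            for name in (d.numerator, d.denominator):
                if name not in known:
                    raise RatioError(f"{d.label}: unknown species {name!r}")
            if d.ratio_class is RatioClass.VS_PTP:
                if d.denominator != "PTP":
                    raise RatioError(f"{d.label}: vs-PTP ratio must divide by PTP")
            elif d.ratio_class is RatioClass.SUBSTRATE_PRODUCT:
                if not (
                    nx.has_path(dag, d.denominator, d.numerator)
                    or nx.has_path(dag, d.numerator, d.denominator)
                ):
                    raise RatioError(f"{d.label}: no substrate-product path in the pathway")
            else:  # mutually exclusive
                if nx.has_path(dag, d.denominator, d.numerator) or nx.has_path(
                    dag, d.numerator, d.denominator
                ):
                    raise RatioError(f"{d.label}: species are on one route, not exclusive")


def default_mouse_panel(graph: PathwayGraph | None = None) -> RatioPanel:
    """The default two-tile mouse panel.

    Tile 1: 34S, 36S, 29S, 20S, 19S, 18SE, 32S, 12S each over PTP.
    Tile 2: 34S/36S, then 29S/34S, 20S/34S, 18SE/34S, 18SE/20S, 32S/36S,
    12S/32S.  The tile-2 order is a documented default (branch-choice ratio
    first, then SSU maturation, then LSU maturation).
    """
    tile1 = ["34S", "36S", "29S", "20S", "19S", "18SE", "32S", "12S"]
    tile2 = [
        ("34S", "36S", RatioClass.MUTUALLY_EXCLUSIVE),
        ("29S", "34S", RatioClass.SUBSTRATE_PRODUCT),
        ("20S", "34S", RatioClass.SUBSTRATE_PRODUCT),
        ("18SE", "34S", RatioClass.SUBSTRATE_PRODUCT),
        ("18SE", "20S", RatioClass.SUBSTRATE_PRODUCT),
        ("32S", "36S", RatioClass.SUBSTRATE_PRODUCT),
        ("12S", "32S", RatioClass.SUBSTRATE_PRODUCT),
    ]
    defs = [RatioDefinition(n, "PTP", RatioClass.VS_PTP) for n in tile1]
    defs += [RatioDefinition(n, d, c) for n, d, c in tile2]
    panel = RatioPanel(tuple(defs))
    if graph is not None:
        panel.validate_against(graph)
    return panel


# ---------------------------------------------------------------------------
# ratio arithmetic


def compute_ratio(
    table: QuantTable,
    definition: RatioDefinition,
    blot_id: str,
    lane: int,
    *,
    denom_blot_id: str | None = None,
    denom_lane: int | None = None,
) -> float:
    """Numerator / denominator signal from one lane of one hybridization.

    Passing a different blot or lane for the denominator is a provenance
    error: cross-blot ratios would absorb probe-efficiency differences and
    cross-lane ratios loading differences, which is exactly what RAMP is
    designed to avoid.
    """
    if denom_blot_id is not None and denom_blot_id != blot_id:
        raise ProvenanceError(
            f"{definition.label}: numerator from blot {blot_id!r} but denominator "
            f"from blot {denom_blot_id!r}"
        )
    if denom_lane is not None and denom_lane != lane:
        raise ProvenanceError(
            f"{definition.label}: numerator from lane {lane} but denominator from "
            f"lane {denom_lane}"
        )
    try:
        num = table.lane_signal(blot_id, lane, definition.numerator)
    except MissingMeasurementError:
        raise BelowDetectionError(definition.numerator, f" (absent on {blot_id} lane {lane})")
    try:
        den = table.lane_signal(blot_id, lane, definition.denominator)
    except MissingMeasurementError:
        raise BelowDetectionError(definition.denominator, f" (absent on {blot_id} lane {lane})")
    if num <= 0:
        raise BelowDetectionError(definition.numerator)
    if den <= 0:
        raise BelowDetectionError(definition.denominator)
    return num / den


def normalized_log_ratio(kd_ratio: float, ref_ratio: float) -> float:
    """log2(knockdown ratio) - log2(reference ratio)."""
    if not (kd_ratio > 0 and ref_ratio > 0):
        raise RatioError(f"ratios must be positive, got kd={kd_ratio}, ref={ref_ratio}")
    return math.log2(kd_ratio) - math.log2(ref_ratio)


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class ProfileEntry:
    definition: RatioDefinition
    value: float | None  # normalized log2 ratio; None when missing
    sd: float | None = None  # sample SD, present only for n >= 2
    n: int = 1
    flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return self.value is None


@dataclass
class RAMPProfile:
    panel: RatioPanel
    entries: tuple[ProfileEntry, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(e.definition for e in self.entries) != tuple(self.panel.definitions):
            raise RatioError("profile entries do not follow the panel order")

    def values(self) -> np.ndarray:
        """Entry values in panel order, NaN where missing."""
        return np.array(
            [np.nan if e.value is None else e.value for e in self.entries], dtype=float
        )

    def entry(self, label: str) -> ProfileEntry:
        for e in self.entries:
            if e.definition.label == label:
                return e
        raise KeyError(label)

    def value(self, label: str) -> float | None:
        return self.entry(label).value


def _sample_lane(table: QuantTable, sample_id: str, blot_id: str) -> int | None:
    rows = table.lanes_for_sample(sample_id)
    rows = rows[rows["blot_id"] == blot_id]
    if len(rows) == 0:
        return None
    return int(rows["lane"].iloc[0])


def build_profile(
    table: QuantTable,
    kd_sample: str,
    ref_sample: str,
    panel: RatioPanel,
    graph: PathwayGraph | None = None,
) -> RAMPProfile:
    """Build a single-experiment RAMP profile from one kd/ref sample pair.

    Both samples must come from the same experiment (the same pair of
    biological samples), because pre-rRNA transcription fluctuates with the
    physiological state of the cells and pairing is what cancels it.  For
    every panel ratio the first blot (sorted by id) carrying both species
    for both samples is used; species below detection leave the entry
    flagged missing rather than zero.
    """
    if graph is not None:
        panel.validate_against(graph)
    kd_rows = table.lanes_for_sample(kd_sample)
    ref_rows = table.lanes_for_sample(ref_sample)
    if len(kd_rows) == 0:
        raise RatioError(f"sample {kd_sample!r} not present in table")
    if len(ref_rows) == 0:
        raise RatioError(f"sample {ref_sample!r} not present in table")
    kd_exp = set(kd_rows["experiment_id"])
    ref_exp = set(ref_rows["experiment_id"])
    if len(kd_exp) != 1 or kd_exp != ref_exp:
        raise RatioError(
            f"samples {kd_sample!r} and {ref_sample!r} are not a pair from one "
            f"experiment (experiment ids {sorted(kd_exp)} vs {sorted(ref_exp)})"
        )

    entries: list[ProfileEntry] = []
    for d in panel:
        value = None
        flags: list[str] = []
        chosen = None
        for blot_id in sorted(set(kd_rows["blot_id"]) & set(ref_rows["blot_id"])):
            kd_lane = _sample_lane(table, kd_sample, blot_id)
            ref_lane = _sample_lane(table, ref_sample, blot_id)
            if kd_lane is None or ref_lane is None:
                continue
            if all(
                table.has(blot_id, lane, sp)
                for lane in (kd_lane, ref_lane)
                for sp in (d.numerator, d.denominator)
            ):
                chosen = (blot_id, kd_lane, ref_lane)
                break
        if chosen is None:
            flags.append(f"missing:no-blot-covers:{d.label}")
        else:
            blot_id, kd_lane, ref_lane = chosen
            try:
                kd_ratio = compute_ratio(table, d, blot_id, kd_lane)
                ref_ratio = compute_ratio(table, d, blot_id, ref_lane)
                value = normalized_log_ratio(kd_ratio, ref_ratio)
            except BelowDetectionError as exc:
                flags.append(f"missing:below-detection:{exc.species}")
        entries.append(ProfileEntry(d, value, None, 1 if value is not None else 0, tuple(flags)))
    meta = {"kd_sample": kd_sample, "ref_sample": ref_sample, "experiment_id": next(iter(kd_exp))}
    return RAMPProfile(panel, tuple(entries), meta)


def aggregate_replicates(profiles: list[RAMPProfile]) -> RAMPProfile:
    """Mean +/- sample SD (n-1 denominator) over replicate profiles.

    Panels must be identical.  Per ratio, replicates where the entry is
    missing simply do not contribute to n; SD is reported only for n >= 2.
    """
    if not profiles:
        raise RatioError("no profiles to aggregate")
    panel = profiles[0].panel
    for p in profiles[1:]:
        if p.panel.labels != panel.labels:
            raise RatioError("panel mismatch between replicate profiles")
    entries: list[ProfileEntry] = []
    for i, d in enumerate(panel):
        vals = [p.entries[i].value for p in profiles if p.entries[i].value is not None]
        n = len(vals)
        if n == 0:
            flags = tuple(
                sorted({fl for p in profiles for fl in p.entries[i].flags})
            ) or ("missing:all-replicates",)
            entries.append(ProfileEntry(d, None, None, 0, flags))
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n >= 2 else None
        entries.append(ProfileEntry(d, mean, sd, n))
    meta = {
        "replicates": len(profiles),
        "experiment_ids": [p.metadata.get("experiment_id") for p in profiles],
    }
    if profiles[0].metadata.get("factor"):
        meta["factor"] = profiles[0].metadata["factor"]
    return RAMPProfile(panel, tuple(entries), meta)


# ---------------------------------------------------------------------------
# TSV round trip


def write_profile_tsv(profile: RAMPProfile, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("ratio_label\ttile\tmean_log2\tsd\tn\tflags\n")
        for e in profile.entries:
            value = "NA" if e.value is None else f"{e.value:.10g}"
            sd = "NA" if e.sd is None else f"{e.sd:.10g}"
            flags = ";".join(e.flags) if e.flags else "-"
            fh.write(f"{e.definition.label}\t{e.definition.tile}\t{value}\t{sd}\t{e.n}\t{flags}\n")


def _classify(label: str, tile: int, graph: PathwayGraph | None) -> RatioClass:
    num, den = label.split("/", 1)
    if den == "PTP" or tile == 1:
        return RatioClass.VS_PTP
    if graph is not None:
        dag = graph.species_dag()
        if num in dag and den in dag:
            if nx.has_path(dag, den, num) or nx.has_path(dag, num, den):
                return RatioClass.SUBSTRATE_PRODUCT
            return RatioClass.MUTUALLY_EXCLUSIVE
    return (
        RatioClass.MUTUALLY_EXCLUSIVE if {num, den} == {"34S", "36S"} else RatioClass.SUBSTRATE_PRODUCT
    )


def read_profile_tsv(path, graph: PathwayGraph | None = None) -> RAMPProfile:
    defs: list[RatioDefinition] = []
    entries: list[ProfileEntry] = []
    with open(path, encoding="utf-8") as fh:
        rows = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header, *body = rows
    if header.split("\t") != ["ratio_label", "tile", "mean_log2", "sd", "n", "flags"]:
        raise RatioError(f"unexpected profile header in {path}")
    for ln in body:
        label, tile, value, sd, n, flags = ln.split("\t")
        num, den = label.split("/", 1)
        d = RatioDefinition(num, den, _classify(label, int(tile), graph))
        defs.append(d)
        entries.append(
            ProfileEntry(
                d,
                None if value == "NA" else float(value),
                None if sd == "NA" else float(sd),
                int(n),
                () if flags in ("-", "") else tuple(flags.split(";")),
            )
        )
    return RAMPProfile(RatioPanel(tuple(defs)), tuple(entries))
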