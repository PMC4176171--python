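"""Quantified hybridization tables.

A quant table holds per-(blot, probe, lane, species) phosphorimager signals
with sample and replicate metadata.  Signals are unitless; background
subtraction is assumed to have been done by the quantification software.
The table enforces the provenance RAMP needs: every ratio must later be
formed from one lane of one hybridization, so each (blot, lane) pair maps
to exactly one sample and signals are never imputed across blots.

CSV dialect: UTF-8, comma separated, header
``blot_id,probe,sample_id,lane,species,signal,experiment_id,condition``
with ``#`` comment lines allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pathway import PathwayGraph

__all__ = [
    "COLUMNS",
    "QuantTable",
    "QuantTableError",
    "MissingMeasurementError",
    "read_quant_table",
    "write_quant_table",
    "aggregate_ptp",
]

COLUMNS = (
    "blot_id",
    "probe",
    "sample_id",
    "lane",
    "species",
    "signal",
    "experiment_id",
    "condition",
)

KEY = ["blot_id", "probe", "lane", "species"]

PTP_MEMBERS = ("47S", "46S", "45S")


class QuantTableError(ValueError):
    """Malformed or inconsistent quantification data."""


class MissingMeasurementError(KeyError):
    """A requested (blot, lane, species) signal does not exist."""

    def __init__(self, blot_id: str, lane: int, species: str):
        super().__init__(f"no measurement for blot={blot_id!r} lane={lane} species={species!r}")
        self.blot_id, self.lane, self.species = blot_id, lane, species


@dataclass
class QuantTable:
    """Collection of signal measurements, backed by a pandas DataFrame."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise QuantTableError(f"missing columns: {missing}")
        self.frame = self.frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.frame["lane"] = self.frame["lane"].astype(int)
        self.frame["signal"] = self.frame["signal"].astype(float)
        self._check()

    def _check(self) -> None:
        f = self.frame
        bad = f.index[f["signal"] < 0]
        if len(bad):
            raise QuantTableError(f"negative signal in row(s) {list(bad)}")
        bad = f.index[f["lane"] < 1]
        if len(bad):
            raise QuantTableError(f"non-positive lane in row(s) {list(bad)}")
        dup = f.duplicated(subset=KEY)
        if dup.any():
            raise QuantTableError(
                f"duplicate (blot, probe, lane, species) in row(s) {list(f.index[dup])}"
            )
        samples = f.groupby(["blot_id", "lane"])["sample_id"].nunique()
        clash = samples[samples > 1]
        if len(clash):
            raise QuantTableError(
                "a (blot, lane) must hold exactly one sample; violated at "
                + ", ".join(f"{b}/lane {ln}" for b, ln in clash.index)
            )

    def validate_species(self, graph: PathwayGraph) -> None:
        known = set(graph.species) | {"PTP"}
        bad = self.frame[~self.frame["species"].isin(known)]
        if len(bad):
            rows = ", ".join(f"row {i}: {s!r}" for i, s in bad["species"].items())
            raise QuantTableError(f"unknown species ({rows})")

    # -- queries ------------------------------------------------------------

    def lane_signal(self, blot_id: str, lane: int, species: str) -> float:
        """The stored signal; never imputed across blots or lanes."""
        f = self.frame
        hit = f[(f["blot_id"] == blot_id) & (f["lane"] == lane) & (f["species"] == species)]
        if len(hit) == 0:
            raise MissingMeasurementError(blot_id, lane, species)
        return float(hit["signal"].iloc[0])

    def has(self, blot_id: str, lane: int, species: str) -> bool:
        f = self.frame
        return bool(
            ((f["blot_id"] == blot_id) & (f["lane"] == lane) & (f["species"] == species)).any()
        )

    def lanes_for_sample(self, sample_id: str) -> pd.DataFrame:
        f = self.frame
        return f[f["sample_id"] == sample_id]

    def __len__(self) -> int:
        return len(self.frame)


def lane_signal(table: QuantTable, blot_id: str, lane: int, species: str) -> float:
    return table.lane_signal(blot_id, lane, species)


def read_quant_table(path, graph: PathwayGraph | None = None) -> QuantTable:
    """Read and validate a quant-table CSV.

    Unknown species (when a graph is given), negative signals and duplicate
    keys are reported with row numbers.
    """
    frame = pd.read_csv(path, comment="#", dtype={"blot_id": str, "probe": str, "sample_id": str})
    table = QuantTable(frame)
    if graph is not None:
        table.validate_species(graph)
    return table


def write_quant_table(table: QuantTable, path) -> None:
    table.frame.to_csv(path, index=False)


def aggregate_ptp(table: QuantTable) -> QuantTable:
    """Add PTP rows where 47S/46S/45S were quantified separately.

    The 47S, 46S and 45S pre-rRNAs co-migrate on agarose gels; their total
    hybridization signal is what RAMP uses as the 'primary transcript plus'
    denominator.  Where a (blot, lane) carries the three member rows, they
    are summed into a single PTP row and the member rows are consumed.
    Direct PTP rows pass through unchanged.  A lane holding both a direct
    PTP row and member rows is ambiguous and rejected.  The operation is
    idempotent.
    """
    f = table.frame
    out_rows = []
    for (blot, lane), grp in f.groupby(["blot_id", "lane"], sort=False):
        present = set(grp["species"])
        has_direct = "PTP" in present
        members = [m for m in PTP_MEMBERS if m in present]
        if has_direct and members:
            raise QuantTableError(
                f"blot {blot!r} lane {lane}: both a direct PTP row and member rows "
                f"({members}) are present"
            )
        if members:
            if len(members) < 3:
                raise QuantTableError(
                    f"blot {blot!r} lane {lane}: PTP members incomplete ({members}); "
                    "need 47S, 46S and 45S"
                )
            member_rows = grp[grp["species"].isin(PTP_MEMBERS)]
            ptp = member_rows.iloc[0].copy()
            ptp["species"] = "PTP"
            ptp["signal"] = float(member_rows["signal"].sum())
            out_rows.append(grp[~grp["species"].isin(PTP_MEMBERS)])
            out_rows.append(ptp.to_frame().T)
        else:
            out_rows.append(grp)
    frame = pd.concat(out_rows, ignore_index=True)
    frame["lane"] = frame["lane"].astype(int)
    frame["signal"] = frame["signal"].astype(float)
    return QuantTable(frame)
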