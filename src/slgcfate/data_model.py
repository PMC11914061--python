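"""Shared record types and tabular I/O.

The package works with two tables: a *cell table* with one row per
stomatal-lineage ground cell (SLGC) at birth, and a *trajectory table*
holding time-stamped nuclear fluorescence for tracked cells.  Both are
plain CSV (comma-separated, UTF-8, ``.`` decimal, mandatory header) so
that fixtures and outputs are diffable and bit-stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ACD",
    "DIFF",
    "UNKNOWN",
    "BEHAVIOURS",
    "CellRecord",
    "Trajectory",
    "RunConfig",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "read_cell_table",
    "write_cell_table",
    "read_trajectory_table",
    "write_trajectory_table",
]

# Behaviour labels.  ACD = asymmetric cell division (the SLGC divided
# again), DIFF = differentiation into a pavement cell, UNKNOWN = outcome
# not captured by the end of tracking.
ACD = "ACD"
DIFF = "DIFF"
UNKNOWN = "UNKNOWN"
BEHAVIOURS = (ACD, DIFF, UNKNOWN)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell of an input table could not be parsed as the expected type."""


class ValidationError(ValueError):
    """Parsed values violate a record invariant."""


CELL_COLUMNS = [
    "cell_id",
    "individual",
    "mother_id",
    "birth_time_min",
    "birth_area_um2",
    "perimeter_um",
    "pos_x_um",
    "pos_y_um",
    "n_neighbours_total",
    "n_sig_neighbours",
    "n_meristemoid_nb",
    "n_gmc_nb",
    "n_stoma_nb",
    "sig_contact_fraction",
    "behaviour",
]

_NUMERIC_CELL_COLUMNS = [
    "birth_time_min",
    "birth_area_um2",
    "perimeter_um",
    "pos_x_um",
    "pos_y_um",
    "n_neighbours_total",
    "n_sig_neighbours",
    "n_meristemoid_nb",
    "n_gmc_nb",
    "n_stoma_nb",
    "sig_contact_fraction",
]

_COUNT_CELL_COLUMNS = [
    "n_neighbours_total",
    "n_sig_neighbours",
    "n_meristemoid_nb",
    "n_gmc_nb",
    "n_stoma_nb",
]

TRAJECTORY_COLUMNS = ["cell_id", "time_min", "intensity_au"]


@dataclass(frozen=True)
class CellRecord:
    """One SLGC at birth.

    Attributes
    ----------
    cell_id, individual, mother_id
        Opaque identifiers; ``mother_id`` is ``None`` when the mother was
        not tracked.
    birth_time_min
        Minutes since the start of the experiment.
    birth_area_um2, perimeter_um
        Cell geometry at birth (µm², µm).
    pos_x_um, pos_y_um
        Leaf coordinates (µm); decorative for simulation purposes.
    n_neighbours_total
        All adjacent cells.
    n_sig_neighbours
        Signaling neighbours: adjacent meristemoids + GMCs + stomata.
    sig_contact_fraction
        Fraction of the perimeter touching signaling neighbours, in [0, 1].
    behaviour
        ``ACD``, ``DIFF`` or ``UNKNOWN``.
    """

    cell_id: str
    individual: str
    mother_id: str | None
    birth_time_min: float
    birth_area_um2: float
    perimeter_um: float
    pos_x_um: float
    pos_y_um: float
    n_neighbours_total: int
    n_sig_neighbours: int
    n_meristemoid_nb: int
    n_gmc_nb: int
    n_stoma_nb: int
    sig_contact_fraction: float
    behaviour: str

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.birth_area_um2 > 0:
            problems.append("birth_area_um2 must be > 0")
        if not self.perimeter_um > 0:
            problems.append("perimeter_um must be > 0")
        if self.n_sig_neighbours != (
            self.n_meristemoid_nb + self.n_gmc_nb + self.n_stoma_nb
        ):
            problems.append(
                "n_sig_neighbours must equal n_meristemoid_nb + n_gmc_nb + n_stoma_nb"
            )
        if self.n_sig_neighbours > self.n_neighbours_total:
            problems.append("n_sig_neighbours must be <= n_neighbours_total")
        if not 0.0 <= self.sig_contact_fraction <= 1.0:
            problems.append("sig_contact_fraction must be in [0, 1]")
        if self.behaviour not in BEHAVIOURS:
            problems.append(f"behaviour must be one of {BEHAVIOURS}")
        return problems


@dataclass
class Trajectory:
    """Time-stamped fluorescence for one tracked cell.

    Times are minutes from cell birth (first sample re-based to 0) and
    strictly increasing; intensities are arbitrary units, finite and >= 0.
    ``nuclear_area_um2`` is optional and aligned with ``times`` when set.
    """

    cell_id: str
    times: np.ndarray
    intensities: np.ndarray
    nuclear_area_um2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities must align")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"times not strictly increasing for {self.cell_id}")
        if np.any(~np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValidationError(f"intensities must be finite and >= 0 for {self.cell_id}")
        if self.nuclear_area_um2 is not None:
            self.nuclear_area_um2 = np.asarray(self.nuclear_area_um2, dtype=float)
            if self.nuclear_area_um2.shape != self.times.shape:
                raise ValidationError("nuclear_area_um2 must align with times")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass
class RunConfig:
    """Run-level configuration: seed, cohort shape, and parameter blocks.

    A fixed ``seed`` makes every downstream output reproducible.  Extra
    module-specific parameters live in ``blocks`` keyed by module name.
    """

    seed: int = 0
    n_individuals: int = 4
    n_mothers: int = 1000  # mother cells per individual
    out_dir: str = "."
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"blocks"}
        kwargs = {k: raw[k] for k in known if k in raw}
        blocks = {k: v for k, v in raw.items() if k not in known}
        return cls(blocks=blocks, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "n_individuals": self.n_individuals,
            "n_mothers": self.n_mothers,
            "out_dir": str(self.out_dir),
        }
        data.update(self.blocks)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_cell_table(path: str | Path) -> list[CellRecord]:
    """Read a cell table CSV into validated :class:`CellRecord` objects.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If a numeric field fails to parse (message carries the row number).
    ValidationError
        If any record violates an invariant (message lists offending rows).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, CELL_COLUMNS, path)

    records: list[CellRecord] = []
    violations: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = {}
        for col in _NUMERIC_CELL_COLUMNS:
            text = getattr(row, col)
            try:
                values[col] = float(text)
            except ValueError:
                raise ParseError(
                    f"{path}: row {i + 1}: non-numeric value {text!r} in column {col!r}"
                ) from None
        for col in _COUNT_CELL_COLUMNS:
            if values[col] != int(values[col]):
                raise ParseError(
                    f"{path}: row {i + 1}: column {col!r} must be an integer count"
                )
            values[col] = int(values[col])
        rec = CellRecord(
            cell_id=row.cell_id,
            individual=row.individual,
            mother_id=row.mother_id or None,
            behaviour=row.behaviour,
            **values,
        )
        problems = rec.validate()
        if problems:
            violations.append(f"row {i + 1} ({rec.cell_id}): " + "; ".join(problems))
        records.append(rec)
    if violations:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(violations))
    return records


def write_cell_table(records: Iterable[CellRecord], path: str | Path) -> None:
    """Write records to CSV so that a re-read round-trips field-for-field."""
    rows = []
    for rec in records:
        problems = rec.validate()
        if problems:
            raise ValidationError(f"{rec.cell_id}: " + "; ".join(problems))
        d = dataclasses.asdict(rec)
        d["mother_id"] = rec.mother_id if rec.mother_id is not None else ""
        rows.append(d)
    df = pd.DataFrame(rows, columns=CELL_COLUMNS)
    df.to_csv(path, index=False)


def cell_records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Convenience: records as a DataFrame with the canonical columns."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CELL_COLUMNS)


def read_trajectory_table(path: str | Path) -> list[Trajectory]:
    """Read a long-format trajectory CSV.

    Samples are grouped by ``cell_id``, sorted by time, and re-based so the
    first sample of each cell sits at t = 0 (birth).
    """
    df = pd.read_csv(path)
    _check_columns(df, TRAJECTORY_COLUMNS, path)
    dup = df.duplicated(subset=["cell_id", "time_min"])
    if dup.any():
        pairs = df.loc[dup, ["cell_id", "time_min"]].itertuples(index=False)
        listing = ", ".join(f"({c}, {t})" for c, t in pairs)
        raise ValidationError(f"{path}: duplicate (cell_id, time) pair(s): {listing}")
    if (df["intensity_au"] < 0).any():
        bad = df.index[df["intensity_au"] < 0] + 1
        raise ValidationError(f"{path}: negative intensity at row(s) {list(bad)}")

    has_area = "nuclear_area_um2" in df.columns
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        out.append(
            Trajectory(
                cell_id=str(cell_id),
                times=times - times[0],
                intensities=grp["intensity_au"].to_numpy(dtype=float),
                nuclear_area_um2=(
                    grp["nuclear_area_um2"].to_numpy(dtype=float) if has_area else None
                ),
            )
        )
    return out


def write_trajectory_table(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    frames = []
    for traj in trajectories:
        d = {
            "cell_id": traj.cell_id,
            "time_min": traj.times,
            "intensity_au": traj.intensities,
        }
        if traj.nuclear_area_um2 is not None:
            d["nuclear_area_um2"] = traj.nuclear_area_um2
        frames.append(pd.DataFrame(d))
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    """Write fitted parameters / summaries as pretty JSON."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
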