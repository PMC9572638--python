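"""Reading and writing long-format trial tables and published agronomy tables.

Trial observations are kept in long format: one row per
(genotype, water regime, harvest round, replicate, trait) combination.
Published yield tables carry Fisher-LSD significance letters appended to
each numeric cell (e.g. ``"48.48ij"``); :func:`parse_published_value`
separates the number from the letter group.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import IntegrityError, ParseError

#: Water regimes: rainfed wet season, moderate (20% volumetric soil water)
#: and severe (10%) dry-season water stress.
REGIMES = ("wet", "MWS", "SWS")

#: Trait codes used across the analysis (morphology, physiology, agronomy,
#: feed quality).
TRAITS = (
    "PH", "LL", "LW", "IL", "ST", "TN", "FvFm", "PI", "TFW", "TDW",
    "LSR", "WUE", "NDF", "ADF", "ADL", "OM", "CP", "IVOMD", "Me",
)

KEY_COLUMNS = ("genotype", "regime", "harvest", "replicate", "trait")
COLUMNS = KEY_COLUMNS + ("value",)


@dataclass(frozen=True)
class TrialRecord:
    """One observation of one trait on one plot.

    Missing observations are absent records, never sentinel numbers.
    """

    genotype: str
    regime: str
    harvest: int
    replicate: int
    trait: str
    value: float

    def key(self) -> tuple:
        return (self.genotype, self.regime, self.harvest, self.replicate, self.trait)


@dataclass(frozen=True)
class PublishedCell:
    """A printed table cell: numeric value plus trailing significance letters."""

    raw: str
    value: float
    letters: str


_CELL_RE = re.compile(r"^([0-9]+(?:\.[0-9]+)?)([a-z]*)$")


def parse_published_value(raw: str) -> PublishedCell:
    """Split a printed cell like ``"68.05a"`` into value 68.05 and letters "a".

    Genotype-name footnote markers (``*``/``**``) are stripped before
    parsing. Raises :class:`ParseError` when no leading decimal number is
    present.
    """
    cleaned = raw.strip().rstrip("*").strip()
    m = _CELL_RE.match(cleaned)
    if m is None:
        raise ParseError(f"cannot parse published cell {raw!r}: "
                         "expected a decimal number followed by lowercase letters")
    return PublishedCell(raw=cleaned, value=float(m.group(1)), letters=m.group(2))


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a record collection (row order kept)."""
    return pd.DataFrame([r.__dict__ for r in records], columns=COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Convert a long-format DataFrame to records, validating invariants."""
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"trial table is missing columns: {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            value = float(row.value)
            harvest = int(row.harvest)
            replicate = int(row.replicate)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed numeric value in row {i}: {exc}") from exc
        if not math.isfinite(value):
            raise ParseError(f"non-finite value in row {i}: {row.value!r}")
        if harvest < 1 or replicate < 1:
            raise ParseError(f"harvest/replicate indices must be >= 1 (row {i})")
        records.append(TrialRecord(str(row.genotype), str(row.regime),
                                   harvest, replicate, str(row.trait), value))
    seen: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        k = rec.key()
        if k in seen:
            raise IntegrityError(
                f"duplicate observation key {k} at rows {seen[k]} and {i}")
        seen[k] = i
    return records


def read_trial_table(path: str | Path, delimiter: str = ",") -> list[TrialRecord]:
    """Read a long-format trial CSV into validated records.

    The file must carry a header naming the five key columns plus ``value``.
    Duplicate observation keys raise :class:`IntegrityError`; malformed
    numbers raise :class:`ParseError` naming the row.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    return frame_to_records(frame)


def write_trial_table(records: Sequence[TrialRecord], path: str | Path,
                      delimiter: str = ",") -> None:
    """Write records as a long-format CSV (inverse of :func:`read_trial_table`)."""
    records_to_frame(records).to_csv(path, sep=delimiter, index=False)


_TABLE5_VALUE_COLS = ("mws_tdw", "mws_cpy", "sws_tdw", "sws_cpy")
N_TABLE5_GENOTYPES = 84


def table5_fixture_path() -> Path:
    """Location of the packaged transcription of the published annual-yield table."""
    return Path(resources.files("metstab").joinpath("data/table5_annual_yield.csv"))


def load_table5(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published 84-genotype annual TDW / CPY table.

    Columns: genotype, per-regime annual total dry weight (t/ha/year) and
    crude protein yield with their significance-letter columns, and boolean
    top-CPY flags. Every numeric cell is re-validated through
    :func:`parse_published_value`. A row count other than 84 raises
    :class:`IntegrityError`.
    """
    if path is None:
        path = table5_fixture_path()
    df = pd.read_csv(path, dtype={"genotype": str})
    if len(df) != N_TABLE5_GENOTYPES:
        raise IntegrityError(
            f"published yield table must have {N_TABLE5_GENOTYPES} rows, got {len(df)}")
    if df["genotype"].duplicated().any():
        raise IntegrityError("duplicate genotype names in published yield table")
    for col in _TABLE5_VALUE_COLS:
        letters = df[f"{col}_letters"].fillna("")
        for i, (v, s) in enumerate(zip(df[col], letters)):
            cell = parse_published_value(f"{v:g}{s}")
            if cell.value != float(v) or cell.letters != s:
                raise IntegrityError(
                    f"cell round-trip failed for {col} row {i}: {v!r}/{s!r}")
    for col in ("top_cpy_mws", "top_cpy_sws"):
        df[col] = df[col].astype(bool)
    return df
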