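"""Reading, writing and filtering per-frame energy tables.

Tables are delimited text with one row per frame and columns drawn from
{frame, elec, vdw, total, rmsd}; either ``total`` or ``elec`` + ``vdw``
must be resolvable. An explicit energy-unit tag is required — Amber-
ecosystem tools emit kcal/mol while entropies here are discussed in
kJ/mol, and silently mixing the two is the most likely real-world bug.
Written tables carry the unit in a comment header so round-trips are
self-describing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KCAL_TO_KJ
from .series import EnergySeries, interaction_energy

__all__ = [
    "EnergyTableDialect",
    "read_energy_table",
    "write_energy_table",
    "sniff_dialect",
    "filter_frames",
    "rmsd_below",
    "drop_first",
]

_KNOWN_COLUMNS = ("frame", "elec", "vdw", "total", "rmsd")
_UNITS = ("kJ/mol", "kcal/mol")


@dataclass(frozen=True)
class EnergyTableDialect:
    """How to interpret a delimited energy table.

    delimiter : field separator; ``None`` means any whitespace.
    columns : map from canonical names (frame/elec/vdw/total/rmsd) to
        the column names in the file; any subset, but either ``total``
        or both ``elec`` and ``vdw`` must be present.
    comment : comment-line prefix.
    unit : ``"kJ/mol"`` or ``"kcal/mol"`` — required, never defaulted
        silently between unit systems.
    """

    delimiter: Optional[str] = None
    columns: Dict[str, str] = field(
        default_factory=lambda: {c: c for c in _KNOWN_COLUMNS}
    )
    comment: str = "#"
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        resolvable = "total" in self.columns or (
            "elec" in self.columns and "vdw" in self.columns
        )
        if not resolvable:
            raise ValueError(
                "dialect must map either 'total' or both 'elec' and 'vdw'"
            )
        if self.unit is not None and self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")


_UNIT_RE = re.compile(r"unit\s*[:=]\s*(kJ/mol|kcal/mol)", re.IGNORECASE)


def sniff_dialect(path: Union[str, Path]) -> EnergyTableDialect:
    """Guess delimiter, columns and unit from a table's header.

    The unit is read from a ``# unit: ...`` comment; files without one
    must be read with an explicit dialect (the reader refuses to guess
    between kJ/mol and kcal/mol).
    """
    path = Path(path)
    unit = None
    header = None
    with path.open() as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                m = _UNIT_RE.search(stripped)
                if m:
                    unit = "kJ/mol" if m.group(1).lower() == "kj/mol" else "kcal/mol"
                continue
            header = stripped
            break
    if header is None:
        raise ValueError(f"{path}: no header row found")
    delimiter = None
    for cand in (",", "\t", ";"):
        if cand in header:
            delimiter = cand
            break
    fields = [f.strip().lower() for f in re.split(delimiter or r"\s+", header)]
    columns = {c: c for c in fields if c in _KNOWN_COLUMNS}
    if not columns:
        raise ValueError(
            f"{path}: header {header!r} contains none of the known "
            f"columns {_KNOWN_COLUMNS}"
        )
    return EnergyTableDialect(delimiter=delimiter, columns=columns, unit=unit)


def read_energy_table(
    path: Union[str, Path],
    dialect: Optional[EnergyTableDialect] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    frame_spacing: Optional[float] = None,
) -> EnergySeries:
    """Read a per-frame energy table into an EnergySeries (kJ/mol).

    With ``dialect=None`` the file layout and unit are sniffed from the
    header; kcal/mol energies are converted (×4.184). Frames keep file
    order; frame index and rmsd, when present, are carried into
    ``labels``.
    """
    path = Path(path)
    if dialect is None:
        dialect = sniff_dialect(path)
    elif dialect.unit is None:
        sniffed = sniff_dialect(path)
        dialect = replace(dialect, unit=sniffed.unit)
    if dialect.unit is None:
        raise ValueError(
            f"{path}: energy unit unknown — add a '# unit: kJ/mol' (or "
            "kcal/mol) header line or pass a dialect with an explicit unit"
        )
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter if dialect.delimiter else r"\s+",
            comment=dialect.comment,
            float_precision="round_trip",
        )
    except Exception as exc:  # pandas errors carry line info
        raise ValueError(f"{path}: could not parse table: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    if df.empty:
        raise ValueError(f"{path}: table has no data rows")

    def col(name: str) -> Optional[pd.Series]:
        mapped = dialect.columns.get(name)
        if mapped is None or mapped.lower() not in df.columns:
            return None
        series = pd.to_numeric(df[mapped.lower()], errors="coerce")
        if series.isna().any():
            bad = int(series.index[series.isna()][0]) + 2  # +header +1-based
            raise ValueError(f"{path}: non-numeric value in column "
                             f"{mapped!r} near line {bad}")
        return series

    scale = KCAL_TO_KJ if dialect.unit == "kcal/mol" else 1.0
    total = col("total")
    labels = pd.DataFrame()
    frame = col("frame")
    labels["frame"] = frame if frame is not None else np.arange(1, len(df) + 1)
    rmsd = col("rmsd")
    if rmsd is not None:
        labels["rmsd"] = rmsd
    if total is not None:
        return EnergySeries(total.to_numpy() * scale, temperature, frame_spacing, labels)
    elec, vdw = col("elec"), col("vdw")
    if elec is None or vdw is None:
        raise ValueError(
            f"{path}: need a 'total' column or both 'elec' and 'vdw' "
            f"(found {list(df.columns)})"
        )
    return interaction_energy(
        elec.to_numpy() * scale, vdw.to_numpy() * scale,
        temperature, frame_spacing, labels,
    )


def write_energy_table(
    series: EnergySeries,
    path: Union[str, Path],
    delimiter: str = "\t",
) -> None:
    """Write a series as a self-describing kJ/mol table (round-trip safe).

    Values are written with shortest round-trip formatting (and read
    back with round-trip float parsing), so a write/read cycle
    reproduces them bit-exactly.
    """
    path = Path(path)
    labels = series.labels
    frame = (
        labels["frame"].to_numpy()
        if labels is not None and "frame" in labels
        else np.arange(1, len(series) + 1)
    )
    cols = {"frame": frame, "total": series.values}
    if labels is not None and "rmsd" in labels:
        cols["rmsd"] = labels["rmsd"].to_numpy()
    with path.open("w") as fh:
        fh.write("# unit: kJ/mol\n")
        if series.frame_spacing is not None:
            fh.write(f"# frame_spacing_ps: {series.frame_spacing!r}\n")
        fh.write(f"# temperature_K: {series.temperature!r}\n")
        fh.write(delimiter.join(cols.keys()) + "\n")
        for row in zip(*cols.values()):
            fh.write(delimiter.join(
                repr(float(v)) if isinstance(v, float) else str(v) for v in row
            ) + "\n")


def filter_frames(
    series: EnergySeries,
    predicate: Callable[[pd.DataFrame], np.ndarray],
) -> Tuple[EnergySeries, int]:
    """Keep frames where ``predicate(labels)`` is True.

    The predicate receives the per-frame labels DataFrame and returns a
    boolean mask; order is preserved and metadata retained. Returns the
    filtered series and the number of removed frames.
    """
    if series.labels is None:
        raise ValueError("series has no labels to filter on")
    try:
        mask = np.asarray(predicate(series.labels), dtype=bool)
    except KeyError as exc:
        raise ValueError(
            f"predicate references a label missing from the series: {exc}"
        ) from exc
    if mask.shape != (len(series),):
        raise ValueError("predicate must return one boolean per frame")
    return series.subset(mask), int((~mask).sum())


def rmsd_below(threshold: float) -> Callable[[pd.DataFrame], np.ndarray]:
    """Predicate keeping frames with ligand rmsd ≤ threshold (Å)."""
    def predicate(labels: pd.DataFrame) -> np.ndarray:
        return labels["rmsd"].to_numpy() <= threshold
    return predicate


def drop_first(k: int) -> Callable[[pd.DataFrame], np.ndarray]:
    """Predicate discarding the first k frames (equilibration cut)."""
    def predicate(labels: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(labels), dtype=bool)
        mask[:k] = False
        return mask
    return predicate
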