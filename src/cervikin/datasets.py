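"""Packaged cohort tables and loaders.

The three CSV fixtures transcribe the study's printed cohort tables:
baseline characteristics with the per-timepoint sequence outcome (10
individuals), ranges of motion per individual and timepoint, and the
three-individual external-validation group (whose recordings cover only the
second half of extension, so ranges are not directly comparable). Values are
the printed per-individual cells; average rows are recomputed, not stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from cervikin.records import CohortRecord
from cervikin.segments import SEGMENTS

_SROM_COLS = {"C4-C5": "srom_c4c5", "C5-C6": "srom_c5c6", "C6-C7": "srom_c6c7"}
_KS_COLS = {"C4-C5": "ks_c4c5", "C5-C6": "ks_c5c6", "C6-C7": "ks_c6c7"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("cervikin.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_baseline() -> pd.DataFrame:
    """Baseline characteristics: sex, age, NDI, Kellgren scores, sequence +/-."""
    return _read("table1_baseline.csv")


def load_rom() -> pd.DataFrame:
    """Per-individual tROM and sROM (degrees) at T1 and T2, long format."""
    return _read("table2_rom.csv")


def load_external() -> pd.DataFrame:
    """External-validation group: ROM and sequence outcome (second half of
    extension only)."""
    return _read("table4_external.csv")


def cohort_records() -> list[CohortRecord]:
    """Join the baseline and ROM tables into CohortRecord objects."""
    base = load_baseline()
    rom = load_rom()
    records = []
    for row in base.itertuples():
        rid = str(row.individual)
        sub = rom[rom["individual"].astype(str) == rid]
        srom = {}
        trom = {}
        for r in sub.itertuples():
            srom[r.timepoint] = {seg: float(getattr(r, col)) for seg, col in _SROM_COLS.items()}
            trom[r.timepoint] = float(r.trom)
        records.append(CohortRecord(
            id=rid,
            sex=str(row.sex),
            age=float(row.age),
            ndi_points=float(row.ndi_points),
            ndi_pct=float(row.ndi_pct),
            ks={seg: int(getattr(row, col)) for seg, col in _KS_COLS.items()},
            srom=srom,
            trom=trom,
            sequence={"T1": str(row.sequence_t1), "T2": str(row.sequence_t2)},
        ))
    return records


def srom_column(df: pd.DataFrame, timepoint: str, segment: str) -> pd.Series:
    """One sROM column of a ROM table (degrees) at a timepoint."""
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    sub = df[df["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no rows for timepoint {timepoint!r}")
    return sub[_SROM_COLS[segment]].reset_index(drop=True)


def trom_column(df: pd.DataFrame, timepoint: str) -> pd.Series:
    sub = df[df["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no rows for timepoint {timepoint!r}")
    return sub["trom"].reset_index(drop=True)
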