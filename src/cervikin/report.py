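"""Cohort report tables: recomputed average rows with provenance footer."""

from __future__ import annotations

import pandas as pd

from cervikin import datasets
from cervikin.classification import cohort_prevalence
from cervikin.segments import SEGMENTS
from cervikin.stats import summarize

_SROM_COLS = {"C4-C5": "srom_c4c5", "C5-C6": "srom_c5c6", "C6-C7": "srom_c6c7"}


def _footer(seed=None, config=None) -> str:
    from cervikin import __version__

    parts = [f"cervikin {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config={config}")
    return "Generated by " + ", ".join(parts)


def baseline_report(df: pd.DataFrame | None = None) -> dict:
    """Baseline summary: mean age, NDI, Kellgren scores, sequence prevalence."""
    if df is None:
        df = datasets.load_baseline()
    rows = {
        "age": summarize(df["age"], decimals=0),
        "ndi_points": summarize(df["ndi_points"], decimals=0),
        "ks_c4c5": summarize(df["ks_c4c5"], decimals=1),
        "ks_c5c6": summarize(df["ks_c5c6"], decimals=1),
        "ks_c6c7": summarize(df["ks_c6c7"], decimals=1),
    }
    prevalence = {
        tp: cohort_prevalence(df[f"sequence_{tp.lower()}"].tolist()) for tp in ("T1", "T2")
    }
    return {"summary": rows, "prevalence_pct": prevalence, "n": len(df)}


def rom_report(df: pd.DataFrame | None = None, decimals: int = 1) -> pd.DataFrame:
    """Average [min;max] row per tROM/sROM column and timepoint."""
    if df is None:
        df = datasets.load_rom()
    rows = []
    for tp in sorted(df["timepoint"].unique()):
        sub = df[df["timepoint"] == tp]
        row = {"timepoint": tp, "n": len(sub)}
        s = summarize(sub["trom"], decimals)
        row["trom_mean"] = s.mean
        row["trom"] = s.text
        for seg in SEGMENTS:
            s = summarize(sub[_SROM_COLS[seg]], decimals)
            row[f"srom_mean[{seg}]"] = s.mean
            row[f"srom[{seg}]"] = s.text
        rows.append(row)
    return pd.DataFrame(rows)


def report_markdown(table: str = "rom", seed=None) -> str:
    """Markdown twin of a cohort table's average row(s), with provenance."""
    if table == "baseline":
        rep = baseline_report()
        lines = ["| column | average [min;max] |", "| --- | --- |"]
        for name, s in rep["summary"].items():
            lines.append(f"| {name} | {s.text} |")
        for tp, p in rep["prevalence_pct"].items():
            lines.append(f"| sequence prevalence {tp} | {p:g}% |")
        body = "\n".join(lines)
    elif table in ("rom", "external"):
        df = datasets.load_rom() if table == "rom" else datasets.load_external()
        body = rom_report(df).to_markdown(index=False)
        if table == "external":
            prev = {
                tp: cohort_prevalence(
                    df[df["timepoint"] == tp]["sequence"].tolist())
                for tp in sorted(df["timepoint"].unique())
            }
            body += "\n\nSequence prevalence: " + ", ".join(
                f"{tp} {p:g}%" for tp, p in prev.items())
    else:
        raise ValueError(f"unknown table {table!r}; use baseline|rom|external")
    return body + "\n\n" + _footer(seed=seed) + "\n"
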