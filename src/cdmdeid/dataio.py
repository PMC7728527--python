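"""CSV readers/writers for CDM exports, run outputs and manifests.

The on-disk dialect is fixed: RFC-4180 quoting, comma delimiter, UTF-8, one
file per table named ``<TABLE>.csv`` (tab-delimited accepted on input via
``delimiter="\\t"``).  Values are read as strings; the empty field is the
on-disk null/removed representation.  Table names are normalized to upper
case and column names to lower case at load, since CDM exports vary by DBMS.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataFormatError
from .risk import RiskReport, format_percentage


@dataclass
class Dataset:
    """In-memory collection of CDM tables plus load provenance."""

    tables: dict
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.tables)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name.upper()]

    def items(self):
        return self.tables.items()


def read_table_csv(path, delimiter: str = ",") -> pd.DataFrame:
    """Read one table file, validating rectangular shape.

    A ragged row raises :class:`DataFormatError` naming the file and the
    1-based line number.  All values load as strings; empty fields stay "".
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DataFormatError(f"{path}: empty file, no header row")
        header = [h.strip().lower() for h in header]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise DataFormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {len(header)})"
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=header, dtype=str)


def load_dataset(
    directory,
    expected_tables: Sequence[str] | None = None,
    required_tables: Sequence[str] = (),
    delimiter: str = ",",
) -> Dataset:
    """Load ``<TABLE>.csv`` files (case-insensitive names) from a directory.

    With ``expected_tables`` given, only those files are read; missing
    optional tables are recorded in provenance, missing ``required_tables``
    raise.  Without it, every ``*.csv`` in the directory is loaded.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DataFormatError(f"not a directory: {directory}")
    by_upper = {p.stem.upper(): p for p in sorted(directory.glob("*.csv"))}
    # case-insensitive glob fallback for .CSV etc.
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() == ".csv":
            by_upper.setdefault(p.stem.upper(), p)

    names = [t.upper() for t in expected_tables] if expected_tables else sorted(by_upper)
    tables, missing = {}, []
    for t in names:
        if t in by_upper:
            tables[t] = read_table_csv(by_upper[t], delimiter)
        else:
            missing.append(t)
    required = {t.upper() for t in required_tables}
    missing_required = sorted(required & set(missing))
    if missing_required:
        raise DataFormatError(f"missing required tables: {', '.join(missing_required)}")
    return Dataset(
        tables=tables,
        provenance={
            "directory": str(directory),
            "delimiter": delimiter,
            "files": {t: str(by_upper[t]) for t in tables},
            "missing_optional": missing,
        },
    )


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n",
              encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _report_pair_dict(pair: Mapping) -> dict:
    return {phase: r.to_dict() for phase, r in pair.items()}


def render_summary(reports: Mapping) -> str:
    """Text Before/After summary, one block per table."""
    lines = ["table\tphase\trecords_at_risk(%)\thighest_risk(%)\tsuccess_rate(%)"]
    for table in sorted(reports):
        for phase in ("before", "after"):
            r: RiskReport = reports[table][phase]
            lines.append(
                f"{table}\t{phase}\t{format_percentage(r.records_at_risk)}"
                f"\t{format_percentage(r.highest_risk)}"
                f"\t{format_percentage(r.success_rate)}"
            )
    return "\n".join(lines) + "\n"


def write_outputs(result, reports: Mapping, out_directory, seed: int | None = None) -> dict:
    """Write anonymized tables, risk reports, summary and run log.

    Returns the manifest: one entry per file with its sha256 content hash.
    ``result`` may be None (analysis-only runs: reports without tables).
    """
    out = Path(out_directory)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if result is not None:
        for name, df in result.tables.items():
            p = out / f"{name}.csv"
            write_table_csv(df, p)
            written.append(p)

    rp = out / "risk_report.json"
    rp.write_text(
        json.dumps({t: _report_pair_dict(pair) for t, pair in reports.items()},
                   indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    written.append(rp)

    sp = out / "risk_summary.txt"
    sp.write_text(render_summary(reports), encoding="utf-8")
    written.append(sp)

    log = {"seed": seed}
    if result is not None:
        log["config"] = vars(result.config)
        log["chosen_nodes"] = {
            t: (list(n.levels) if n is not None else None)
            for t, n in result.chosen_nodes.items()
        }
        log["suppressed"] = result.suppressed
    lp = out / "run_log.json"
    lp.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n",
                  encoding="utf-8")
    written.append(lp)

    manifest = {p.name: _sha256(p) for p in written}
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
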