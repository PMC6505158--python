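"""Reading and writing frequency tables and allele-frequency files.

CSV dialect: comma-separated, header row, UTF-8, "." decimal point.
Frequency tables use columns ``genotype,frequency``; JSON files are
objects keyed by genotype string.  Allele-frequency files are CSV with
columns ``allele,frequency`` (or a bare one-column list of frequencies),
or a JSON array.
"""

from __future__ import annotations

import csv
import json
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .genotypes import Genotype, format_genotype, parse_genotype, validate_allele_frequencies

__all__ = [
    "write_frequency_table",
    "read_frequency_table",
    "read_allele_frequencies",
]


def _to_float(x) -> float:
    return float(x)


def write_frequency_table(
    freq: Mapping[Genotype, object],
    path,
    fmt: str = "csv",
    h: int | None = None,
    fractions: bool = False,
) -> None:
    """Write a genotype/phenotype frequency table as CSV or JSON."""
    path = Path(path)
    items = sorted(freq.items())
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            header = ["genotype", "frequency"]
            if fractions:
                header.append("fraction")
            w.writerow(header)
            for g, val in items:
                row = [format_genotype(g, h), repr(_to_float(val))]
                if fractions:
                    row.append(str(Fraction(val)) if not isinstance(val, float) else "")
                w.writerow(row)
    elif fmt == "json":
        payload = {format_genotype(g, h): _to_float(val) for g, val in items}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")


def read_frequency_table(path) -> dict[Genotype, float]:
    """Read a frequency table written by :func:`write_frequency_table`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return {parse_genotype(k): float(v) for k, v in payload.items()}
    out: dict[Genotype, float] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "genotype" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a CSV with a 'genotype' column")
        for row in reader:
            out[parse_genotype(row["genotype"])] = float(row["frequency"])
    return out


def read_allele_frequencies(path) -> tuple[float, ...]:
    """Read allele frequencies from CSV (allele,frequency) or a JSON array."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        values = [float(x) for x in json.loads(path.read_text())]
    else:
        values = []
        with path.open(newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise ValueError(f"{path}: empty allele-frequency file")
        start = 1 if rows[0] and not _is_number(rows[0][-1]) else 0
        for row in rows[start:]:
            if not row:
                continue
            values.append(float(row[-1]))
    p = tuple(values)
    validate_allele_frequencies(p)
    return p


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False
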