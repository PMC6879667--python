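"""Plain-text I/O: P-value vectors, correlation matrices, haplotype tables,
result TSVs, and the packaged worked-example fixture.

Everything is TSV or one-value-per-line text with '#' comment lines; no
binary formats. Numbers are written in the C locale ('.' decimal point).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .decorrelation import HaplotypeTable
from .pvalues import CombinedResult, PValueSet

__all__ = ["read_pvalues", "read_correlation", "read_haplotypes",
           "write_results", "results_frame", "mor_table8", "FIXTURES"]

# Reported SNP-level association P-values between mu-opioid receptor (OPRM1)
# variants and pain sensitivity; the packaged worked example.
_MOR_TABLE8 = (
    ("rs563649", 0.0007),
    ("rs9322446", 0.0941),
    ("rs2075572", 0.2957),
    ("rs533586", 0.7037),
    ("rs540825", 0.8171),
    ("rs675026", 0.8012),
    ("rs660756", 0.5745),
    ("rs677830", 0.9891),
    ("rs623956", 0.8308),
    ("rs609148", 0.8208),
    ("rs497332", 0.3139),
)


def mor_table8() -> pd.DataFrame:
    """The 11 mu-opioid receptor SNP P-values (pain sensitivity study)."""
    return pd.DataFrame(_MOR_TABLE8, columns=["snp", "pvalue"])


FIXTURES = {"mor_table8": mor_table8}


def read_pvalues(path, *, column: str | None = None) -> PValueSet:
    """Read a P-value vector from text.

    Accepts either one P-value per line, or a TSV with a named ``column``.
    '#'-prefixed lines are ignored. Errors name the offending line.
    """
    path = Path(path)
    if column is not None:
        df = pd.read_csv(path, sep="\t", comment="#")
        if column not in df.columns:
            raise ValueError(f"{path}: no column named {column!r}")
        return PValueSet(df[column].to_numpy(dtype=float))
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            # tolerate a trailing TSV field order: last numeric token wins
            token = text.split("\t")[-1] if "\t" in text else text
            try:
                v = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric P-value {token!r} on line {lineno}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{path}: P-value {v} outside [0, 1] on line {lineno}"
                )
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no P-values found")
    return PValueSet(values)


def read_correlation(path) -> np.ndarray:
    """Read an L x L correlation matrix from headerless TSV."""
    m = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    return m


def read_haplotypes(path) -> HaplotypeTable:
    """Read a haplotype table: TSV with columns ``haplotype`` and ``freq``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"haplotype": str})
    missing = {"haplotype", "freq"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return HaplotypeTable(df["haplotype"].tolist(), df["freq"].to_numpy(float))


def results_frame(results: Iterable[CombinedResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        notes = ";".join(f"{k}={v}" for k, v in r.extra.items()
                         if not isinstance(v, dict))
        rows.append(dict(method=r.method, k=r.k, statistic=r.statistic,
                         p_combined=r.p_combined, notes=notes))
    if not rows:
        raise ValueError("no results to write")
    return pd.DataFrame(rows, columns=["method", "k", "statistic",
                                       "p_combined", "notes"])


def write_results(results: Sequence[CombinedResult], path, *,
                  header_lines: Sequence[str] = ()) -> None:
    """Write combined-test results as TSV (deterministic column order).

    ``header_lines`` are emitted as '#'-prefixed metadata before the table.
    Refuses an empty result list rather than writing an empty file.
    """
    df = results_frame(results)
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
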