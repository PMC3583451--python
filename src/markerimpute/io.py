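"""Delimited-text readers and writers for genotype and phenotype data.

The default dialect matches the supplementary-file style of DArT/GBS panels:
tab-delimited, a header row of marker ids, first column the individual id,
``NA`` as the missing token, individuals as rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import Coding, GenotypeMatrix, PhenotypeVector


@dataclass
class GenotypeDialect:
    delimiter: str = "\t"
    header: bool = True
    missing: str = "NA"
    orientation: str = "individuals-as-rows"  # or "markers-as-rows"
    coding: Coding = Coding.MINUS1_1
    continuous: bool = False  # allow arbitrary reals (imputed output)


def read_genotype_matrix(path, dialect: GenotypeDialect | None = None) -> GenotypeMatrix:
    """Parse a delimited genotype file into a validated :class:`GenotypeMatrix`.

    Tokens equal to the dialect's missing token become masked cells; any other
    unparseable or out-of-coding token raises an error naming the offending
    row and column.
    """
    dialect = dialect or GenotypeDialect()
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.header else None,
            index_col=0,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no records")
    if dialect.orientation == "markers-as-rows":
        df = df.T
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok == dialect.missing:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable genotype {tok!r} at row "
                    f"{row_ids[i]!r}, column {col_ids[j]!r}"
                ) from None
    try:
        return GenotypeMatrix(
            values=values,
            individual_ids=row_ids,
            marker_ids=col_ids,
            coding=dialect.coding,
            continuous=dialect.continuous,
        )
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_genotype_matrix(gm: GenotypeMatrix, path, dialect: GenotypeDialect | None = None) -> None:
    dialect = dialect or GenotypeDialect(coding=gm.coding, continuous=gm.continuous)
    df = pd.DataFrame(gm.values, index=gm.individual_ids, columns=gm.marker_ids)
    if dialect.orientation == "markers-as-rows":
        df = df.T
    if gm.continuous:
        df.to_csv(path, sep=dialect.delimiter, na_rep=dialect.missing,
                  header=dialect.header, index=True)
        return

    # discrete codes are written without a trailing .0
    def fmt(x: float) -> str:
        if np.isnan(x):
            return dialect.missing
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    df.map(fmt).to_csv(path, sep=dialect.delimiter, header=dialect.header, index=True)


def read_phenotypes(path, delimiter: str = "\t") -> PhenotypeVector:
    """Read a two-column (id, value) phenotype file; header names the trait."""
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: expected columns (id, value)")
    return PhenotypeVector(
        values=df.iloc[:, 1].to_numpy(dtype=float),
        individual_ids=df.iloc[:, 0].astype(str).tolist(),
        trait_name=str(df.columns[1]),
    )


def write_phenotypes(ph: PhenotypeVector, path, delimiter: str = "\t") -> None:
    pd.DataFrame({"id": ph.individual_ids, ph.trait_name: ph.values}).to_csv(
        path, sep=delimiter, index=False
    )
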