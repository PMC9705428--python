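"""Tabular I/O for the cohort tables (tab-separated text with header rows)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "read_variants", "write_variants",
    "read_ld_table", "write_ld_table",
]


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Samples x SNPs matrix, 0/1/2 additive coding, NaN for missing."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> Path:
    genotypes.to_csv(path, sep="\t")
    return Path(path)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix of log-scale expression."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expression: pd.DataFrame, path: str | Path) -> Path:
    expression.to_csv(path, sep="\t")
    return Path(path)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> Path:
    clinical.to_csv(path, sep="\t")
    return Path(path)


def read_variants(path: str | Path) -> pd.DataFrame:
    """Variant table: rsid, chrom, pos_1based, ref, alt [, extras]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"rsid", "chrom", "pos_1based"} - set(df.columns)
    if missing:
        raise ValueError(f"variant table lacks columns {sorted(missing)}")
    return df


def write_variants(variants: pd.DataFrame, path: str | Path) -> Path:
    variants.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_ld_table(path: str | Path) -> pd.DataFrame:
    """LD pairs: tag, proxy, r2."""
    df = pd.read_csv(path, sep="\t")
    missing = {"tag", "proxy", "r2"} - set(df.columns)
    if missing:
        raise ValueError(f"LD table lacks columns {sorted(missing)}")
    return df


def write_ld_table(ld: pd.DataFrame, path: str | Path) -> Path:
    ld.to_csv(path, sep="\t", index=False)
    return Path(path)
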