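"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-separated.  BED-family files are header-less per
convention; matrices and tables carry headers.  All readers return pandas
frames with the package's lowercase column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "h3k27ac_rpm", "input_rpm"]
BEDPE_BASE = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "oe"]


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    pd.DataFrame(sizes.items(), columns=["chrom", "size"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path, n_cols: int = 3) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"][:n_cols]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    return df


def write_bed(df: pd.DataFrame, path, cols=("chrom", "start", "end")) -> None:
    df.loc[:, list(cols)].to_csv(path, sep="\t", header=False, index=False)


def read_peaks(path) -> pd.DataFrame:
    """BED6+2 peak file: columns 7-8 are H3K27ac and input RPM."""
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS, comment="#")
    return df[["chrom", "start", "end", "h3k27ac_rpm", "input_rpm"]]


def write_peaks(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"peak_{i}" for i in range(len(out))]
    out["score"] = 0
    out["strand"] = "."
    out[PEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> pd.DataFrame:
    """TSS TSV: chrom, pos, gene_id, strand (with header)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_loops(path) -> pd.DataFrame:
    """BEDPE with a name, an O/E enrichment column, and strength_* columns."""
    return pd.read_csv(path, sep="\t")


def write_loops(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_matrix_tsv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, matrix, delimiter="\t", fmt="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_gene_list(path) -> set[str]:
    text = Path(path).read_text().split()
    return set(text)


def write_gene_list(ids, path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + ("\n" if ids else ""))
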