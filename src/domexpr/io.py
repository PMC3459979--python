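"""Readers, writers and validation for the tabular and interval formats.

Conventions
-----------
* Count matrices are TSV with genes as rows, a header row of sample ids,
  and non-negative integer entries.
* Sample metadata is TSV with columns ``sample``, ``pair``, ``status``
  (``domesticated`` or ``wild``) and ``sex`` (``F``, ``M`` or ``unknown``).
* BED intervals are 0-based half-open; VCF positions are 1-based.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

VALID_STATUS = ("domesticated", "wild")
VALID_SEX = ("F", "M", "unknown")


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# counts


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a gene x sample count matrix: unique ids, integral, non-negative."""
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    values = counts.to_numpy()
    if values.dtype.kind == "f":
        frac = values != np.floor(values)
        if frac.any():
            g, s = np.argwhere(frac)[0]
            raise ValidationError(
                f"non-integer count {values[g, s]} at gene "
                f"{counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        counts = counts.astype(np.int64)
        values = counts.to_numpy()
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    return counts


def load_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# sample metadata


def validate_sample_info(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"pair", "status", "sex"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    bad = set(samples["status"]) - set(VALID_STATUS)
    if bad:
        raise ValidationError(
            f"unknown status tokens {sorted(bad)}; expected {VALID_STATUS}"
        )
    bad = set(samples["sex"]) - set(VALID_SEX)
    if bad:
        raise ValidationError(
            f"unknown sex tokens {sorted(bad)}; expected {VALID_SEX}"
        )
    return samples


def load_sample_info(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return validate_sample_info(samples)


def write_sample_info(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def load_dataset(counts_path, metadata_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate a count matrix and its sample metadata.

    Samples present in only one of the two files are rejected by name.
    """
    counts = load_counts(counts_path)
    samples = load_sample_info(metadata_path)
    only_counts = [s for s in counts.columns if s not in samples.index]
    only_meta = [s for s in samples.index if s not in counts.columns]
    if only_counts or only_meta:
        raise ValidationError(
            f"samples in counts but not metadata: {only_counts}; "
            f"in metadata but not counts: {only_meta}"
        )
    # order metadata rows as the count columns
    return counts, samples.loc[counts.columns]


# ---------------------------------------------------------------------------
# orthologues, gene lengths


def load_orthologue_map(path) -> pd.DataFrame:
    """1:1 orthologue table: index orthologue_id, one gene-id column per pair."""
    omap = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for col in omap.columns:
        if omap[col].duplicated().any():
            dups = omap[col][omap[col].duplicated()].unique().tolist()
            raise ValidationError(
                f"orthologue map column {col!r} is not 1:1; repeated gene "
                f"ids: {dups[:5]}"
            )
    return omap


def write_orthologue_map(omap: pd.DataFrame, path) -> None:
    omap.to_csv(path, sep="\t", index_label="orthologue_id")


def load_gene_lengths(path) -> pd.Series:
    lengths = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValidationError(f"non-positive gene lengths: {bad[:5]}")
    return lengths


# ---------------------------------------------------------------------------
# intervals


def load_bed(path) -> pd.DataFrame:
    """Read a BED file into a (chrom, start, end[, name]) frame, 0-based half-open."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if (bed["start"] >= bed["end"]).any():
        raise ValidationError("BED intervals must satisfy start < end")
    return bed.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression filter


def filter_expressed(counts: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep genes detected (count > 0) in at least ``min_fraction`` of samples.

    "At least half" with an odd sample count n cannot be satisfied
    fractionally, so the threshold is ``ceil(min_fraction * n)`` samples.
    Idempotent and order-preserving.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if counts.empty:
        raise ValidationError("empty count matrix")
    n = counts.shape[1]
    need = math.ceil(min_fraction * n)
    keep = (counts > 0).sum(axis=1) >= need
    return counts.loc[keep]
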