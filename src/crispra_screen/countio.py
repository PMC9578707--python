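"""Guide libraries, count tables, exact guide counting and per-guide
enrichment statistics.

Counting is exact-match: each read is searched for the constant vector
anchor and the protospacer-length substring that follows is looked up in the
library.  Each selection round is compared to the naive library (not the
previous round) when computing enrichments.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import CountTable

__all__ = [
    "GuideLibrary",
    "read_guide_library",
    "write_guide_library",
    "count_guides_from_reads",
    "normalize",
    "guide_log_enrichment",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 0.5
VALID_CATEGORIES = frozenset({"gene", "safe", "nontargeting"})
_NUCLEOTIDES = frozenset("ACGT")


@dataclass
class GuideLibrary:
    """Guide library: guide_id, target gene (or control label), category and
    optionally the protospacer sequence."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"guide_id", "gene_id", "category"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"guide library missing columns: {sorted(missing)}")
        dup = self.table["guide_id"][self.table["guide_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate guide_id: {dup.iloc[0]!r}")
        bad = set(self.table["category"]) - VALID_CATEGORIES
        if bad:
            raise ValueError(
                f"unknown categories {sorted(bad)}; expected {sorted(VALID_CATEGORIES)}"
            )
        if "protospacer" in self.table.columns:
            for spacer in self.table["protospacer"].dropna():
                if set(spacer) - _NUCLEOTIDES:
                    raise ValueError(f"invalid protospacer {spacer!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def guide_ids(self) -> pd.Series:
        return self.table["guide_id"]

    def protospacer_index(self) -> dict[str, str]:
        """Map protospacer -> guide_id, rejecting ambiguous protospacers."""
        if "protospacer" not in self.table.columns:
            raise ValueError("library has no protospacer column")
        spacers = self.table["protospacer"]
        if spacers.isna().any():
            raise ValueError("library protospacers are incomplete")
        dup = spacers[spacers.duplicated()]
        if len(dup):
            raise ValueError(f"ambiguous (duplicated) protospacer {dup.iloc[0]!r}")
        return dict(zip(spacers, self.table["guide_id"]))


def read_guide_library(path) -> GuideLibrary:
    return GuideLibrary(pd.read_csv(path, sep="\t", dtype=str))


def write_guide_library(lib: GuideLibrary, path) -> None:
    lib.table.to_csv(path, sep="\t", index=False)


def _open_reads(reads):
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        handle = gzip.open(path, "rt") if path.suffix == ".gz" else open(path)
        return (str(rec.seq) for rec in SeqIO.parse(handle, "fastq"))
    return (str(r) for r in reads)


def count_guides_from_reads(
    reads, lib: GuideLibrary, anchor: str
) -> tuple[pd.Series, int]:
    """Count exact protospacer matches downstream of ``anchor``.

    ``reads`` is a FASTQ path (.gz accepted) or an iterable of read
    sequences.  Returns per-guide counts (indexed like the library) and the
    number of unmatched reads; matched + unmatched equals the total.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    index = lib.protospacer_index()
    lengths = sorted({len(s) for s in index})
    counts = dict.fromkeys(lib.guide_ids, 0)
    unmatched = 0
    for seq in _open_reads(reads):
        seq = seq.upper()
        pos = seq.find(anchor)
        hit = None
        if pos >= 0:
            start = pos + len(anchor)
            for L in lengths:
                hit = index.get(seq[start : start + L])
                if hit is not None:
                    break
        if hit is None:
            unmatched += 1
        else:
            counts[hit] += 1
    series = pd.Series(counts, name="count", dtype=np.int64)
    series.index.name = "guide_id"
    return series, unmatched


def normalize(
    counts: pd.DataFrame | pd.Series, pseudocount: float = DEFAULT_PSEUDOCOUNT
):
    """Per-sample guide frequencies after adding ``pseudocount`` to every
    count; each sample's frequencies sum to 1."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    shifted = counts.astype(float) + pseudocount
    return shifted / shifted.sum(axis=0) if isinstance(counts, pd.DataFrame) else (
        shifted / shifted.sum()
    )


def guide_log_enrichment(
    table: CountTable | pd.DataFrame,
    selected_sample: str,
    reference_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-guide log2 frequency ratio of selected vs reference sample."""
    counts = table.counts if isinstance(table, CountTable) else table
    for sample in (selected_sample, reference_sample):
        if sample not in counts.columns:
            raise KeyError(f"sample {sample!r} not in count table")
    f_sel = normalize(counts[selected_sample], pseudocount)
    f_ref = normalize(counts[reference_sample], pseudocount)
    x = np.log2(f_sel / f_ref)
    x.name = "x"
    return x
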