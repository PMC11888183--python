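"""Guide library and count-table I/O, UMI-aware counting, representation QC.

The guide library is the designed universe of sgRNAs: targeting guides
(four per gene in the screens this package supports), safe-targeting
controls (cut a neutral locus), non-targeting controls, and positive
controls.  Count tables hold UMI-deduplicated guide abundances per sorted
bin and replicate.  Library-representation QC (coverage, Gini skew) is
computed on a single sample column, typically the plasmid pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("targeting", "safe_targeting", "non_targeting", "positive_control")
BINS = ("unsorted", "low", "medium", "high", "plasmid")
SPACER_ALPHABET = frozenset("ACGT")
UMI_LENGTH = 9

LIBRARY_COLUMNS = ["guide_id", "spacer", "target_gene", "category"]


class GuideLibraryError(ValueError):
    pass


@dataclass
class GuideLibrary:
    """Designed guide universe.

    Wraps a DataFrame with columns guide_id, spacer (20 nt over ACGT),
    target_gene (empty for non-targeting/safe-targeting) and category.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in LIBRARY_COLUMNS if c not in t.columns]
        if missing:
            raise GuideLibraryError(f"library table missing columns: {missing}")
        self.table = t = t[LIBRARY_COLUMNS].reset_index(drop=True).astype(str)
        if len(t) == 0:
            raise GuideLibraryError("empty guide library")
        if t["guide_id"].duplicated().any():
            dups = t.loc[t["guide_id"].duplicated(), "guide_id"].tolist()
            raise GuideLibraryError(f"duplicate guide ids: {dups[:5]}")
        bad_spacer = ~t["spacer"].map(
            lambda s: len(s) == 20 and set(s) <= SPACER_ALPHABET
        )
        if bad_spacer.any():
            raise GuideLibraryError(
                f"{int(bad_spacer.sum())} spacers are not 20-nt ACGT strings"
            )
        bad_cat = ~t["category"].isin(CATEGORIES)
        if bad_cat.any():
            raise GuideLibraryError(
                f"unknown categories: {sorted(t.loc[bad_cat, 'category'].unique())}"
            )
        needs_gene = t["category"].isin(["targeting", "positive_control"])
        if (needs_gene & (t["target_gene"] == "")).any():
            raise GuideLibraryError("targeting/positive_control guides need a target_gene")

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def target_genes(self) -> list[str]:
        mask = self.table["category"] == "targeting"
        return sorted(self.table.loc[mask, "target_gene"].unique())

    def guides_for_gene(self, gene: str) -> list[str]:
        mask = self.table["target_gene"] == gene
        return self.table.loc[mask, "guide_id"].tolist()

    def guides_in_category(self, category: str) -> list[str]:
        return self.table.loc[self.table["category"] == category, "guide_id"].tolist()

    @property
    def guide_to_gene(self) -> dict[str, str]:
        return dict(zip(self.table["guide_id"], self.table["target_gene"]))

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(df)


@dataclass
class GuideCountTable:
    """Guides x samples UMI counts with per-sample (replicate, bin) metadata.

    Sample columns are named ``<replicate_id>:<bin>`` so the table
    round-trips through a single TSV without a sidecar.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if (np.asarray(c.to_numpy(dtype=float)) < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(c.to_numpy(dtype=float) % 1, 0):
            raise ValueError("counts must be integral")
        self.counts = c.astype(np.int64)
        if self.samples is None:
            self.samples = self._samples_from_columns(self.counts.columns)
        sm = self.samples
        for col in ("sample_id", "replicate_id", "bin"):
            if col not in sm.columns:
                raise ValueError(f"sample metadata missing column {col}")
        unknown = set(sm["bin"]) - set(BINS)
        if unknown:
            raise ValueError(f"unknown bins: {sorted(unknown)}")
        if list(sm["sample_id"]) != list(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")

    @staticmethod
    def _samples_from_columns(columns: Iterable[str]) -> pd.DataFrame:
        rows = []
        for col in columns:
            rep, _, b = str(col).rpartition(":")
            if not rep or b not in BINS:
                raise ValueError(
                    f"sample column {col!r} is not '<replicate>:<bin>' with a known bin"
                )
            rows.append({"sample_id": col, "replicate_id": rep, "bin": b})
        return pd.DataFrame(rows)

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def replicates(self) -> list[str]:
        return sorted(self.samples["replicate_id"].unique())

    def column(self, replicate_id: str, bin_name: str) -> pd.Series:
        return self.counts[f"{replicate_id}:{bin_name}"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GuideCountTable":
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
        return cls(df)


def count_guide_umis(
    observations: Sequence[tuple[str, str]],
    library: GuideLibrary,
    sample_id: str = "sample",
) -> tuple[pd.Series, pd.DataFrame]:
    """Count distinct UMIs per guide from (guide_id, umi) observations.

    Deduplication is by exact UMI string match within a guide.  Observations
    with an unknown guide id or a malformed UMI (wrong length or non-ACGT
    characters) are not counted; they are returned in a rejected-observations
    log with a reason, because recombined or erroneous reads are expected in
    real screens and should be inspected rather than crash the run.
    """
    known = set(library.guide_ids)
    seen: dict[str, set[str]] = {}
    rejected = []
    for guide_id, umi in observations:
        if guide_id not in known:
            rejected.append({"guide_id": guide_id, "umi": umi, "reason": "unknown_guide"})
            continue
        if len(umi) != UMI_LENGTH or not set(umi) <= SPACER_ALPHABET:
            rejected.append({"guide_id": guide_id, "umi": umi, "reason": "malformed_umi"})
            continue
        seen.setdefault(guide_id, set()).add(umi)
    counts = pd.Series(
        [len(seen.get(g, ())) for g in library.guide_ids],
        index=library.guide_ids,
        name=sample_id,
        dtype=np.int64,
    )
    log = pd.DataFrame(rejected, columns=["guide_id", "umi", "reason"])
    return counts, log


def gini_coefficient(counts: np.ndarray) -> float:
    """Gini by the mean-absolute-difference formula sum|xi-xj| / (2 n^2 mu)."""
    x = np.asarray(counts, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty counts")
    mu = x.mean()
    if mu == 0:
        return 0.0
    # O(n log n) equivalent of the pairwise sum via the sorted form
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * xs) / (n**2 * mu))


def library_skew(counts: pd.Series | np.ndarray, library: GuideLibrary) -> dict:
    """Representation QC for one sample column aligned to the library.

    Returns coverage (fraction of designed guides observed at least once),
    the Gini coefficient of the count distribution, and the 90th/10th
    percentile count ratio (``inf`` when the 10th percentile is zero).
    """
    if isinstance(counts, pd.Series):
        counts = counts.reindex(library.guide_ids, fill_value=0).to_numpy()
    x = np.asarray(counts, dtype=float)
    if x.size != len(library):
        raise ValueError("counts not aligned to library")
    p10, p90 = np.percentile(x, [10, 90])
    return {
        "coverage": float(np.mean(x >= 1)),
        "gini": gini_coefficient(x),
        "p90_p10_ratio": float(p90 / p10) if p10 > 0 else math.inf,
    }
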