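"""GWAS summary-statistics I/O and allele harmonization.

The TWAS statistic consumes a vector of per-SNP association z-scores. Those
z-scores are signed with respect to an effect allele, so before they can be
combined with expression weights trained on a reference panel the alleles of
each SNP must be reconciled with the panel's orientation: a swapped
effect/other pair flips the sign of z, and strand-ambiguous pairs (A/T, C/G)
cannot be reconciled from summary data alone and are dropped by default.
Silent sign errors corrupt w'Z without any detectable symptom downstream,
which is why every record is accounted for in an explicit audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

log = logging.getLogger(__name__)

#: Internal name -> default file column name for tab-delimited sumstats.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",  # effect allele
    "a2": "A2",  # other allele
    "z": "Z",
}

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for palindromic allele pairs (A/T or C/G) whose strand cannot
    be resolved from summary statistics."""
    return _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class ReadAudit:
    """Row accounting for :func:`read_sumstats`."""

    n_rows: int
    n_dropped_invalid: int
    n_dropped_duplicate: int

    @property
    def n_kept(self) -> int:
        return self.n_rows - self.n_dropped_invalid - self.n_dropped_duplicate


@dataclass(frozen=True)
class HarmonizeAudit:
    """Row accounting for :func:`harmonize_alleles`.

    The six categories partition the input exactly:
    ``n_matched + n_flipped + n_ambiguous_dropped + n_absent_dropped +
    n_mismatch_dropped + n_swapped_dropped == n_input``.
    """

    n_input: int
    n_matched: int
    n_flipped: int
    n_ambiguous_dropped: int
    n_absent_dropped: int
    n_mismatch_dropped: int
    n_swapped_dropped: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_matched + self.n_flipped

    def partitions_input(self) -> bool:
        return (
            self.n_matched
            + self.n_flipped
            + self.n_ambiguous_dropped
            + self.n_absent_dropped
            + self.n_mismatch_dropped
            + self.n_swapped_dropped
        ) == self.n_input


@dataclass
class GwasSumstats:
    """Validated per-SNP association z-scores.

    ``df`` has columns ``snp, chrom, pos, a1, a2, z`` with unique SNP ids,
    finite z, valid allele letters and ``a1 != a2``.
    """

    df: pd.DataFrame
    audit: ReadAudit | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        required = ["snp", "chrom", "pos", "a1", "a2", "z"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"sumstats frame missing columns: {missing}")
        if self.df["snp"].duplicated().any():
            raise FormatError("duplicate SNP ids in sumstats")
        z = self.df["z"].to_numpy(dtype=float)
        if not np.all(np.isfinite(z)):
            raise FormatError("non-finite z in sumstats")
        if (self.df["a1"] == self.df["a2"]).any():
            raise FormatError("record with identical effect/other alleles")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def by_snp(self) -> pd.DataFrame:
        """The records indexed by SNP id (for alignment lookups)."""
        return self.df.set_index("snp")

    def z_for(self, snp_ids) -> np.ndarray:
        """z-scores for ``snp_ids``, in that order."""
        return self.by_snp.loc[list(snp_ids), "z"].to_numpy(dtype=float)


def read_sumstats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> GwasSumstats:
    """Read tab-delimited GWAS summary statistics.

    Parameters
    ----------
    path:
        Tab-delimited file with a header. Default column names are
        ``SNP, CHR, BP, A1, A2, Z``; override with ``column_map`` keyed by
        the internal names ``snp, chrom, pos, a1, a2, z``.

    Rows with a missing or non-finite z-score, invalid allele letters, or
    identical alleles are dropped and counted in the audit. Duplicated SNP
    ids keep the first occurrence (with a warning). A file with zero valid
    rows raises :class:`EmptyInputError`.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    df = raw.rename(columns={v: k for k, v in colmap.items()})[list(colmap)]
    n_rows = len(df)

    df["z"] = pd.to_numeric(df["z"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()

    ok = (
        np.isfinite(df["z"].to_numpy(dtype=float))
        & df["a1"].isin(VALID_ALLELES)
        & df["a2"].isin(VALID_ALLELES)
        & (df["a1"] != df["a2"])
        & df["snp"].notna()
    )
    n_invalid = int((~ok).sum())
    df = df[ok]

    dup = df["snp"].duplicated(keep="first")
    n_dup = int(dup.sum())
    if n_dup:
        log.warning("%s: %d duplicate SNP id(s), keeping first occurrence", path.name, n_dup)
    df = df[~dup].reset_index(drop=True)

    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: no valid summary-statistic rows")
    if n_invalid:
        log.info("%s: dropped %d invalid row(s)", path.name, n_invalid)

    audit = ReadAudit(n_rows=n_rows, n_dropped_invalid=n_invalid, n_dropped_duplicate=n_dup)
    return GwasSumstats(df=df, audit=audit)


def harmonize_alleles(
    sumstats: GwasSumstats,
    panel_alleles: Mapping[str, tuple[str, str]],
    ambiguous_policy: str = "drop",
    swapped_policy: str = "flip",
) -> tuple[GwasSumstats, HarmonizeAudit]:
    """Reconcile sumstats alleles with a reference panel's orientation.

    For each SNP, with panel pair ``(p1, p2)``:

    * absent from the panel -> dropped;
    * strand-ambiguous pair (A/T or C/G) -> dropped under
      ``ambiguous_policy="drop"`` (default), else matched normally;
    * exact match ``(a1, a2) == (p1, p2)`` -> kept, z unchanged;
    * swapped match ``(a1, a2) == (p2, p1)`` -> z sign flipped and alleles
      re-oriented under ``swapped_policy="flip"`` (default), dropped under
      ``"drop"``;
    * anything else is irreconcilable -> dropped, never silently kept.

    Returns the harmonized sumstats (alleles in panel orientation, so the
    operation is idempotent) together with an audit whose categories
    partition the input.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    if swapped_policy not in ("flip", "drop"):
        raise ValueError(f"unknown swapped_policy {swapped_policy!r}")

    df = sumstats.df.copy()
    n_input = len(df)

    pairs = df["snp"].map(lambda s: panel_alleles.get(s))
    absent = pairs.isna()
    p1 = pairs.map(lambda t: t[0] if t is not None else "")
    p2 = pairs.map(lambda t: t[1] if t is not None else "")

    ambiguous = df.apply(lambda r: is_strand_ambiguous(r["a1"], r["a2"]), axis=1)
    amb_dropped = ambiguous & ~absent if ambiguous_policy == "drop" else pd.Series(False, index=df.index)

    candidate = ~absent & ~amb_dropped
    exact = candidate & (df["a1"] == p1) & (df["a2"] == p2)
    swapped = candidate & (df["a1"] == p2) & (df["a2"] == p1)
    mismatch = candidate & ~exact & ~swapped

    if swapped_policy == "flip":
        df.loc[swapped, "z"] = -df.loc[swapped, "z"]
        df.loc[swapped, ["a1", "a2"]] = df.loc[swapped, ["a2", "a1"]].to_numpy()
        kept = exact | swapped
        n_flipped, n_swapped_dropped = int(swapped.sum()), 0
    else:
        kept = exact
        n_flipped, n_swapped_dropped = 0, int(swapped.sum())

    audit = HarmonizeAudit(
        n_input=n_input,
        n_matched=int(exact.sum()),
        n_flipped=n_flipped,
        n_ambiguous_dropped=int(amb_dropped.sum()),
        n_absent_dropped=int(absent.sum()),
        n_mismatch_dropped=int(mismatch.sum()),
        n_swapped_dropped=n_swapped_dropped,
    )
    assert audit.partitions_input()

    out = df[kept].reset_index(drop=True)
    if len(out) == 0:
        raise EmptyInputError("no SNPs survive allele harmonization")
    return GwasSumstats(df=out), audit
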