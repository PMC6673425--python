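"""Differential-expression filtering and the TWAS ∩ DE intersection.

The TWAS scan nominates gene-tissue features whose genetically predicted
expression associates with the trait; an independent case/control
expression experiment nominates differentially expressed genes. The
intersection of the two lists is the set of candidate genes supported by
both prediction and observation. Intersection happens at the feature level
first and is then collapsed to unique genes, so one gene significant in
several panels contributes several feature rows but one candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import TwasResult, z_to_p
from .errors import DomainError, EmptyInputError, FormatError


@dataclass
class DeTable:
    """Differential-expression records: gene symbol, fold change, raw p.

    Fold change is on the case/control ratio scale (so 0.7 means
    down-regulation); p-values are uncorrected, as produced by the upstream
    per-gene test.
    """

    df: pd.DataFrame  # columns: gene, fc, p

    def __post_init__(self) -> None:
        missing = [c for c in ("gene", "fc", "p") if c not in self.df.columns]
        if missing:
            raise FormatError(f"DE table missing columns: {missing}")
        fc = self.df["fc"].to_numpy(dtype=float)
        p = self.df["p"].to_numpy(dtype=float)
        if not np.all(np.isfinite(fc)) or np.any(fc <= 0):
            raise FormatError("DE fold changes must be finite and positive")
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise FormatError("DE p-values must lie in (0, 1]")
        if (self.df["gene"].astype(str).str.len() == 0).any():
            raise FormatError("empty gene symbol in DE table")

    def __len__(self) -> int:
        return len(self.df)


def read_de_table(path: str | Path) -> DeTable:
    """Read a tab-delimited DE table with columns ``GENE, FC, P``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("GENE", "FC", "P") if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    out = df.rename(columns={"GENE": "gene", "FC": "fc", "P": "p"})[["gene", "fc", "p"]]
    if len(out) == 0:
        raise EmptyInputError(f"{path.name}: empty DE table")
    return DeTable(df=out.reset_index(drop=True))


def write_de_table(de: DeTable, path: str | Path) -> None:
    de.df.rename(columns={"gene": "GENE", "fc": "FC", "p": "P"}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def filter_de(
    table: DeTable,
    fc_thresh: float = 1.2,
    p_thresh: float = 0.05,
    direction: str = "symmetric",
) -> set[str]:
    """Genes passing the fold-change and raw-p filter.

    ``symmetric`` (default) treats up- and down-regulation alike: a gene
    passes when ``max(FC, 1/FC) > fc_thresh``. ``up_only`` reads the
    fold-change rule literally and requires ``FC > fc_thresh``. Both modes
    additionally require ``p < p_thresh``; all inequalities are strict.
    Duplicate symbols collapse to one entry.
    """
    if direction not in ("symmetric", "up_only"):
        raise DomainError(f"unknown direction {direction!r}")
    if fc_thresh <= 1:
        raise DomainError("fc_thresh must exceed 1")
    if not (0 < p_thresh <= 1):
        raise DomainError("p_thresh must lie in (0, 1]")
    fc = table.df["fc"].to_numpy(dtype=float)
    p = table.df["p"].to_numpy(dtype=float)
    effective_fc = np.maximum(fc, 1.0 / fc) if direction == "symmetric" else fc
    keep = (effective_fc > fc_thresh) & (p < p_thresh)
    return set(table.df.loc[keep, "gene"].astype(str))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if not (0 < alpha <= 1):
        raise DomainError("alpha must lie in (0, 1]")
    if m < 1:
        raise DomainError("m must be >= 1")
    return alpha / m


def count_bonferroni_hits(z_values, alpha: float = 0.05, m: int = 1) -> int:
    """Number of z-scores whose two-sided p falls strictly below alpha/m."""
    arr = np.asarray(z_values, dtype=float).ravel()
    if arr.size == 0:
        return 0
    thresh = bonferroni_threshold(alpha, m)
    return int(np.count_nonzero(z_to_p(arr) < thresh))


@dataclass
class OverlapReport:
    """TWAS ∩ DE bookkeeping.

    ``feature_rows`` holds the retained (gene, panel, p_twas) records sorted
    by ascending p then symbol; ``unique_genes`` preserves that order;
    ``multi_panel_genes`` are genes significant in at least two distinct
    panels; ``per_panel_counts`` counts retained feature rows per panel.
    """

    feature_rows: pd.DataFrame
    unique_genes: list[str]
    multi_panel_genes: list[str]
    per_panel_counts: dict[str, int]

    @property
    def n_features(self) -> int:
        return len(self.feature_rows)

    @property
    def n_unique(self) -> int:
        return len(self.unique_genes)


def intersect_with_de(
    sig_features: Sequence[TwasResult], de_genes: Iterable[str]
) -> OverlapReport:
    """Retain significant features whose gene is differentially expressed.

    Matching is by exact gene symbol, case-insensitive. The report is
    deterministic: feature rows are ordered by ascending p_twas with ties
    broken by symbol then panel, and all counts are invariant under
    permutation of the inputs.
    """
    de_upper = {str(g).upper() for g in de_genes}
    rows = [
        (r.gene, r.panel, r.p_twas)
        for r in sig_features
        if r.gene.upper() in de_upper
    ]
    rows.sort(key=lambda t: (t[2], t[0], t[1]))
    frame = pd.DataFrame(rows, columns=["gene", "panel", "p_twas"])

    unique_genes = list(dict.fromkeys(frame["gene"]))
    panels_per_gene = frame.groupby("gene")["panel"].nunique() if len(frame) else pd.Series(dtype=int)
    multi = sorted(panels_per_gene[panels_per_gene >= 2].index.tolist())
    per_panel = frame["panel"].value_counts().to_dict() if len(frame) else {}
    return OverlapReport(
        feature_rows=frame,
        unique_genes=unique_genes,
        multi_panel_genes=multi,
        per_panel_counts={str(k): int(v) for k, v in per_panel.items()},
    )


def write_overlap_table(
    report: OverlapReport,
    path: str | Path,
    panels: Sequence[str] | None = None,
    de_table: DeTable | None = None,
) -> None:
    """Write the overlap as a wide per-gene table.

    One row per unique gene, one ``P_TWAS`` column per panel with ``/`` as
    the explicit missing marker, plus the DE p-value when a DE table is
    supplied.
    """
    if panels is None:
        panels = sorted(report.per_panel_counts)
    de_p = {}
    if de_table is not None:
        de_p = {
            str(g).upper(): p
            for g, p in zip(de_table.df["gene"], de_table.df["p"])
        }
    records = []
    by_gene = report.feature_rows.groupby("gene")
    for gene in report.unique_genes:
        grp = by_gene.get_group(gene)
        row: dict[str, object] = {"GENE": gene}
        for panel in panels:
            hit = grp[grp["panel"] == panel]
            row[f"P_TWAS_{panel}"] = f"{hit['p_twas'].iloc[0]:.4G}" if len(hit) else "/"
        row["P_MRNA"] = f"{de_p[gene.upper()]:.4G}" if gene.upper() in de_p else "/"
        records.append(row)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
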