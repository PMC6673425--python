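"""Expression-weight features, locus LD matrices, and feature alignment.

A gene-tissue *feature* is one (gene, expression panel) pair carrying a
vector of cis-eQTL weights ``w`` over the SNPs of its locus. The TWAS
statistic additionally needs the GWAS z-scores ``Z`` at those SNPs and the
SNP-correlation (LD) matrix ``D`` of the locus. This module represents all
three, restores positive semi-definiteness of LD matrices read from files,
and restricts (w, Z, D) to a common SNP subset in one shared order — the
order of appearance in the LD matrix, which serves as the single source of
truth for SNP ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FeatureSkipped, FormatError
from .sumstats import GwasSumstats

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
DEFAULT_PSD_EPS = 1e-8
DEFAULT_MIN_OVERLAP = 0.5


@dataclass
class FeatureWeights:
    """Expression weights of one gene-tissue feature.

    ``w[i]`` is the weight of ``snp_ids[i]``; at least one weight must be
    nonzero, otherwise the feature carries no prediction at all.
    """

    gene: str
    panel: str
    snp_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.snp_ids = list(self.snp_ids)
        if self.w.ndim != 1 or len(self.w) != len(self.snp_ids):
            raise DomainError(
                f"{self.gene}/{self.panel}: weight vector and SNP list lengths differ"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DomainError(f"{self.gene}/{self.panel}: duplicate SNP ids in feature")
        if not np.all(np.isfinite(self.w)):
            raise DomainError(f"{self.gene}/{self.panel}: non-finite weight")
        if not np.any(self.w != 0.0):
            raise DomainError(f"{self.gene}/{self.panel}: all expression weights are zero")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.panel)

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class LdMatrix:
    """SNP-correlation matrix ``D`` of one locus.

    Symmetric with unit diagonal (tolerance 1e-8). Use :meth:`regularized`
    to guarantee positive semi-definiteness before quadratic forms.
    """

    snp_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.snp_ids = list(self.snp_ids)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise DomainError("LD matrix must be square")
        if self.D.shape[0] != len(self.snp_ids):
            raise DomainError("LD matrix dimension does not match SNP list")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DomainError("duplicate SNP ids in LD matrix")
        if not np.allclose(self.D, self.D.T, atol=SYMMETRY_TOL, rtol=0):
            raise DomainError("LD matrix is not symmetric within 1e-8")
        if not np.allclose(np.diag(self.D), 1.0, atol=SYMMETRY_TOL, rtol=0):
            raise DomainError("LD matrix diagonal is not 1 within 1e-8")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.D + self.D.T) / 2.0).min())

    def regularized(self, eps: float = DEFAULT_PSD_EPS) -> "LdMatrix":
        return LdMatrix(self.snp_ids, regularize_psd(self.D, eps=eps))


def regularize_psd(D: np.ndarray, eps: float = DEFAULT_PSD_EPS) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone and restore unit diagonal.

    Eigenvalues are clipped from below at ``eps`` (>= 0), the matrix is
    rebuilt, and rescaled by its diagonal so every diagonal entry is exactly
    one again. An input that is already PSD (min eigenvalue >= eps) with unit
    diagonal is returned unchanged up to symmetrization. The result is the
    variance matrix used in w'Dw, so nonnegativity is a hard requirement.
    """
    D = np.asarray(D, dtype=float)
    if eps < 0:
        raise DomainError("eps must be >= 0")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DomainError("regularize_psd requires a square matrix")
    if not np.allclose(D, D.T, atol=SYMMETRY_TOL, rtol=0):
        raise DomainError("regularize_psd requires a symmetric matrix (tol 1e-8)")

    sym = (D + D.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps and np.allclose(np.diag(sym), 1.0, atol=SYMMETRY_TOL, rtol=0):
        return sym

    clipped = np.clip(vals, eps, None)
    M = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(M))
    # d > 0: clipping cannot zero a diagonal of a unit-diagonal matrix unless
    # the whole row was degenerate; guard anyway.
    d = np.where(d > 0, d, 1.0)
    M = M / np.outer(d, d)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return M


def load_weights(path: str | Path) -> list[FeatureWeights]:
    """Read gene-tissue expression weights from long-format TSV.

    Columns ``GENE, PANEL, SNP, WEIGHT``; one feature per (gene, panel)
    group, SNP order preserved from the file. A feature whose weights are
    all zero is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"GENE": str, "PANEL": str, "SNP": str})
    missing = [c for c in ("GENE", "PANEL", "SNP", "WEIGHT") if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    features: list[FeatureWeights] = []
    for (gene, panel), grp in df.groupby(["GENE", "PANEL"], sort=False):
        try:
            features.append(
                FeatureWeights(
                    gene=gene,
                    panel=panel,
                    snp_ids=grp["SNP"].tolist(),
                    w=grp["WEIGHT"].to_numpy(dtype=float),
                )
            )
        except DomainError as exc:
            raise FormatError(f"{path.name}: invalid feature: {exc}") from exc
    if not features:
        raise FormatError(f"{path.name}: no features found")
    return features


def write_weights(features: Iterable[FeatureWeights], path: str | Path) -> None:
    rows = [
        (fw.gene, fw.panel, snp, weight)
        for fw in features
        for snp, weight in zip(fw.snp_ids, fw.w)
    ]
    pd.DataFrame(rows, columns=["GENE", "PANEL", "SNP", "WEIGHT"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def load_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square LD matrix from TSV with SNP ids as header and index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in df.columns]
    if [str(s) for s in df.index] != snp_ids:
        raise FormatError(f"{Path(path).name}: LD header and index SNP ids differ")
    return LdMatrix(snp_ids=snp_ids, D=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.D, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


class LdStore:
    """A collection of per-locus LD matrices with SNP-based lookup.

    Each SNP may belong to at most one locus; a feature is served the
    matrix of the single locus its SNPs fall in.
    """

    def __init__(self, matrices: Sequence[LdMatrix], regularize_eps: float | None = DEFAULT_PSD_EPS):
        if regularize_eps is not None:
            matrices = [m.regularized(regularize_eps) for m in matrices]
        self.matrices = list(matrices)
        self._snp_to_locus: dict[str, int] = {}
        for i, m in enumerate(self.matrices):
            for s in m.snp_ids:
                if s in self._snp_to_locus:
                    raise FormatError(f"SNP {s} appears in more than one LD locus")
                self._snp_to_locus[s] = i

    def __len__(self) -> int:
        return len(self.matrices)

    def locus_for(self, snp_ids: Iterable[str]) -> LdMatrix:
        loci = {self._snp_to_locus[s] for s in snp_ids if s in self._snp_to_locus}
        if not loci:
            raise FeatureSkipped("no LD information for any feature SNP")
        if len(loci) > 1:
            raise FeatureSkipped("feature SNPs span multiple LD loci")
        return self.matrices[loci.pop()]

    @classmethod
    def from_dir(cls, path: str | Path, regularize_eps: float | None = DEFAULT_PSD_EPS) -> "LdStore":
        """Load every ``*.tsv`` matrix under ``path`` (sorted by name)."""
        path = Path(path)
        files = sorted(path.glob("*.tsv"))
        if not files:
            raise FormatError(f"no LD matrix files (*.tsv) under {path}")
        return cls([load_ld_matrix(f) for f in files], regularize_eps=regularize_eps)


@dataclass
class AlignedFeature:
    """One feature's (w, z, D) restricted to a common SNP subset.

    All three components are indexed identically, in the LD matrix's SNP
    order. ``overlap_fraction`` is n_overlap over the feature's original
    SNP count.
    """

    gene: str
    panel: str
    snp_ids: list[str]
    w: np.ndarray
    z: np.ndarray
    D: np.ndarray
    n_overlap: int
    overlap_fraction: float


def align_feature(
    fw: FeatureWeights,
    sumstats: GwasSumstats,
    ld: LdMatrix,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
) -> AlignedFeature:
    """Intersect a feature's SNPs with the sumstats and LD SNP sets.

    The canonical order is the LD matrix's. Raises :class:`FeatureSkipped`
    when the retained fraction of the feature's SNPs falls below
    ``min_overlap_fraction`` or the retained weights are all zero — a
    statistic computed from a nearly empty weight vector is not the
    feature's statistic.
    """
    wmap = dict(zip(fw.snp_ids, fw.w))
    ss_index = set(sumstats.df["snp"])
    positions = [i for i, s in enumerate(ld.snp_ids) if s in wmap and s in ss_index]
    n_overlap = len(positions)
    fraction = n_overlap / len(fw.snp_ids)
    if n_overlap == 0 or fraction < min_overlap_fraction:
        raise FeatureSkipped(
            f"overlap {n_overlap}/{len(fw.snp_ids)} below minimum fraction {min_overlap_fraction}"
        )
    common = [ld.snp_ids[i] for i in positions]
    w = np.array([wmap[s] for s in common], dtype=float)
    if not np.any(w != 0.0):
        raise FeatureSkipped("all weights at overlapping SNPs are zero")
    z = sumstats.z_for(common)
    D = ld.D[np.ix_(positions, positions)]
    return AlignedFeature(
        gene=fw.gene,
        panel=fw.panel,
        snp_ids=common,
        w=w,
        z=z,
        D=D,
        n_overlap=n_overlap,
        overlap_fraction=fraction,
    )
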