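"""The TWAS association statistic and the transcriptome-wide scan.

The statistic tests association between the cis-genetic component of a
gene's expression and the trait using only GWAS summary statistics: with
expression weights ``w``, GWAS z-scores ``Z`` and SNP-correlation matrix
``D`` at the locus,

    z_TWAS = w'Z / sqrt(w'Dw)

which is standard normal under the null hypothesis that Z ~ MVN(0, D).
Two-sided p-values use the stable upper-tail survival function — a naive
``1 - cdf`` loses all precision beyond |z| of about 6, i.e. exactly where
the interesting hits live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FeatureSkipped, UndefinedStatisticError
from .sumstats import GwasSumstats
from .weights import DEFAULT_MIN_OVERLAP, FeatureWeights, LdStore, align_feature

log = logging.getLogger(__name__)

#: Tolerance below which w'Dw is treated as zero and the statistic undefined.
VAR_TOL = 1e-10

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


def twas_zscore(w, z, D) -> float:
    """w'z / sqrt(w'Dw).

    Invariant under positive rescaling of ``w``; negating ``w`` negates the
    statistic. Raises :class:`UndefinedStatisticError` when w'Dw <= 1e-10.
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    D = np.asarray(D, dtype=float)
    if w.shape != z.shape or D.shape != (len(w), len(w)):
        raise DomainError("twas_zscore: inconsistent dimensions")
    denom = float(w @ D @ w)
    if denom <= VAR_TOL:
        raise UndefinedStatisticError(f"w'Dw = {denom:g} below tolerance {VAR_TOL:g}")
    return float(w @ z) / np.sqrt(denom)


def z_to_p(z):
    """Two-sided standard-normal p-value, 2 * P(N(0,1) >= |z|).

    Accepts a scalar or array; computed with the survival function so the
    far tail keeps full relative precision.
    """
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("z_to_p requires finite z")
    p = 2.0 * stats.norm.sf(np.abs(arr))
    p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(z) or arr.ndim == 0 else p


def genomic_lambda(z_values) -> float:
    """Genomic inflation factor: median(z^2) over the null chi-square median.

    Equals 1 for a perfectly calibrated scan; values above 1 indicate
    inflation of the observed statistics relative to the null.
    """
    arr = np.asarray(z_values, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise DomainError("genomic_lambda requires at least one finite value")
    return float(np.median(arr**2) / CHI2_MEDIAN_1DF)


@dataclass
class TwasResult:
    """Per-feature scan result; ``p_perm`` is filled by the permutation stage."""

    gene: str
    panel: str
    z_twas: float
    p_twas: float
    n_overlap: int
    p_perm: float | None = None


@dataclass(frozen=True)
class SkipRecord:
    gene: str
    panel: str
    reason: str


def scan_panels(
    sumstats: GwasSumstats,
    features: Sequence[FeatureWeights],
    ld_store: LdStore,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[list[TwasResult], list[SkipRecord]]:
    """Compute z_TWAS and p for every feature across all panels.

    Features that cannot be aligned (insufficient SNP overlap, no LD locus)
    or whose variance term is degenerate are recorded in the skip log with
    a reason and never abort the scan. With ``n_perm > 0`` a permutation
    empirical p-value is attached to each result (see
    :mod:`twaskit.permutation`). Output is deterministic given inputs and
    seed, independent of feature order.
    """
    from .permutation import permutation_p  # local import to avoid a cycle

    results: list[TwasResult] = []
    skips: list[SkipRecord] = []
    for fw in features:
        try:
            ld = ld_store.locus_for(fw.snp_ids)
            af = align_feature(fw, sumstats, ld, min_overlap_fraction)
            z = twas_zscore(af.w, af.z, af.D)
        except FeatureSkipped as exc:
            skips.append(SkipRecord(fw.gene, fw.panel, exc.reason))
            continue
        except UndefinedStatisticError as exc:
            skips.append(SkipRecord(fw.gene, fw.panel, f"undefined statistic: {exc}"))
            continue
        p_perm = None
        if n_perm > 0:
            p_perm = permutation_p(af, n_perm=n_perm, seed=seed).p_empirical
        results.append(
            TwasResult(
                gene=fw.gene,
                panel=fw.panel,
                z_twas=z,
                p_twas=z_to_p(z),
                n_overlap=af.n_overlap,
                p_perm=p_perm,
            )
        )
    if skips:
        log.info("scan: %d feature(s) skipped, %d tested", len(skips), len(results))
    return results, skips


_RESULT_COLUMNS = ["GENE", "PANEL", "NSNPS_USED", "ZTWAS", "P_TWAS", "P_PERM"]


def results_frame(results: Iterable[TwasResult]) -> pd.DataFrame:
    rows = [
        (r.gene, r.panel, r.n_overlap, r.z_twas, r.p_twas,
         np.nan if r.p_perm is None else r.p_perm)
        for r in results
    ]
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(results: Iterable[TwasResult], path: str | Path) -> None:
    """Write the scan table, scientific notation with 6 significant digits."""
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6G")


def read_results(path: str | Path) -> list[TwasResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        p_perm = getattr(row, "P_PERM", np.nan)
        out.append(
            TwasResult(
                gene=str(row.GENE),
                panel=str(row.PANEL),
                z_twas=float(row.ZTWAS),
                p_twas=float(row.P_TWAS),
                n_overlap=int(row.NSNPS_USED),
                p_perm=None if pd.isna(p_perm) else float(p_perm),
            )
        )
    return out
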