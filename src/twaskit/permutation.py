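"""Permutation filter for TWAS hits.

A highly significant GWAS locus with extensive LD can drag any gene tested
there to transcriptome-wide significance through chance co-localization of
its eQTLs with the GWAS signal. The permutation filter conditions on the
observed GWAS effects: the expression weights are randomly re-assigned to
the locus's SNP positions, the statistic is recomputed with z and D fixed,
and the empirical p-value measures how extreme the observed statistic is
relative to that conditional null. Features whose signal survives the
shuffle carry weight-specific information rather than locus-wide LD.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import VAR_TOL, TwasResult, twas_zscore
from .errors import DomainError
from .weights import AlignedFeature

DEFAULT_N_PERM = 5000

#: Absolute slack when comparing |z_perm| against |z_obs|, so that exact
#: ties (e.g. the identity permutation) always count as extreme.
_TIE_TOL = 1e-9


def feature_seed(master_seed: int, gene: str, panel: str) -> int:
    """Deterministic per-feature sub-seed in [0, 2^31).

    Derived by hashing (master seed, gene, panel) so permutation streams do
    not depend on scan order or parallel scheduling.
    """
    digest = hashlib.blake2b(
        f"{master_seed}|{gene}|{panel}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass(frozen=True)
class PermutationResult:
    gene: str
    panel: str
    z_obs: float
    n_perm: int
    n_as_extreme: int
    p_empirical: float


def permutation_p(
    af: AlignedFeature, n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> PermutationResult:
    """Empirical p-value from uniform shuffles of the weight vector.

    Each permutation re-assigns the entries of ``w`` uniformly at random to
    the locus's SNP positions and recomputes z_TWAS with z and D unchanged.
    Extremeness is two-sided (|z_perm| >= |z_obs|) to match the two-sided
    analytic p, and the add-one estimator

        p = (n_as_extreme + 1) / (n_perm + 1)

    keeps p in [1/(n_perm+1), 1] and never returns zero. ``seed`` is the
    scan's master seed; the feature's own stream is derived from it via
    :func:`feature_seed`, so results are reproducible and order-independent.
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    z_obs = twas_zscore(af.w, af.z, af.D)
    rng = np.random.default_rng(feature_seed(seed, af.gene, af.panel))

    W = np.tile(af.w, (n_perm, 1))
    W = rng.permuted(W, axis=1)
    num = W @ af.z
    den = np.einsum("ij,jk,ik->i", W, af.D, W)
    ok = den > VAR_TOL
    z_perm = np.zeros(n_perm)
    z_perm[ok] = num[ok] / np.sqrt(den[ok])

    n_extreme = int(np.count_nonzero(np.abs(z_perm) >= np.abs(z_obs) - _TIE_TOL))
    p = (n_extreme + 1) / (n_perm + 1)
    return PermutationResult(
        gene=af.gene,
        panel=af.panel,
        z_obs=z_obs,
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        p_empirical=p,
    )


def significant_features(
    results: Sequence[TwasResult],
    p_thresh: float = 0.05,
    perm_thresh: float = 0.05,
) -> list[TwasResult]:
    """Rows with p_TWAS < p_thresh AND permutation p < perm_thresh.

    Both inequalities are strict; rows without a permutation p never pass.
    """
    if not (0 < p_thresh <= 1) or not (0 < perm_thresh <= 1):
        raise DomainError("thresholds must lie in (0, 1]")
    return [
        r
        for r in results
        if r.p_twas < p_thresh and r.p_perm is not None and r.p_perm < perm_thresh
    ]
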