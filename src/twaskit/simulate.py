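"""Synthetic study generator with known ground truth.

Every input of the analysis — GWAS summary statistics, expression-weight
panels, locus LD matrices, a case/control differential-expression table and
GO-style annotations — is generated with the statistical structure the
method assumes, so each stage can be validated against planted truth
without any external download.

Model
-----
Each gene occupies its own locus of ``snps_per_locus`` SNPs with AR(1)
correlation ``D[i,j] = rho^|i-j|``. GWAS z-scores at a locus follow the
standard summary-statistics likelihood

    Z ~ MVN(sqrt(n) * D * beta, D)

where beta is the joint per-SNP effect vector and n the GWAS sample size.
For a causal gene, beta is proportional to one of its panels' weight
vectors, beta = effect * w / sqrt(w'Dw), which makes the expected TWAS
statistic of that feature exactly sqrt(n) * effect. With the defaults
(n = 446,696, effect = 0.01) a causal feature sits at E[z_TWAS] ~ 6.7 —
the magnitude of a genuine top hit — while null features are standard
normal.

The DE experiment mimics a small two-group microarray comparison: per-gene
log2 expression is Gaussian within groups (sd ``de_noise_sd``), truly DE
genes receive a mean shift of ``de_log2_shift`` log2 units with random
sign, fold change is 2^(case mean - control mean) and the p-value comes
from a two-sample t-test. Annotations are random term memberships plus one
planted term equal to the causal-and-DE gene set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, GeneSetCollection, write_gmt
from .errors import DomainError
from .integrate import DeTable, write_de_table
from .sumstats import GwasSumstats
from .weights import FeatureWeights, LdMatrix, write_ld_matrix, write_weights

#: Ordered, strand-unambiguous allele pairs assigned to simulated SNPs.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """Conditions of a synthetic study.

    Defaults emulate the real analysis at desk scale: three expression
    panels, a GWAS of 40,585 cases + 406,111 controls (sample size only),
    a 20 case / 20 control expression experiment, 5000-permutation
    filtering downstream.
    """

    n_loci: int = 80
    snps_per_locus: int = 20
    ld_rho: float = 0.6
    panels: tuple[str, ...] = ("METSIM", "NTR", "YFS")
    genes_per_panel: int = 40
    weight_sparsity: float = 0.3
    causal_fraction: float = 0.1
    causal_effect: float = 0.01
    gwas_n: int = 446_696
    swapped_allele_fraction: float = 0.1
    de_n_cases: int = 20
    de_n_controls: int = 20
    de_log2_shift: float = 1.0
    de_noise_sd: float = 0.5
    n_go_terms: int = 50
    go_term_size_range: tuple[int, int] = (5, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_loci", "snps_per_locus", "genes_per_panel", "gwas_n",
                     "de_n_cases", "de_n_controls", "n_go_terms"):
            if getattr(self, name) < 1:
                raise DomainError(f"{name} must be positive")
        if not abs(self.ld_rho) < 1:
            raise DomainError("|ld_rho| must be < 1")
        if not (0 < self.weight_sparsity <= 1):
            raise DomainError("weight_sparsity must lie in (0, 1]")
        if not (0 <= self.causal_fraction <= 1):
            raise DomainError("causal_fraction must lie in [0, 1]")
        if not (0 <= self.swapped_allele_fraction <= 1):
            raise DomainError("swapped_allele_fraction must lie in [0, 1]")
        if self.genes_per_panel > self.n_loci:
            raise DomainError("genes_per_panel cannot exceed n_loci")


@dataclass
class SimTruth:
    """Planted ground truth of a synthetic study."""

    causal_genes: set[str]
    de_genes: set[str]
    planted_term: str
    beta: dict[str, np.ndarray] = field(default_factory=dict)  # gene -> locus beta


@dataclass
class SimStudy:
    """In-memory synthetic study: every pipeline input plus the truth."""

    config: SimConfig
    sumstats: GwasSumstats
    ref_alleles: dict[str, tuple[str, str]]
    features: list[FeatureWeights]
    ld: list[LdMatrix]
    de_table: DeTable
    gene_sets: GeneSetCollection
    truth: SimTruth


def make_ld(size: int, rho: float, snp_ids: Sequence[str] | None = None) -> LdMatrix:
    """AR(1) LD matrix, D[i,j] = rho^|i-j|. Always positive definite for
    |rho| < 1."""
    if size < 1:
        raise DomainError("size must be >= 1")
    if not abs(rho) < 1:
        raise DomainError("|rho| must be < 1")
    idx = np.arange(size)
    D = np.power(float(rho), np.abs(idx[:, None] - idx[None, :])) if rho != 0 else np.eye(size)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(size)]
    return LdMatrix(snp_ids=list(snp_ids), D=D)


def simulate_weights(size: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    """Sparse weight vector: ceil(sparsity * size) standard-normal entries
    at random positions, the rest zero; always at least one nonzero."""
    if size < 1:
        raise DomainError("size must be >= 1")
    if not (0 < sparsity <= 1):
        raise DomainError("sparsity must lie in (0, 1]")
    n_nonzero = max(1, int(np.ceil(sparsity * size)))
    w = np.zeros(size)
    positions = rng.choice(size, size=n_nonzero, replace=False)
    values = rng.standard_normal(n_nonzero)
    # a weight drawn exactly 0.0 has probability zero; re-draw defensively
    while not np.any(values != 0.0):  # pragma: no cover
        values = rng.standard_normal(n_nonzero)
    w[positions] = values
    return w


def simulate_gwas_z(
    D: LdMatrix | np.ndarray,
    beta: np.ndarray,
    gwas_n: int,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw GWAS z-scores, Z ~ MVN(sqrt(gwas_n) * D * beta, D).

    With ``size=None`` returns one draw of shape (m,); otherwise ``size``
    independent draws of shape (size, m) — useful for Monte-Carlo checks.
    """
    Dm = D.D if isinstance(D, LdMatrix) else np.asarray(D, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (Dm.shape[0],):
        raise DomainError("beta length does not match LD dimension")
    if gwas_n < 1:
        raise DomainError("gwas_n must be >= 1")
    mean = np.sqrt(gwas_n) * (Dm @ beta)
    # Cholesky with a tiny jitter fallback for numerically semidefinite D.
    try:
        L = np.linalg.cholesky(Dm)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(Dm + 1e-10 * np.eye(Dm.shape[0]))
    n_draws = 1 if size is None else size
    eps = rng.standard_normal((n_draws, Dm.shape[0]))
    draws = mean + eps @ L.T
    return draws[0] if size is None else draws


def plant_causal(fw: FeatureWeights, ld: LdMatrix, effect: float) -> np.ndarray:
    """Joint effect vector making a feature causal with known strength.

    Returns beta over ``ld.snp_ids`` with beta = effect * w / sqrt(w'Dw) at
    the feature's SNP positions and zero elsewhere. Under the GWAS model
    Z ~ MVN(sqrt(n) D beta, D) this gives

        E[z_TWAS] = sqrt(n) * w'D beta / sqrt(w'Dw) = sqrt(n) * effect

    exactly, so statistical power is controlled in closed form. With
    ``effect=0`` the locus stays null.
    """
    beta = np.zeros(len(ld.snp_ids))
    if effect == 0:
        return beta
    pos = {s: i for i, s in enumerate(ld.snp_ids)}
    missing = [s for s in fw.snp_ids if s not in pos]
    if missing:
        raise DomainError(f"feature SNPs not in LD locus: {missing[:3]}")
    idx = [pos[s] for s in fw.snp_ids]
    Dsub = ld.D[np.ix_(idx, idx)]
    scale = float(fw.w @ Dsub @ fw.w)
    if scale <= 0:
        raise DomainError("w'Dw must be positive to plant a causal effect")
    beta[idx] = effect * fw.w / np.sqrt(scale)
    return beta


def simulate_de_table(
    genes: Sequence[str],
    de_genes: set[str],
    n_cases: int = 20,
    n_controls: int = 20,
    log2_shift: float = 1.0,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> DeTable:
    """Two-group expression comparison with planted DE genes.

    Per gene, log2 expression is drawn Normal(baseline, noise_sd) in each
    group; genes in ``de_genes`` get a case-group mean shift of
    ``log2_shift`` log2 units with random sign. Fold change is
    2^(case mean - control mean); the p-value is a two-sample t-test.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for gene in genes:
        baseline = rng.normal(7.0, 1.0)
        shift = 0.0
        if gene in de_genes:
            shift = log2_shift * (1.0 if rng.random() < 0.5 else -1.0)
        cases = rng.normal(baseline + shift, noise_sd, size=n_cases)
        controls = rng.normal(baseline, noise_sd, size=n_controls)
        t = stats.ttest_ind(cases, controls, equal_var=True)
        fc = float(2.0 ** (cases.mean() - controls.mean()))
        p = float(np.clip(t.pvalue, np.finfo(float).tiny, 1.0))
        rows.append((gene, fc, p))
    return DeTable(df=pd.DataFrame(rows, columns=["gene", "fc", "p"]))


def simulate_go(
    genes: Sequence[str],
    n_terms: int,
    planted_term: set[str],
    rng: np.random.Generator,
    size_range: tuple[int, int] = (5, 30),
) -> GeneSetCollection:
    """Random term memberships plus one term equal to ``planted_term``.

    The universe is the full gene list; categories rotate over BP/MF/CC.
    """
    genes = list(genes)
    if planted_term and not set(planted_term) <= set(genes):
        raise DomainError("planted term members must be drawn from the gene list")
    lo, hi = size_range
    hi = min(hi, len(genes))
    lo = min(lo, hi)
    categories = ("BP", "MF", "CC")
    terms = []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False).tolist())
        terms.append(
            GeneSet(
                term_id=f"TERM{i + 1:04d}",
                name=f"random term {i + 1}",
                category=categories[i % len(categories)],
                members=members,
            )
        )
    if planted_term:
        terms.append(
            GeneSet(
                term_id="TERM_PLANTED",
                name="planted candidate-gene term",
                category="BP",
                members=frozenset(planted_term),
            )
        )
    return GeneSetCollection(terms=terms, universe=frozenset(genes))


def generate_study(config: SimConfig, out_dir: str | Path | None = None) -> SimStudy:
    """Build a complete synthetic study; optionally write it to disk.

    One gene per locus; each panel covers a random subset of
    ``genes_per_panel`` genes with its own sparse weights. Causal genes are
    sampled from the genes covered by at least one panel and their effect
    is planted through the weights of their first covering panel. The DE
    truth set is all causal genes plus an equal number of non-causal genes,
    so the causal∩DE set equals the causal set and the DE list also carries
    decoys. A fraction of sumstats rows is stored with swapped alleles and
    negated z to exercise harmonization (the reference-allele table keeps
    the panel orientation, so harmonization restores the original z).

    Deterministic per config (including seed): repeated calls produce
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_loci)]

    # Loci, LD and per-SNP metadata
    ld_list: list[LdMatrix] = []
    locus_of: dict[str, LdMatrix] = {}
    snp_rows = []
    ref_alleles: dict[str, tuple[str, str]] = {}
    for i, gene in enumerate(genes):
        snp_ids = [f"rs{i * config.snps_per_locus + j + 1}" for j in range(config.snps_per_locus)]
        ld = make_ld(config.snps_per_locus, config.ld_rho, snp_ids)
        ld_list.append(ld)
        locus_of[gene] = ld
        chrom = str(i % 22 + 1)
        for j, snp in enumerate(snp_ids):
            pair = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
            ref_alleles[snp] = pair
            snp_rows.append((snp, chrom, (i + 1) * 10**6 + j * 1000, pair[0], pair[1]))

    # Panel features
    features: list[FeatureWeights] = []
    panel_genes: dict[str, list[str]] = {}
    for panel in config.panels:
        chosen = sorted(rng.choice(genes, size=config.genes_per_panel, replace=False).tolist())
        panel_genes[panel] = chosen
        for gene in chosen:
            ld = locus_of[gene]
            w = simulate_weights(config.snps_per_locus, config.weight_sparsity, rng)
            features.append(FeatureWeights(gene=gene, panel=panel, snp_ids=ld.snp_ids, w=w))

    covered = sorted({g for gl in panel_genes.values() for g in gl})
    first_feature = {}
    for fw in features:
        first_feature.setdefault(fw.gene, fw)

    # Causal genes and per-locus effects
    n_causal = min(int(round(config.causal_fraction * config.n_loci)), len(covered))
    causal = set(rng.choice(covered, size=n_causal, replace=False).tolist()) if n_causal else set()
    beta_by_gene: dict[str, np.ndarray] = {}
    for gene in sorted(causal):
        beta_by_gene[gene] = plant_causal(first_feature[gene], locus_of[gene], config.causal_effect)

    # GWAS z-scores, one draw per locus
    z_all = []
    for gene, ld in zip(genes, ld_list):
        beta = beta_by_gene.get(gene, np.zeros(len(ld.snp_ids)))
        z_all.append(simulate_gwas_z(ld, beta, config.gwas_n, rng))
    z_flat = np.concatenate(z_all)

    ss_df = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "a1", "a2"])
    ss_df["z"] = z_flat
    # store a fraction with swapped alleles + negated z (harmonization fodder)
    swap = rng.random(len(ss_df)) < config.swapped_allele_fraction
    ss_df.loc[swap, ["a1", "a2"]] = ss_df.loc[swap, ["a2", "a1"]].to_numpy()
    ss_df.loc[swap, "z"] = -ss_df.loc[swap, "z"]
    sumstats = GwasSumstats(df=ss_df.reset_index(drop=True))

    # DE truth: causal genes plus an equal count of non-causal decoys
    non_causal = sorted(set(genes) - causal)
    n_decoys = min(len(causal), len(non_causal))
    decoys = set(rng.choice(non_causal, size=n_decoys, replace=False).tolist()) if n_decoys else set()
    de_genes = causal | decoys
    de_table = simulate_de_table(
        genes, de_genes,
        n_cases=config.de_n_cases, n_controls=config.de_n_controls,
        log2_shift=config.de_log2_shift, noise_sd=config.de_noise_sd, rng=rng,
    )

    planted = causal & de_genes  # == causal by construction
    gene_sets = simulate_go(genes, config.n_go_terms, planted, rng, config.go_term_size_range)

    truth = SimTruth(
        causal_genes=causal,
        de_genes=de_genes,
        planted_term="TERM_PLANTED",
        beta=beta_by_gene,
    )
    study = SimStudy(
        config=config, sumstats=sumstats, ref_alleles=ref_alleles,
        features=features, ld=ld_list, de_table=de_table,
        gene_sets=gene_sets, truth=truth,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: SimStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every study artifact in the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sumstats": out / "sumstats.tsv",
        "weights": out / "weights.tsv",
        "ld_dir": out / "ld",
        "ref_alleles": out / "reference_alleles.tsv",
        "de_table": out / "de_table.tsv",
        "gmt": out / "annotations.gmt",
        "truth": out / "truth.tsv",
        "beta": out / "beta.tsv",
        "config": out / "sim_config.json",
    }
    study.sumstats.df.rename(
        columns={"snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2", "z": "Z"}
    ).to_csv(paths["sumstats"], sep="\t", index=False, float_format="%.10g")

    write_weights(study.features, paths["weights"])

    paths["ld_dir"].mkdir(exist_ok=True)
    for i, ld in enumerate(study.ld):
        write_ld_matrix(ld, paths["ld_dir"] / f"locus{i + 1:04d}.tsv")

    pd.DataFrame(
        [(s, a1, a2) for s, (a1, a2) in study.ref_alleles.items()],
        columns=["SNP", "A1", "A2"],
    ).to_csv(paths["ref_alleles"], sep="\t", index=False)

    write_de_table(study.de_table, paths["de_table"])
    write_gmt(study.gene_sets, paths["gmt"])

    truth_rows = [(g, "causal_gene") for g in sorted(study.truth.causal_genes)]
    truth_rows += [(g, "de_gene") for g in sorted(study.truth.de_genes)]
    truth_rows += [(study.truth.planted_term, "planted_term")]
    pd.DataFrame(truth_rows, columns=["ITEM", "ROLE"]).to_csv(
        paths["truth"], sep="\t", index=False
    )

    beta_rows = []
    gene_to_ld = dict(zip([f"GENE{i + 1:04d}" for i in range(len(study.ld))], study.ld))
    for gene, beta in sorted(study.truth.beta.items()):
        for snp, b in zip(gene_to_ld[gene].snp_ids, beta):
            if b != 0:
                beta_rows.append((gene, snp, b))
    pd.DataFrame(beta_rows, columns=["GENE", "SNP", "BETA"]).to_csv(
        paths["beta"], sep="\t", index=False, float_format="%.10g"
    )

    cfg = asdict(study.config)
    cfg["panels"] = list(cfg["panels"])
    cfg["go_term_size_range"] = list(cfg["go_term_size_range"])
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t")
    return SimTruth(
        causal_genes=set(df.loc[df["ROLE"] == "causal_gene", "ITEM"]),
        de_genes=set(df.loc[df["ROLE"] == "de_gene", "ITEM"]),
        planted_term=str(df.loc[df["ROLE"] == "planted_term", "ITEM"].iloc[0]),
    )
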