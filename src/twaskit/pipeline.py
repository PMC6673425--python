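"""End-to-end orchestration: scan -> permutation filter -> DE intersection
-> enrichment, with per-stage TSV outputs and a machine-readable summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .engine import (
    TwasResult,
    genomic_lambda,
    results_frame,
    scan_panels,
    write_results,
)
from .enrichment import read_gmt, enrich, write_enrichment
from .errors import ConfigError
from .integrate import (
    bonferroni_threshold,
    count_bonferroni_hits,
    filter_de,
    intersect_with_de,
    read_de_table,
    write_overlap_table,
)
from .permutation import DEFAULT_N_PERM, significant_features
from .sumstats import harmonize_alleles, read_sumstats
from .weights import DEFAULT_MIN_OVERLAP, LdStore, load_weights

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and knobs for one pipeline run.

    Threshold defaults follow the analysis conventions: transcriptome-wide
    p < 0.05 with permutation p < 0.05 for significant features,
    Bonferroni alpha 0.05 over the tested features, DE filter
    FC > 1.2 with raw p < 0.05, enrichment p < 0.05.
    """

    sumstats: str
    weights: str
    ld_dir: str
    de_table: str
    gmt: str
    out_dir: str
    ref_alleles: str | None = None
    p_twas: float = 0.05
    p_perm: float = 0.05
    bonferroni_alpha: float = 0.05
    fc_thresh: float = 1.2
    de_p: float = 0.05
    go_p: float = 0.05
    n_perm: int = DEFAULT_N_PERM
    direction: str = "symmetric"
    enrichment_method: str = "hypergeometric"
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP
    seed: int = 0
    qq_plot: bool = False

    def __post_init__(self) -> None:
        for name in ("p_twas", "p_perm", "bonferroni_alpha", "de_p", "go_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.fc_thresh <= 1:
            raise ConfigError("fc_thresh must exceed 1")
        if self.n_perm < 0:
            raise ConfigError("n_perm must be >= 0")
        if self.direction not in ("symmetric", "up_only"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if self.enrichment_method not in ("hypergeometric", "ease"):
            raise ConfigError(f"unknown enrichment method {self.enrichment_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _check_inputs(cfg: PipelineConfig) -> None:
    paths = [cfg.sumstats, cfg.weights, cfg.ld_dir, cfg.de_table, cfg.gmt]
    if cfg.ref_alleles:
        paths.append(cfg.ref_alleles)
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"input path(s) not found: {missing}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and write all stage outputs.

    Returns the run summary (also written to ``summary.json``): features
    tested and skipped, genomic inflation factor, Bonferroni bookkeeping,
    significant features, DE gene count, overlap counts and significant
    enrichment terms.
    """
    _check_inputs(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("twaskit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("twaskit %s starting; seed=%d", __version__, cfg.seed)
        log.info("config: %s", json.dumps(asdict(cfg)))

        ss = read_sumstats(cfg.sumstats)
        if cfg.ref_alleles:
            ref = pd.read_csv(cfg.ref_alleles, sep="\t", dtype=str)
            panel_alleles = {
                r.SNP: (r.A1, r.A2) for r in ref.itertuples(index=False)
            }
            ss, audit = harmonize_alleles(ss, panel_alleles)
            log.info(
                "harmonization: %d matched, %d flipped, %d ambiguous, %d absent, %d mismatch",
                audit.n_matched, audit.n_flipped, audit.n_ambiguous_dropped,
                audit.n_absent_dropped, audit.n_mismatch_dropped,
            )

        store = LdStore.from_dir(cfg.ld_dir)
        features = load_weights(cfg.weights)
        results, skips = scan_panels(
            ss, features, store,
            min_overlap_fraction=cfg.min_overlap_fraction,
            n_perm=cfg.n_perm, seed=cfg.seed,
        )
        write_results(results, out / "twas_results.tsv")
        pd.DataFrame(
            [(s.gene, s.panel, s.reason) for s in skips],
            columns=["GENE", "PANEL", "REASON"],
        ).to_csv(out / "skipped.tsv", sep="\t", index=False)

        lam = genomic_lambda([r.z_twas for r in results]) if results else float("nan")
        m = len(results)
        bonf_thresh = bonferroni_threshold(cfg.bonferroni_alpha, m) if m else float("nan")
        n_bonf = count_bonferroni_hits(
            [r.z_twas for r in results], cfg.bonferroni_alpha, m
        ) if m else 0

        sig = significant_features(results, cfg.p_twas, cfg.p_perm)
        write_results(sig, out / "significant_features.tsv")

        de = read_de_table(cfg.de_table)
        de_genes = filter_de(de, cfg.fc_thresh, cfg.de_p, cfg.direction)
        overlap = intersect_with_de(sig, de_genes)
        write_overlap_table(overlap, out / "overlap.tsv", de_table=de)
        overlap.feature_rows.to_csv(out / "overlap_features.tsv", sep="\t", index=False)

        collection = read_gmt(cfg.gmt)
        enrichment = enrich(
            overlap.unique_genes, collection,
            method=cfg.enrichment_method, p_thresh=cfg.go_p,
        )
        write_enrichment(enrichment, out / "enrichment.tsv")

        if cfg.qq_plot and results:
            save_qq_plot([r.p_twas for r in results], out / "qq.png")

        summary = {
            "twaskit_version": __version__,
            "seed": cfg.seed,
            "n_features_tested": m,
            "n_features_skipped": len(skips),
            "genomic_lambda": lam,
            "bonferroni_threshold": bonf_thresh,
            "n_bonferroni_hits": n_bonf,
            "n_significant_features": len(sig),
            "n_de_genes": len(de_genes),
            "n_overlap_features": overlap.n_features,
            "n_overlap_genes": overlap.n_unique,
            "n_multi_panel_genes": len(overlap.multi_panel_genes),
            "overlap_genes": overlap.unique_genes,
            "per_panel_counts": overlap.per_panel_counts,
            "n_significant_terms": sum(r.significant for r in enrichment),
            "top_term": enrichment[0].term_id if enrichment else None,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        log.info("pipeline finished: %s", json.dumps(summary))
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def report_top(results: Sequence[TwasResult], k: int = 10) -> pd.DataFrame:
    """Top ``k`` features by ascending p_TWAS, ties broken by gene symbol."""
    frame = results_frame(results)
    frame = frame.sort_values(["P_TWAS", "GENE"], kind="mergesort").reset_index(drop=True)
    return frame.head(k)


def save_qq_plot(p_values: Sequence[float], path: str | Path) -> None:
    """Observed-vs-expected -log10(p) Q-Q plot of the scan."""
    import numpy as np
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    expected = -np.log10((np.arange(n) + 0.5) / n)
    observed = -np.log10(p)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(expected, observed, "o", ms=3)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
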