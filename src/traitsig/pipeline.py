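"""End-to-end orchestration: simulate -> filter -> discover -> cluster ->
validate -> motif-enrich, driven by a flat key=value config with fixed
per-stage seeds and a JSON run manifest."""
from __future__ import annotations

import ast
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, motifs, simulate, study, validation

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "discover", "cluster", "validate", "motifs")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the analysis conventions
    (FDR bound 0.10, WL cut 5 %, SI cut 5 mg/l, threshold fraction 0.8,
    1,500 bp promoter window)."""

    out_dir: str = "run"
    # optional external inputs; empty string means "simulate instead"
    expression_tsv: str = ""
    detection_tsv: str = ""
    clinical_tsv: str = ""
    fg_fasta: str = ""
    bg_fasta: str = ""
    ct_tsv: str = ""
    pfm_dir: str = ""  # empty -> packaged motif collection
    # analysis constants
    covariate: str = "weight_loss_pct"
    fdr_bound: float = 0.10
    wl_cut: float = 5.0
    si_cut: float = 5.0
    threshold_fraction: float = 0.8
    pseudocount: float = 1.0
    promoter_window: int = 1500
    sd_quantile: float = 0.0
    n_permutations: int = 200
    s0_mode: str = "auto"
    cluster_method: str = "hierarchical"
    cluster_k: int = 2
    alpha: float = 0.05
    n_qpcr_targets: int = 9
    # simulation shape
    sim_n_samples: int = 21
    sim_n_genes: int = 2000
    sim_n_pos: int = 74
    sim_n_neg: int = 9
    sim_noise_sd: float = 1.0
    sim_frac_absent: float = 0.05
    sim_n_fg_promoters: int = 80
    sim_n_bg_promoters: int = 400
    # planted motif rates, e.g. "AP2LIKE=0.8/0.2;FKHLIKE=0/0.5"
    planted_motif_rates: str = ""
    # per-stage seeds
    seed_simulate: int = 11
    seed_sam: int = 12
    seed_cluster: int = 13

    def parsed_rates(self) -> dict[str, tuple[float, float]]:
        rates: dict[str, tuple[float, float]] = {}
        if not self.planted_motif_rates:
            return rates
        for part in self.planted_motif_rates.split(";"):
            part = part.strip()
            if not part:
                continue
            motif_id, pair = part.split("=")
            fg, bg = pair.split("/")
            rates[motif_id.strip()] = (float(fg), float(bg))
        return rates

    def config_hash(self) -> str:
        canonical = "\n".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in sorted(fields(self), key=lambda f: f.name)
        )
        return hashlib.sha256(canonical.encode()).hexdigest()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


def _write_table(df: pd.DataFrame, path: Path, index_label="gene_id") -> int:
    df.to_csv(path, sep="\t", index_label=index_label)
    return len(df)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order, writing every intermediate table plus a
    manifest.  Re-running with the same config reproduces identical numeric
    outputs.  Any stage failure aborts with the stage name; partial outputs
    are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": {
            "simulate": config.seed_simulate,
            "sam": config.seed_sam,
            "cluster": config.seed_cluster,
        },
        "stages": [],
    }
    config.to_file(out / "config.txt")

    def record(stage: str, rows: int) -> None:
        manifest["stages"].append({"name": stage, "status": "completed", "rows": rows})
        logger.info("stage %s completed (%d rows)", stage, rows)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"].append({"name": stage, "status": "failed", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineStageError(stage, exc)

    matrices = None
    sim_cfg = None

    # -- simulate / load --------------------------------------------------
    try:
        if config.pfm_dir:
            matrices = motifs.load_pfm_directory(
                config.pfm_dir, config.threshold_fraction, config.pseudocount
            )
        else:
            matrices = motifs.builtin_motifs(config.threshold_fraction, config.pseudocount)
        if config.expression_tsv:
            current = study.read_study(
                config.expression_tsv,
                config.detection_tsv,
                config.clinical_tsv,
                wl_cut=config.wl_cut,
                si_cut=config.si_cut,
            )
            fg = motifs.PromoterSet.from_fasta(config.fg_fasta) if config.fg_fasta else None
            bg = motifs.PromoterSet.from_fasta(config.bg_fasta) if config.bg_fasta else None
            ct = (
                validation.CtTable.from_tsv(config.ct_tsv) if config.ct_tsv else None
            )
        else:
            sim_cfg = simulate.SimConfig(
                n_samples=config.sim_n_samples,
                n_genes=config.sim_n_genes,
                n_pos_signature=config.sim_n_pos,
                n_neg_signature=config.sim_n_neg,
                noise_sd=config.sim_noise_sd,
                frac_absent=config.sim_frac_absent,
                n_fg_promoters=config.sim_n_fg_promoters,
                n_bg_promoters=config.sim_n_bg_promoters,
                planted_motif_rates=config.parsed_rates(),
                wl_cut=config.wl_cut,
                si_cut=config.si_cut,
                seed=config.seed_simulate,
            )
            current = simulate.generate_expression_study(sim_cfg)
            fg, bg = simulate.generate_promoter_sets(sim_cfg, matrices)
            planted = current.truth[current.truth["direction"] != 0]
            target_genes = list(planted.index[: config.n_qpcr_targets])
            ct = simulate.generate_ct_table(sim_cfg, current, target_genes)
            study.write_study(
                current,
                out / "expression.tsv",
                out / "detection.tsv",
                out / "clinical.tsv",
            )
            fg.to_fasta(out / "fg_promoters.fasta")
            bg.to_fasta(out / "bg_promoters.fasta")
            ct.to_tsv(out / "ct.tsv")
        record("simulate", current.n_genes)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail("simulate", exc)

    # -- filter -----------------------------------------------------------
    try:
        filtered = study.filter_all_absent(current)
        if config.sd_quantile > 0:
            filtered = study.filter_low_sd(filtered, config.sd_quantile)
        study.write_study(
            filtered,
            out / "expression.filtered.tsv",
            out / "detection.filtered.tsv",
            out / "clinical.filtered.tsv",
        )
        record("filter", filtered.n_genes)
    except Exception as exc:
        fail("filter", exc)

    # -- discover ---------------------------------------------------------
    try:
        sam = discovery.sam_quantitative(
            filtered,
            covariate_name=config.covariate,
            n_permutations=config.n_permutations,
            s0_mode=config.s0_mode,
            seed=config.seed_sam,
        )
        mod = discovery.moderated_covariate_test(filtered, covariate_name=config.covariate)
        pearson = discovery.pearson_per_gene(filtered, covariate_name=config.covariate)
        stats_table = discovery.gene_stat_table(sam, mod, pearson)
        signature = discovery.intersect_signature(sam, mod, config.fdr_bound)
        _write_table(stats_table, out / "gene_stats.tsv")
        signature.to_tsv(out / "signature.tsv")
        record("discover", len(signature))
    except Exception as exc:
        fail("discover", exc)

    # -- cluster ----------------------------------------------------------
    try:
        clustering = validation.cluster_subjects(
            filtered,
            signature,
            method=config.cluster_method,
            k=config.cluster_k,
            seed=config.seed_cluster,
        )
        pd.DataFrame(
            {
                "sample_id": filtered.sample_ids,
                "cluster": clustering.labels,
                "wl_label": filtered.wl_labels(),
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        manifest["cluster_accuracy"] = clustering.accuracy
        record("cluster", len(clustering.labels))
    except Exception as exc:
        fail("cluster", exc)

    # -- validate ---------------------------------------------------------
    try:
        if ct is None:
            raise ValueError("no Ct table available for the validate stage")
        dct = validation.delta_ct(ct)
        dct.to_csv(out / "delta_ct.tsv", sep="\t", index=False)
        trait = dict(zip(filtered.sample_ids, filtered.covariate(config.covariate)))
        qpcr = validation.qpcr_trait_correlation(ct, trait)
        array_r = pearson["pearson_r"].reindex(ct.target_genes).dropna()
        report = validation.concordance(array_r, qpcr, alpha=config.alpha)
        report.to_tsv(out / "concordance.tsv")
        manifest["n_validated"] = report.n_validated
        manifest["n_tested"] = report.n_tested
        record("validate", report.n_tested)
    except Exception as exc:
        fail("validate", exc)

    # -- motifs -----------------------------------------------------------
    try:
        if fg is None or bg is None:
            raise ValueError("no promoter sets available for the motifs stage")
        fg_win = fg.truncated(config.promoter_window)
        bg_win = bg.truncated(config.promoter_window)
        fg_profiles, bg_profiles = motifs.profile_sets(matrices, fg_win, bg_win)
        table = motifs.enrichment_table(fg_profiles, bg_profiles)
        _write_table(table, out / "motif_enrichment.tsv", index_label="motif_id")
        z = table[["z_score"]].rename(columns={"z_score": "foreground"})
        motifs.enrichment_heatmap(z, out / "motif_heatmap.tsv")
        record("motifs", len(table))
    except Exception as exc:
        fail("motifs", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
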