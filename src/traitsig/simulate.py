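"""Synthetic study generation: expression matrices with planted
trait-correlated genes, promoter sets with planted motif occurrences, and
replicate-level qPCR Ct tables.

All three generators draw from independent substreams of ``config.seed`` so
outputs are bit-identical for identical (config, seed) regardless of call
order.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import PromoterSet, WeightMatrix
from .study import ExpressionStudy
from .validation import CtTable, DEFAULT_REFERENCE_GENE

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``target_abs_correlation_range`` is the |r| band for positively planted
    genes; ``neg_correlation_range`` overrides it for the negative direction
    (``None`` reuses the positive band).  Covariate units are percent weight
    loss; expression is on a log2-like scale and ``noise_sd`` is its
    within-gene residual SD (the source study reports no noise magnitude, so
    this is a free parameter with default 1.0).
    """

    n_samples: int = 21
    n_genes: int = 20000
    n_pos_signature: int = 74
    n_neg_signature: int = 9
    target_abs_correlation_range: tuple[float, float] = (0.57, 0.82)
    neg_correlation_range: tuple[float, float] | None = (0.65, 0.74)
    covariate_range: tuple[float, float] = (-0.5, 43.8)
    noise_sd: float = 1.0
    frac_absent: float = 0.05
    n_fg_promoters: int = 80
    n_bg_promoters: int = 800
    promoter_length: int = 1500
    planted_motif_rates: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    gc_content: float = 0.5
    wl_cut: float = 5.0
    si_cut: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_pos_signature", "n_neg_signature",
                     "n_fg_promoters", "n_bg_promoters", "promoter_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_pos_signature + self.n_neg_signature > self.n_genes:
            raise ValueError(
                "n_pos_signature + n_neg_signature exceeds n_genes "
                f"({self.n_pos_signature} + {self.n_neg_signature} > {self.n_genes})"
            )
        lo, hi = self.covariate_range
        if not lo < hi:
            raise ValueError(f"covariate_range lower must be < upper, got {self.covariate_range}")
        for name in ("target_abs_correlation_range", "neg_correlation_range"):
            band = getattr(self, name)
            if band is None:
                continue
            blo, bhi = band
            if not (0 < blo <= bhi < 1):
                raise ValueError(f"{name} must satisfy 0 < lower <= upper < 1, got {band}")
        for name in ("frac_absent", "gc_content"):
            frac = getattr(self, name)
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for motif_id, (fg_rate, bg_rate) in self.planted_motif_rates.items():
            if fg_rate < 0 or bg_rate < 0:
                raise ValueError(f"planted_motif_rates[{motif_id!r}] must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the three output artifacts."""
        return np.random.default_rng([self.seed, stream])

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")


@dataclass
class SimulatedExpressionStudy(ExpressionStudy):
    """An :class:`ExpressionStudy` carrying its planting ground truth.

    ``truth`` has one row per gene: ``direction`` (+1/-1/0), ``target_r``
    and ``slope``.  It survives gene-subsetting filters unchanged (it always
    describes the full generated gene universe).
    """

    truth: pd.DataFrame | None = None


# -- covariate model -----------------------------------------------------

def _draw_covariate(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Right-skewed weight-loss distribution over ``covariate_range``.

    A two-component mixture mimics the cohort structure the analysis assumes:
    weight-stable subjects uniform below the WL cut, weight-losing subjects
    on a shifted, truncated gamma tail above it.  With the default range the
    overall mean lands near 8.9 %.
    """
    lo, hi = config.covariate_range
    cut = config.wl_cut
    n = config.n_samples
    stable_hi = cut - 0.1 * (cut - lo)
    losing_lo = cut + 0.18 * (hi - cut)
    if hi <= cut or lo >= stable_hi or losing_lo >= hi:
        return rng.uniform(lo, hi, size=n)
    is_stable = rng.random(n) < 0.6
    y = np.empty(n)
    y[is_stable] = rng.uniform(lo, stable_hi, size=int(is_stable.sum()))
    n_losing = int((~is_stable).sum())
    scale = 0.142 * (hi - cut)
    tail = losing_lo + rng.gamma(1.2, scale, size=n_losing)
    for _ in range(100):
        over = tail > hi
        if not over.any():
            break
        tail[over] = losing_lo + rng.gamma(1.2, scale, size=int(over.sum()))
    y[~is_stable] = np.minimum(tail, hi)
    return y


def _target_correlations(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Per-gene planted |r| targets (0 for null genes)."""
    targets = np.zeros(config.n_genes)
    pos_lo, pos_hi = config.target_abs_correlation_range
    neg_band = config.neg_correlation_range or config.target_abs_correlation_range
    n_pos, n_neg = config.n_pos_signature, config.n_neg_signature
    targets[:n_pos] = rng.uniform(pos_lo, pos_hi, size=n_pos)
    targets[n_pos : n_pos + n_neg] = rng.uniform(*neg_band, size=n_neg)
    return targets


def generate_expression_study(config: SimConfig) -> SimulatedExpressionStudy:
    """Generate a log-expression study with planted trait-correlated genes.

    Planted gene g follows ``baseline_g + slope_g * covariate + noise`` with
    ``slope = +/- r * noise_sd / (sd(covariate) * sqrt(1 - r^2))`` so the
    target correlation is the population Pearson r.  A ``frac_absent``
    fraction of non-signature genes is flagged absent on every array (planted
    genes are never absented, so the all-absent filter cannot silently remove
    planted signal).
    """
    rng = config.rng(0)
    n_g, n_s = config.n_genes, config.n_samples
    y = _draw_covariate(rng, config)
    sd_y = y.std(ddof=1)

    targets = _target_correlations(rng, config)
    direction = np.zeros(n_g, dtype=int)
    direction[: config.n_pos_signature] = 1
    direction[config.n_pos_signature : config.n_pos_signature + config.n_neg_signature] = -1

    if config.noise_sd > 0 and sd_y > 0:
        slope = direction * targets * config.noise_sd / (sd_y * np.sqrt(1 - targets**2))
    else:  # noiseless limit: any nonzero slope yields |r| = 1
        slope = direction.astype(float)

    baseline = rng.normal(7.0, 1.0, size=n_g)
    noise = rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    values = baseline[:, None] + slope[:, None] * y[None, :] + noise

    detected = np.ones((n_g, n_s), dtype=bool)
    null_idx = np.flatnonzero(direction == 0)
    n_absent = min(int(round(config.frac_absent * n_g)), null_idx.size)
    if n_absent:
        absent = rng.choice(null_idx, size=n_absent, replace=False)
        detected[absent, :] = False

    gene_ids = [f"G{i:06d}" for i in range(n_g)]
    sample_ids = [f"S{j:03d}" for j in range(n_s)]
    bmi = np.clip(rng.normal(25.5, 3.0, size=n_s), 16.0, 42.0)
    crp = rng.lognormal(math.log(8.0), 1.0, size=n_s)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "weight_loss_pct": y,
            "bmi": bmi,
            "crp": crp,
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "direction": direction,
            "target_r": direction * targets,
            "slope": slope,
        }
    ).set_index("gene_id")
    return SimulatedExpressionStudy(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        detected=detected,
        clinical=clinical,
        wl_cut=config.wl_cut,
        si_cut=config.si_cut,
        truth=truth,
    )


# -- promoter sets -------------------------------------------------------

def _random_sequences(
    rng: np.random.Generator, n: int, length: int, gc: float
) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=probs).astype(np.uint8)


def _sample_site(rng: np.random.Generator, motif: WeightMatrix) -> np.ndarray:
    probs = motif.site_probabilities()
    return np.array(
        [rng.choice(4, p=probs[:, j]) for j in range(motif.length)], dtype=np.uint8
    )


def _plant_motif(
    rng: np.random.Generator,
    seqs: np.ndarray,
    motif: WeightMatrix,
    rate: float,
    occupied: list[list[tuple[int, int]]],
) -> int:
    """Insert Poisson(rate) occurrences per sequence at non-overlapping
    uniform positions; returns the number of insertions actually placed."""
    L = motif.length
    length = seqs.shape[1]
    placed = 0
    for i in range(seqs.shape[0]):
        k = rng.poisson(rate)
        for _ in range(k):
            site = _sample_site(rng, motif)
            for _attempt in range(100):
                start = int(rng.integers(0, length - L + 1))
                if all(start + L <= s or start >= e for s, e in occupied[i]):
                    seqs[i, start : start + L] = site
                    occupied[i].append((start, start + L))
                    placed += 1
                    break
            else:
                logger.warning("could not place a motif occurrence without overlap")
    return placed


def _generate_set(
    rng: np.random.Generator,
    config: SimConfig,
    motifs: Sequence[WeightMatrix],
    n: int,
    which: int,
    prefix: str,
) -> tuple[PromoterSet, dict[str, int]]:
    seqs = _random_sequences(rng, n, config.promoter_length, config.gc_content)
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    counts: dict[str, int] = {}
    by_id = {m.motif_id: m for m in motifs}
    for motif_id, rates in config.planted_motif_rates.items():
        if motif_id not in by_id:
            raise ValueError(f"planted motif {motif_id!r} has no matrix")
        rate = rates[which]
        if rate > 0:
            counts[motif_id] = _plant_motif(rng, seqs, by_id[motif_id], rate, occupied)
        else:
            counts[motif_id] = 0
    names = [f"{prefix}_{i:04d}" for i in range(n)]
    sequences = {
        name: bytes(_BASES[row]).decode("ascii") for name, row in zip(names, seqs)
    }
    return PromoterSet(sequences), counts


def generate_promoter_sets(
    config: SimConfig,
    motifs: Sequence[WeightMatrix],
    with_counts: bool = False,
):
    """Generate (foreground, background) promoter sets with planted motifs.

    Background composition is i.i.d. with the configured GC content; each
    planted motif is inserted at its per-promoter Poisson rate (foreground
    and background rates are independent — a ``(0, high)`` pair simulates
    depletion).  ``with_counts=True`` additionally returns the realized
    insertion counts per set for calibration tests.
    """
    planted_ids = [m for m, r in config.planted_motif_rates.items() if max(r) > 0]
    by_id = {m.motif_id: m for m in motifs}
    for motif_id in planted_ids:
        if motif_id not in by_id:
            raise ValueError(f"planted motif {motif_id!r} has no matrix")
        if by_id[motif_id].length > config.promoter_length:
            raise ValueError(
                f"motif {motif_id!r} (length {by_id[motif_id].length}) is longer "
                f"than promoter_length={config.promoter_length}"
            )
    rng = config.rng(1)
    fg, fg_counts = _generate_set(rng, config, motifs, config.n_fg_promoters, 0, "fg")
    bg, bg_counts = _generate_set(rng, config, motifs, config.n_bg_promoters, 1, "bg")
    if with_counts:
        return fg, bg, fg_counts, bg_counts
    return fg, bg


# -- qPCR Ct tables ------------------------------------------------------

def generate_ct_table(
    config: SimConfig,
    study: ExpressionStudy,
    target_genes: Sequence[str],
    replicates: int = 3,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    reference_ct: float = 10.0,
    offset: float = 25.0,
    replicate_sd: float = 0.15,
) -> CtTable:
    """Replicate-level Ct values so that -delta-Ct tracks log expression.

    For each sample and target gene, ``Ct = reference_ct + offset -
    log-expression + noise`` per replicate well, plus triplicate reference
    wells around ``reference_ct``.
    """
    unknown = [g for g in target_genes if g not in study.gene_ids]
    if unknown:
        raise ValueError(f"unknown gene id(s): {unknown}")
    rng = config.rng(2)
    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    rows = []
    for s_idx, sample in enumerate(study.sample_ids):
        for rep in range(1, replicates + 1):
            ct = reference_ct + rng.normal(0.0, replicate_sd)
            rows.append((sample, reference_gene, rep, ct))
        for gene in target_genes:
            expr = study.values[gene_index[gene], s_idx]
            for rep in range(1, replicates + 1):
                ct = reference_ct + offset - expr + rng.normal(0.0, replicate_sd)
                rows.append((sample, gene, rep, ct))
    data = pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"])
    if (data["ct"] <= 0).any():
        raise ValueError(
            "generated non-positive Ct values; increase `offset` relative to "
            "the expression scale"
        )
    return CtTable(data=data, reference_gene=reference_gene)
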