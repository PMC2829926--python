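"""Expression-study container, TSV round-tripping and pre-analysis filters.

An :class:`ExpressionStudy` bundles a genes x samples log-expression matrix
with per-cell detection flags and a per-sample clinical table (percent weight
loss, BMI, CRP).  Subjects are labelled weight-losing (``WL``) at >= 5 %
weight loss and flagged as systemically inflamed at CRP >= 5 mg/l; both cuts
are configurable.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default percent-weight-loss cut separating weight-losing from weight-stable
WL_CUT = 5.0
#: default CRP (mg/l) cut defining systemic inflammation
SI_CUT = 5.0

_CLINICAL_COLUMNS = ("sample_id", "weight_loss_pct", "bmi", "crp")


def _derive_labels(clinical: pd.DataFrame, wl_cut: float, si_cut: float) -> pd.DataFrame:
    clinical = clinical.copy()
    clinical["wl_label"] = np.where(
        clinical["weight_loss_pct"].astype(float) >= wl_cut, "WL", "WS"
    )
    crp = pd.to_numeric(clinical["crp"], errors="coerce")
    # SI undefined when CRP missing; keep as pandas NA so downstream can skip
    clinical["si_flag"] = pd.array(crp >= si_cut, dtype="boolean")
    clinical.loc[crp.isna(), "si_flag"] = pd.NA
    if crp.isna().any():
        logger.warning(
            "%d sample(s) lack CRP values; SI flag undefined for them",
            int(crp.isna().sum()),
        )
    return clinical


@dataclass
class ExpressionStudy:
    """Log-expression matrix with detection flags and aligned clinical data.

    Parameters
    ----------
    gene_ids, sample_ids
        Row and column identifiers.
    values
        ``(n_genes, n_samples)`` float array of log-scale expression.
    detected
        Boolean array of the same shape; ``True`` where the platform called
        the gene present (or marginal) on that array.
    clinical
        Per-sample table with columns ``sample_id``, ``weight_loss_pct``,
        ``bmi`` and ``crp``, one row per sample in matrix column order.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    detected: np.ndarray
    clinical: pd.DataFrame
    wl_cut: float = WL_CUT
    si_cut: float = SI_CUT

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.values.shape != shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.detected.shape != self.values.shape:
            raise ValueError(
                f"detected shape {self.detected.shape} differs from values "
                f"shape {self.values.shape}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids contains duplicates")
        missing = [c for c in _CLINICAL_COLUMNS if c not in self.clinical.columns]
        if missing:
            raise ValueError(f"clinical table lacks columns: {missing}")
        clin_ids = [str(s) for s in self.clinical["sample_id"]]
        if clin_ids != self.sample_ids:
            raise ValueError("clinical rows are not aligned 1:1 with sample_ids")
        if "wl_label" not in self.clinical.columns or "si_flag" not in self.clinical.columns:
            self.clinical = _derive_labels(self.clinical, self.wl_cut, self.si_cut)
        self.clinical = self.clinical.reset_index(drop=True)

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def covariate(self, name: str) -> np.ndarray:
        """Return a clinical column as a float vector in sample order."""
        if name not in self.clinical.columns:
            raise KeyError(f"unknown clinical covariate {name!r}")
        return self.clinical[name].to_numpy(dtype=float)

    def wl_labels(self) -> np.ndarray:
        return self.clinical["wl_label"].to_numpy(dtype=object)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionStudy":
        """Return the study restricted to genes where ``keep`` is True,
        preserving order.  Subclasses (and their extra fields) survive."""
        keep = np.asarray(keep, dtype=bool)
        return dataclasses.replace(
            self,
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k],
            values=self.values[keep],
            detected=self.detected[keep],
        )

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# -- filters -------------------------------------------------------------

def filter_all_absent(study: ExpressionStudy) -> ExpressionStudy:
    """Drop genes called absent on every array; keep genes detected on >= 1."""
    keep = study.detected.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_all_absent: removed %d all-absent gene(s)", n_dropped)
    return study.subset_genes(keep)


def filter_low_sd(study: ExpressionStudy, sd_quantile: float = 0.25) -> ExpressionStudy:
    """Drop genes whose across-sample SD falls below the given quantile of
    all gene SDs.

    ``sd_quantile=0`` is the identity.  Note the threshold is recomputed from
    the surviving genes on re-application, so unlike :func:`filter_all_absent`
    this filter is not idempotent for ``sd_quantile > 0``.
    """
    if not 0 <= sd_quantile < 1:
        raise ValueError(f"sd_quantile must be in [0, 1), got {sd_quantile}")
    if study.n_samples < 2:
        raise ValueError("filter_low_sd requires >= 2 samples")
    sds = study.values.std(axis=1, ddof=1)
    threshold = float(np.quantile(sds, sd_quantile))
    keep = sds >= threshold
    return study.subset_genes(keep)


# -- TSV input / output --------------------------------------------------

def write_study(
    study: ExpressionStudy,
    expression_path,
    detection_path,
    clinical_path,
) -> None:
    """Write the three TSV files (expression, P/A detection flags, clinical)."""
    study.expression_frame().to_csv(expression_path, sep="\t", index_label="gene_id")
    det = pd.DataFrame(
        np.where(study.detected, "P", "A"),
        index=study.gene_ids,
        columns=study.sample_ids,
    )
    det.to_csv(detection_path, sep="\t", index_label="gene_id")
    clin = study.clinical.copy()
    clin.to_csv(clinical_path, sep="\t", index=False)


def read_study(
    expression_path,
    detection_path,
    clinical_path,
    wl_cut: float = WL_CUT,
    si_cut: float = SI_CUT,
) -> ExpressionStudy:
    """Read an :class:`ExpressionStudy` from its three TSV files.

    The detection file uses the P/M/A dialect; marginal (``M``) counts as
    detected.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    det = pd.read_csv(detection_path, sep="\t", index_col=0, dtype=str)
    if list(det.index) != list(expr.index) or list(det.columns) != list(expr.columns):
        raise ValueError("expression and detection TSVs have mismatched shapes or ids")
    flags = det.to_numpy(dtype=str)
    bad = set(np.unique(flags)) - {"P", "M", "A"}
    if bad:
        raise ValueError(f"detection flags must be P, M or A; found {sorted(bad)}")
    clinical = pd.read_csv(clinical_path, sep="\t")
    return ExpressionStudy(
        gene_ids=list(expr.index.astype(str)),
        sample_ids=list(expr.columns.astype(str)),
        values=expr.to_numpy(dtype=float),
        detected=np.isin(flags, ("P", "M")),
        clinical=clinical,
        wl_cut=wl_cut,
        si_cut=si_cut,
    )
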