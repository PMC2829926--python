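"""Signature validation: subject clustering, qRT-PCR delta-Ct quantification,
cross-platform concordance scoring and comparative marker-panel analysis."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .discovery import SignatureSet, pearson_per_gene  # noqa: F401 (re-export)
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENE = "18S"


# -- qRT-PCR -------------------------------------------------------------

@dataclass
class CtTable:
    """Replicate-level qPCR Ct values with a designated reference gene.

    ``data`` columns: ``sample_id``, ``gene_id``, ``replicate``, ``ct``.
    """

    data: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable lacks columns: {sorted(missing)}")
        if (self.data["ct"].astype(float) <= 0).any():
            raise ValueError("all Ct values must be positive")
        self.data = self.data.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"].astype(str)))

    @property
    def target_genes(self) -> list[str]:
        genes = pd.unique(self.data["gene_id"].astype(str))
        return [g for g in genes if g != self.reference_gene]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, reference_gene: str = DEFAULT_REFERENCE_GENE) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene=reference_gene)


def delta_ct(ct: CtTable) -> pd.DataFrame:
    """Replicate-averaged delta-Ct per (sample, gene) plus 2^-dCt.

    delta_ct = mean Ct(target) - mean Ct(reference gene, same sample).
    Samples lacking the reference gene have their targets reported missing.
    """
    means = (
        ct.data.groupby(["sample_id", "gene_id"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = means[means["gene_id"] == ct.reference_gene].set_index("sample_id")["ct"]
    targets = means[means["gene_id"] != ct.reference_gene].copy()
    missing_ref = set(targets["sample_id"]) - set(ref.index)
    if missing_ref:
        logger.warning(
            "delta_ct: no reference gene %r for sample(s) %s; their targets "
            "are reported missing",
            ct.reference_gene,
            sorted(missing_ref),
        )
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.reindex(
        targets["sample_id"]
    ).to_numpy()
    targets["rel_expr"] = 2.0 ** (-targets["delta_ct"])
    return targets[["sample_id", "gene_id", "delta_ct", "rel_expr"]].reset_index(
        drop=True
    )


def qpcr_trait_correlation(
    ct: CtTable, trait: Mapping[str, float]
) -> pd.DataFrame:
    """Per-gene Pearson correlation of -delta-Ct (log-scale relative
    expression) with a per-sample trait value; regression p two-sided."""
    dct = delta_ct(ct).dropna(subset=["delta_ct"])
    known = set(trait)
    rows = []
    for gene, sub in dct.groupby("gene_id", sort=False):
        sub = sub[sub["sample_id"].map(lambda s: s in known)]
        y = np.array([trait[s] for s in sub["sample_id"]])
        x = -sub["delta_ct"].to_numpy()
        if y.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"gene_id": gene, "qpcr_r": np.nan, "qpcr_p": np.nan})
            continue
        res = stats.pearsonr(x, y)
        rows.append(
            {"gene_id": gene, "qpcr_r": float(res.statistic), "qpcr_p": float(res.pvalue)}
        )
    return pd.DataFrame(rows).set_index("gene_id")


# -- concordance ---------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Per-gene platform concordance plus summary counts.

    A gene is validated when both platform coefficients are nonzero with the
    same sign and the qPCR regression p is below alpha; genes missing a qPCR
    coefficient count as tested but not validated.
    """

    table: pd.DataFrame
    n_validated: int
    n_tested: int
    alpha: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def concordance(
    array_r: Mapping[str, float] | pd.Series,
    qpcr: pd.DataFrame | Mapping[str, tuple[float, float]],
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Score sign concordance between array and qPCR trait correlations.

    ``array_r`` maps gene -> platform-A coefficient and defines the tested
    universe.  ``qpcr`` maps gene -> (coefficient, regression p) or is a
    DataFrame with ``qpcr_r``/``qpcr_p`` columns indexed by gene.
    """
    array_r = pd.Series(dict(array_r), dtype=float)
    if isinstance(qpcr, pd.DataFrame):
        qpcr_r = qpcr["qpcr_r"].astype(float)
        qpcr_p = qpcr["qpcr_p"].astype(float)
    else:
        qpcr_r = pd.Series({g: v[0] for g, v in qpcr.items()}, dtype=float)
        qpcr_p = pd.Series({g: v[1] for g, v in qpcr.items()}, dtype=float)
    overlap = [g for g in array_r.index if g in qpcr_r.index and np.isfinite(qpcr_r[g])]
    if not overlap:
        raise ValueError("no genes with coefficients on both platforms")
    rows = []
    for gene in array_r.index:
        a = array_r[gene]
        q = qpcr_r.get(gene, np.nan)
        p = qpcr_p.get(gene, np.nan)
        has_qpcr = np.isfinite(q)
        sign_conc = bool(has_qpcr and a * q > 0)
        validated = bool(sign_conc and np.isfinite(p) and p < alpha)
        rows.append(
            {
                "gene_id": gene,
                "array_r": a,
                "qpcr_r": q,
                "qpcr_p": p,
                "sign_concordant": sign_conc,
                "validated": validated,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return ConcordanceReport(
        table=table,
        n_validated=int(table["validated"].sum()),
        n_tested=int(len(table)),
        alpha=alpha,
    )


# -- subject clustering --------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray
    accuracy: float
    method: str
    k: int


def _best_mapping_accuracy(cluster_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Best cluster-to-label assignment accuracy (each cluster takes its
    majority label; maximises agreement over all mappings)."""
    total = 0
    for c in np.unique(cluster_labels):
        members = true_labels[cluster_labels == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / cluster_labels.size


def cluster_subjects(
    study: ExpressionStudy,
    signature: SignatureSet,
    method: str = "hierarchical",
    k: int = 2,
    seed: int = 0,
) -> ClusterResult:
    """Partition samples on signature-gene expression and score agreement
    with the WL/WS labelling.

    Genes are z-scored across samples first.  Hierarchical clustering uses
    1 - Pearson correlation between subjects with average linkage; k-means
    uses 25 seeded restarts.
    """
    if len(signature) == 0:
        raise ValueError(
            "signature is empty; relax the FDR bound or check the discovery "
            "stage before clustering"
        )
    if not 2 <= k <= study.n_samples:
        raise ValueError(f"k must be in [2, n_samples={study.n_samples}], got {k}")
    idx = [study.gene_ids.index(g) for g in signature.genes if g in study.gene_ids]
    if not idx:
        raise ValueError("no signature genes present in the study")
    if len(idx) < len(signature):
        logger.warning(
            "cluster_subjects: %d signature gene(s) missing from the study",
            len(signature) - len(idx),
        )
    X = study.values[idx]
    sds = X.std(axis=1, ddof=0)
    keep = sds > 0
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sds[keep][:, None]
    subjects = X.T  # samples x genes

    if method == "hierarchical":
        if subjects.shape[1] < 2:
            dist = pdist(subjects, metric="euclidean")
        else:
            dist = pdist(subjects, metric="correlation")
        tree = linkage(dist, method="average")
        labels = fcluster(tree, t=k, criterion="maxclust")
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        labels = km.fit_predict(subjects) + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    accuracy = _best_mapping_accuracy(np.asarray(labels), study.wl_labels())
    return ClusterResult(labels=np.asarray(labels), accuracy=float(accuracy), method=method, k=k)


# -- comparative marker panels -------------------------------------------

@dataclass
class MarkerPanel:
    """A named list of marker genes (e.g. a published top-20 list)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker panel {self.name!r} is empty")


def load_marker_panel(path) -> MarkerPanel:
    """Plain-text panel: one gene id per line, panel name from the filename."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return MarkerPanel(name=path.stem, genes=genes)


@dataclass
class PanelComparison:
    name: str
    table: pd.DataFrame
    n_significant: int


def comparative_panels(
    study: ExpressionStudy,
    panels: Iterable[MarkerPanel],
    group_cut: float = 5.0,
    alpha: float = 0.05,
) -> list[PanelComparison]:
    """Group means +/- SEM and Welch-t p per panel gene, splitting samples at
    ``group_cut`` percent weight loss.  Panel ids absent from the study are
    excluded and logged."""
    wl = study.covariate("weight_loss_pct")
    high = wl >= group_cut
    if not high.any() or high.all():
        raise ValueError(
            f"group_cut={group_cut} does not split the samples into two "
            "non-empty groups"
        )
    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    results = []
    for panel in panels:
        present = [g for g in panel.genes if g in gene_index]
        missing = [g for g in panel.genes if g not in gene_index]
        if missing:
            logger.warning(
                "panel %r: %d id(s) not in the study were excluded: %s",
                panel.name,
                len(missing),
                missing,
            )
        rows = []
        for gene in present:
            x = study.values[gene_index[gene]]
            lo, hi = x[~high], x[high]
            with np.errstate(divide="ignore", invalid="ignore"):
                t_res = stats.ttest_ind(lo, hi, equal_var=False)
            p = float(t_res.pvalue)
            if not np.isfinite(p):  # zero variance in both groups
                p = 1.0
            rows.append(
                {
                    "gene_id": gene,
                    "mean_low": float(lo.mean()),
                    "sem_low": float(stats.sem(lo)) if lo.size > 1 else np.nan,
                    "mean_high": float(hi.mean()),
                    "sem_high": float(stats.sem(hi)) if hi.size > 1 else np.nan,
                    "p_value": p,
                }
            )
        table = pd.DataFrame(
            rows, columns=["gene_id", "mean_low", "sem_low", "mean_high", "sem_high", "p_value"]
        ).set_index("gene_id")
        n_sig = int((table["p_value"] < alpha).sum()) if len(table) else 0
        results.append(PanelComparison(name=panel.name, table=table, n_significant=n_sig))
    return results
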