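"""Promoter motif over/under-representation analysis.

Pipeline: JASPAR-style position frequency matrices are converted to log-ratio
scoring matrices against a zero-order uniform background (pseudo-count 1 by
default); both strands of each promoter are scanned with a hit threshold at a
fixed fraction (default 0.8) of the matrix scoring range; per-sequence hits
feed a Fisher exact test and per-base-pair hits feed a binomial Z-score, each
comparing a foreground promoter set against a background set.

The Z statistic treats every valid window start (both strands, N-containing
windows excluded) as an independent Bernoulli trial at the background hit
rate:  z = (h_fg - n_fg * p_bg) / sqrt(n_fg * p_bg * (1 - p_bg)).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = "ACGT"
# byte -> code lookup: A,C,G,T -> 0..3, N -> 4, anything else -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_N_CODE = 4


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string over {A,C,G,T,N} as uint8 codes (N -> 4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = sorted({chr(c) for c in raw[codes == 255]})
        raise ValueError(f"sequence contains characters outside ACGTN: {bad}")
    return codes


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass
class WeightMatrix:
    """A motif count matrix with its derived log-ratio scoring matrix.

    ``logratio[b, j] = log2(((counts[b, j] + pc) / (col_total_j + 4 pc)) / 0.25)``
    with pseudo-count ``pc``.  ``min_score``/``max_score`` are the sums over
    columns of the column minima/maxima and the hit threshold sits at
    ``min + threshold_fraction * (max - min)``; window scores >= threshold
    count as hits.
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 1.0
    threshold_fraction: float = 0.8
    logratio: np.ndarray = field(init=False, repr=False)
    min_score: float = field(init=False)
    max_score: float = field(init=False)
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(
                f"{self.motif_id}: counts must be 4 x L, got shape {self.counts.shape}"
            )
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: matrix must have >= 1 column")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: counts must be non-negative")
        if not 0 <= self.threshold_fraction <= 1:
            raise ValueError(
                f"threshold_fraction must be in [0, 1], got {self.threshold_fraction}"
            )
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        col_tot = self.counts.sum(axis=0)
        freq = (self.counts + self.pseudocount) / (col_tot + 4 * self.pseudocount)
        self.logratio = np.log2(freq / 0.25)
        self.min_score = float(self.logratio.min(axis=0).sum())
        self.max_score = float(self.logratio.max(axis=0).sum())
        self.threshold = self.min_score + self.threshold_fraction * (
            self.max_score - self.min_score
        )

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def site_probabilities(self) -> np.ndarray:
        """Per-column base probabilities from the raw counts (uniform where a
        column sums to zero); used to sample motif instances."""
        col_tot = self.counts.sum(axis=0)
        probs = np.where(col_tot > 0, self.counts / np.where(col_tot > 0, col_tot, 1), 0.25)
        return probs


def load_pfm(path, threshold_fraction: float = 0.8, pseudocount: float = 1.0) -> WeightMatrix:
    """Parse a JASPAR PFM text file (optional ``>`` header, then 4 count rows).

    Rows may be plain whitespace-separated numbers or the bracketed JASPAR
    dialect ``A [ 3 0 17 ... ]``.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    motif_id = path.stem
    if lines and lines[0].startswith(">"):
        header = lines.pop(0)[1:].strip()
        if header:
            motif_id = header.split()[0]
    if len(lines) != 4:
        raise ValueError(
            f"{path}: expected 4 count rows, found {len(lines)}"
        )
    rows = []
    for lineno, line in enumerate(lines, start=1):
        cleaned = re.sub(r"^[ACGTacgt]\s*", "", line)
        cleaned = cleaned.replace("[", " ").replace("]", " ")
        try:
            row = [float(tok) for tok in cleaned.split()]
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: non-numeric entry ({exc})") from None
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(
            f"{path}: ragged matrix, row lengths {sorted(len(r) for r in rows)}"
        )
    if widths == {0}:
        raise ValueError(f"{path}: empty count rows")
    return WeightMatrix(
        motif_id=motif_id,
        counts=np.array(rows, dtype=float),
        pseudocount=pseudocount,
        threshold_fraction=threshold_fraction,
    )


def load_pfm_directory(
    directory, threshold_fraction: float = 0.8, pseudocount: float = 1.0
) -> list[WeightMatrix]:
    paths = sorted(Path(directory).glob("*.pfm"))
    if not paths:
        raise FileNotFoundError(f"no .pfm files found under {directory}")
    return [load_pfm(p, threshold_fraction, pseudocount) for p in paths]


def builtin_motifs(
    threshold_fraction: float = 0.8, pseudocount: float = 1.0
) -> list[WeightMatrix]:
    """Load the small motif collection shipped with the package."""
    pfm_dir = resources.files("traitsig.data").joinpath("pfms")
    matrices = []
    for entry in sorted(pfm_dir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".pfm"):
            with resources.as_file(entry) as p:
                matrices.append(load_pfm(p, threshold_fraction, pseudocount))
    return matrices


@dataclass
class PromoterSet:
    """Named promoter sequences over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("PromoterSet must be non-empty")
        for name, seq in self.sequences.items():
            encode_sequence(seq)  # raises on bad characters
        self.sequences = {str(k): str(v).upper() for k, v in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def truncated(self, window: int) -> "PromoterSet":
        """Right-truncate sequences longer than ``window`` bp, keeping the 3'
        end nearest the gene start."""
        return PromoterSet({n: s[-window:] for n, s in self.sequences.items()})

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        from Bio import SeqIO

        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq).upper()
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


class Hit(NamedTuple):
    """A motif hit; ``position`` is the forward-strand window start
    (0-based, half-open window of the matrix length)."""

    position: int
    strand: str
    score: float


def _window_scores(codes: np.ndarray, matrix: WeightMatrix):
    """Forward/reverse window scores plus the N-free validity mask.

    Returns (fwd_scores, rev_scores, valid); rev scores are aligned to
    forward-strand window starts.  Scoring runs column-by-column over shifted
    slices of the code vector, which is far cheaper than gathering a windows
    x length matrix.
    """
    L = matrix.length
    n_win = codes.size - L + 1
    if n_win <= 0:
        empty = np.empty(0)
        return empty, empty, np.empty(0, dtype=bool)
    # pad scoring matrix with a zero row so N codes index safely
    padded = np.vstack([matrix.logratio, np.zeros((1, L))])
    # reverse-complement lookup: complement rows (3 - b, N fixed), reversed columns
    comp = padded[[3, 2, 1, 0, 4], ::-1]
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        seg = codes[j : j + n_win]
        fwd += padded[seg, j]
        rev += comp[seg, j]
        valid &= seg != _N_CODE
    return fwd, rev, valid


def scan(sequence: str, matrix: WeightMatrix) -> list[Hit]:
    """Score every window of both strands; return hits (score >= threshold).

    Windows containing ``N`` are skipped.  Hits are sorted by (position,
    strand) with ``+`` before ``-``.
    """
    codes = encode_sequence(sequence)
    fwd, rev, valid = _window_scores(codes, matrix)
    hits: list[Hit] = []
    thr = matrix.threshold
    for pos in np.flatnonzero(valid & (fwd >= thr)):
        hits.append(Hit(int(pos), "+", float(fwd[pos])))
    for pos in np.flatnonzero(valid & (rev >= thr)):
        hits.append(Hit(int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass(frozen=True)
class HitProfile:
    """Aggregated scan tallies for one (motif, promoter set) pair."""

    motif_id: str
    n_sequences: int
    n_sequences_with_hit: int
    total_hits: int
    total_scanned_bp: int


def _concat_codes(promoters: PromoterSet) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate encoded sequences with single-``N`` separators.

    Separator-spanning windows contain N and are excluded by the validity
    mask, so one pass over the concatenation reproduces per-sequence scanning
    exactly.  Returns (codes, per-sequence start offsets).
    """
    parts: list[np.ndarray] = []
    starts = np.zeros(len(promoters.sequences), dtype=np.int64)
    offset = 0
    sep = np.array([_N_CODE], dtype=np.uint8)
    for i, s in enumerate(promoters.sequences.values()):
        codes = encode_sequence(s)
        starts[i] = offset
        parts.append(codes)
        parts.append(sep)
        offset += codes.size + 1
    big = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    return big, starts


def _profile_codes(
    big: np.ndarray, starts: np.ndarray, n_seqs: int, matrix: WeightMatrix
) -> HitProfile:
    fwd, rev, valid = _window_scores(big, matrix)
    if fwd.size == 0:
        return HitProfile(matrix.motif_id, n_seqs, 0, 0, 0)
    thr = matrix.threshold
    hit_pos = np.concatenate(
        [np.flatnonzero(valid & (fwd >= thr)), np.flatnonzero(valid & (rev >= thr))]
    )
    total_hits = int(hit_pos.size)
    seq_idx = np.searchsorted(starts, hit_pos, side="right") - 1
    n_with_hit = int(np.unique(seq_idx).size)
    total_scanned = 2 * int(valid.sum())
    return HitProfile(matrix.motif_id, n_seqs, n_with_hit, total_hits, total_scanned)


def profile_set(promoters: PromoterSet, matrix: WeightMatrix) -> HitProfile:
    """Scan every promoter with the matrix and aggregate hit tallies.

    ``total_scanned_bp`` counts valid (N-free) window starts on both strands.
    """
    big, starts = _concat_codes(promoters)
    return _profile_codes(big, starts, len(promoters), matrix)


def fisher_sequence_test(
    fg: HitProfile, bg: HitProfile, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher exact test on sequences-with-hit; returns (p, odds ratio).

    The odds ratio is the sample (cross-product) estimate with a Haldane
    +0.5 correction when any cell is zero.
    """
    if fg.n_sequences < 1 or bg.n_sequences < 1:
        raise ValueError("both promoter sets must contain at least one sequence")
    a = fg.n_sequences_with_hit
    b = fg.n_sequences - a
    c = bg.n_sequences_with_hit
    d = bg.n_sequences - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return p, float(odds)


def zscore_bp_test(fg: HitProfile, bg: HitProfile) -> float:
    """Per-base-pair over/under-representation Z-score (positive = over)."""
    if fg.total_scanned_bp <= 0 or bg.total_scanned_bp <= 0:
        raise ValueError("both profiles need total_scanned_bp > 0")
    rate_bg = bg.total_hits / bg.total_scanned_bp
    if rate_bg <= 0 or rate_bg >= 1:
        logger.warning(
            "%s: background hit rate %.3g is degenerate; z undefined",
            fg.motif_id,
            rate_bg,
        )
        return float("nan")
    expected = fg.total_scanned_bp * rate_bg
    denom = np.sqrt(fg.total_scanned_bp * rate_bg * (1 - rate_bg))
    return float((fg.total_hits - expected) / denom)


def enrichment_table(
    fg_profiles: Mapping[str, HitProfile] | Iterable[HitProfile],
    bg_profiles: Mapping[str, HitProfile] | Iterable[HitProfile],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Combine per-motif fg/bg profiles into the enrichment result table."""
    if not isinstance(fg_profiles, Mapping):
        fg_profiles = {p.motif_id: p for p in fg_profiles}
    if not isinstance(bg_profiles, Mapping):
        bg_profiles = {p.motif_id: p for p in bg_profiles}
    if set(fg_profiles) != set(bg_profiles):
        raise ValueError("foreground and background profile motif ids differ")
    rows = []
    for motif_id in sorted(fg_profiles):
        fg = fg_profiles[motif_id]
        bg = bg_profiles[motif_id]
        fisher_p, odds = fisher_sequence_test(fg, bg, alternative=alternative)
        z = zscore_bp_test(fg, bg)
        rows.append(
            {
                "motif_id": motif_id,
                "fg_sequences": fg.n_sequences,
                "fg_with_hit": fg.n_sequences_with_hit,
                "fg_hits": fg.total_hits,
                "fg_scanned_bp": fg.total_scanned_bp,
                "bg_sequences": bg.n_sequences,
                "bg_with_hit": bg.n_sequences_with_hit,
                "bg_hits": bg.total_hits,
                "bg_scanned_bp": bg.total_scanned_bp,
                "fisher_p": fisher_p,
                "odds_ratio": odds,
                "z_score": z,
                "direction": "over" if z > 0 else "under",
            }
        )
    return pd.DataFrame(rows).set_index("motif_id")


def profile_sets(
    matrices: Iterable[WeightMatrix], fg: PromoterSet, bg: PromoterSet
) -> tuple[dict[str, HitProfile], dict[str, HitProfile]]:
    """Profile every matrix against both promoter sets (sequences are
    encoded once per set, not once per matrix)."""
    fg_codes, fg_starts = _concat_codes(fg)
    bg_codes, bg_starts = _concat_codes(bg)
    fg_profiles = {
        m.motif_id: _profile_codes(fg_codes, fg_starts, len(fg), m) for m in matrices
    }
    bg_profiles = {
        m.motif_id: _profile_codes(bg_codes, bg_starts, len(bg), m) for m in matrices
    }
    return fg_profiles, bg_profiles


def enrichment_heatmap(
    z_matrix: pd.DataFrame, tsv_path, image_path=None
) -> pd.DataFrame:
    """Write the motifs x gene-sets z-score matrix with canonical ordering.

    Rows (motif ids) and columns (set names) are sorted lexicographically so
    the written artifact is independent of input order.  If ``image_path`` is
    given a heatmap image is rendered as well.
    """
    ordered = z_matrix.sort_index(axis=0).sort_index(axis=1)
    ordered.to_csv(tsv_path, sep="\t", index_label="motif_id")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(1 + 0.6 * ordered.shape[1], 1 + 0.3 * ordered.shape[0])
        )
        vmax = np.nanmax(np.abs(ordered.to_numpy())) or 1.0
        im = ax.imshow(ordered.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90)
        ax.set_yticks(range(ordered.shape[0]), ordered.index)
        fig.colorbar(im, ax=ax, label="z")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return ordered
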