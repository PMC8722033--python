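"""Multi-exon CNV calling from a cohort exon-depth matrix.

A simplified exome-HMM approach: cohort-wide structured variation (capture
batch, GC, library size) is removed by principal-component subtraction, the
residual per-sample depth series is z-scored, and a 3-state hidden Markov
model (deletion / diploid / duplication) is decoded exon-by-exon with
Viterbi. Only runs of at least three contiguous non-diploid exons become
calls — one- and two-exon excursions are treated as noise and suppressed.

Emission model: z ~ Normal(−M, 1) under DEL, Normal(0, 1) under diploid,
Normal(+M, 1) under DUP (M default 3). Transitions allow entering an event
from diploid with probability ``p_event`` and extending it with ``p_stay``;
direct DEL↔DUP transitions are forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExonDepthMatrix",
    "ExonicCnvCall",
    "NormalizationParams",
    "HmmParams",
    "normalize_exon_matrix",
    "viterbi_call_exonic_cnvs",
    "viterbi_decode",
]

STATES = ("DEL", "DIP", "DUP")


@dataclass
class ExonDepthMatrix:
    """Raw and PCA-normalized exon depths for a cohort.

    ``exons`` has columns chrom, start, end, gene_id in genomic order;
    ``z`` rows are the retained samples, standardized to mean 0 / sd 1.
    """

    sample_ids: list[str]
    exons: pd.DataFrame
    raw: np.ndarray  # retained samples x retained exons
    z: np.ndarray
    excluded_samples: list[str]
    excluded_exons: list[int]


@dataclass(frozen=True)
class ExonicCnvCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    gene_ids: tuple[str, ...]
    state: str  # "DEL" | "DUP"
    n_exons: int
    mean_z: float
    first_exon: int  # index into the normalized exon table
    origin: str = "exonic"

    def __post_init__(self) -> None:
        if self.n_exons < 3:
            raise ValueError("exonic calls must span at least 3 exons")
        if self.state not in ("DEL", "DUP"):
            raise ValueError(f"invalid state {self.state!r}")


@dataclass(frozen=True)
class NormalizationParams:
    min_mean_exon: float = 10.0
    max_mean_exon: float = 2000.0
    min_mean_sample: float = 25.0
    max_mean_sample: float = 500.0
    pc_variance_factor: float = 0.7  # remove PCs with variance > factor x mean


@dataclass(frozen=True)
class HmmParams:
    m: float = 3.0  # |emission mean| for DEL/DUP states
    p_event: float = 1e-4  # DIP -> DEL and DIP -> DUP
    p_stay: float = 0.9  # DEL -> DEL and DUP -> DUP
    min_exons: int = 3


def normalize_exon_matrix(
    depths: pd.DataFrame,
    exons: pd.DataFrame,
    params: NormalizationParams = NormalizationParams(),
    min_samples: int = 10,
    min_exons: int = 20,
) -> ExonDepthMatrix:
    """Filter extreme exons/samples, subtract dominant PCs, z-score rows.

    ``depths`` is samples x exons (row index = sample ids); ``exons`` gives
    per-column chrom/start/end/gene_id in genomic order. Components whose
    variance exceeds ``pc_variance_factor`` x the mean component variance are
    removed — they capture cohort-wide structure, not single-sample CNVs.
    """
    raw = depths.to_numpy(dtype=float)
    sample_ids = [str(s) for s in depths.index]
    exon_means = raw.mean(axis=0)
    keep_exon = (exon_means >= params.min_mean_exon) & (exon_means <= params.max_mean_exon)
    sample_means = raw[:, keep_exon].mean(axis=1) if keep_exon.any() else raw.mean(axis=1)
    keep_sample = (sample_means >= params.min_mean_sample) & (
        sample_means <= params.max_mean_sample
    )
    n_s, n_e = int(keep_sample.sum()), int(keep_exon.sum())
    if n_s < min_samples or n_e < min_exons:
        raise ValueError(
            f"after depth filtering only {n_s} samples and {n_e} exons remain; "
            f"need >= {min_samples} samples and >= {min_exons} exons"
        )
    sub = raw[np.ix_(keep_sample, keep_exon)]
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2
    if variances.size and variances.sum() > 0:
        remove = variances > params.pc_variance_factor * variances.mean()
    else:
        remove = np.zeros_like(variances, dtype=bool)
    residual = centered.copy()
    for k in np.where(remove)[0]:
        residual -= s[k] * np.outer(u[:, k], vt[k])
    row_sd = residual.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(
        residual - residual.mean(axis=1, keepdims=True),
        np.where(row_sd > 1e-12, row_sd, 1.0),
    )
    z[row_sd[:, 0] <= 1e-12] = 0.0  # degenerate flat rows carry no signal
    retained_exons = exons.iloc[np.where(keep_exon)[0]].reset_index(drop=True)
    return ExonDepthMatrix(
        sample_ids=[s for s, k in zip(sample_ids, keep_sample) if k],
        exons=retained_exons,
        raw=sub,
        z=z,
        excluded_samples=[s for s, k in zip(sample_ids, keep_sample) if not k],
        excluded_exons=list(np.where(~keep_exon)[0]),
    )


def _log_transitions(params: HmmParams) -> np.ndarray:
    p_e, p_s = params.p_event, params.p_stay
    trans = np.array(
        [
            [p_s, 1.0 - p_s, 0.0],  # DEL -> (DEL, DIP, DUP)
            [p_e, 1.0 - 2.0 * p_e, p_e],
            [0.0, 1.0 - p_s, p_s],
        ]
    )
    with np.errstate(divide="ignore"):
        return np.log(trans)


def _log_emissions(z: np.ndarray, params: HmmParams) -> np.ndarray:
    means = np.array([-params.m, 0.0, params.m])
    # Normal(mu, 1) log-density up to the shared constant
    return -0.5 * (z[:, None] - means[None, :]) ** 2


def viterbi_decode(z: np.ndarray, params: HmmParams = HmmParams()) -> np.ndarray:
    """Most probable DEL/DIP/DUP state path for one z series (indices into STATES)."""
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        return np.zeros(0, dtype=int)
    log_t = _log_transitions(params)
    log_e = _log_emissions(z, params)
    log_start = np.log(
        np.array([params.p_event, 1.0 - 2.0 * params.p_event, params.p_event])
    )
    score = log_start + log_e[0]
    back = np.zeros((n, 3), dtype=int)
    for t in range(1, n):
        cand = score[:, None] + log_t  # prev x next
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(3)] + log_e[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi_call_exonic_cnvs(
    matrix: ExonDepthMatrix,
    params: HmmParams = HmmParams(),
) -> list[ExonicCnvCall]:
    """Decode every sample per chromosome; emit runs of >= 3 non-diploid exons.

    Calls never span chromosome boundaries; 1–2 exon excursions are dropped.
    """
    calls: list[ExonicCnvCall] = []
    chroms = matrix.exons["chrom"].to_numpy()
    for si, sample_id in enumerate(matrix.sample_ids):
        for chrom in pd.unique(chroms):
            cols = np.where(chroms == chrom)[0]
            path = viterbi_decode(matrix.z[si, cols], params)
            for state_idx, start_j, end_j in _runs(path):
                if state_idx == 1 or (end_j - start_j) < params.min_exons:
                    continue
                run_cols = cols[start_j:end_j]
                sub = matrix.exons.iloc[run_cols]
                calls.append(
                    ExonicCnvCall(
                        sample_id=sample_id,
                        chrom=str(chrom),
                        start=int(sub["start"].iloc[0]),
                        end=int(sub["end"].iloc[-1]),
                        gene_ids=tuple(dict.fromkeys(sub["gene_id"])),
                        state=STATES[state_idx],
                        n_exons=int(end_j - start_j),
                        mean_z=float(matrix.z[si, run_cols].mean()),
                        first_exon=int(run_cols[0]),
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return calls


def _runs(path: np.ndarray):
    """Yield (state, start, end) for maximal constant runs of a state path."""
    if path.size == 0:
        return
    start = 0
    for j in range(1, path.size + 1):
        if j == path.size or path[j] != path[start]:
            yield int(path[start]), start, j
            start = j
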