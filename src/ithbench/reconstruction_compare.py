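"""Agreement metrics between subclonal reconstructions.

Three metrics compare two reconstructions of the same sample:

* **score1B** — adequacy of the clone counts J1 (reference) and J2:
  ``(J1 + 1 - min(J1 + 1, |J2 - J1|)) / (J1 + 1)``; 1 iff equal, 0 when
  the counts differ by at least J1 + 1.
* **score1C** — 1-Wasserstein distance between the two CCF distributions,
  each clone contributing a point mass at its CCF weighted by its share
  of mutations.
* **score2A** — co-clustering agreement on the mutations common to both
  reconstructions: the mean of Pearson, Matthews and V-measure scores
  between the two binary co-assignment matrices, each rescaled against
  the better of two degenerate "bad scenarios" (everything in one clone;
  everything its own clone).

score1B and score2A are asymmetric in reference/prediction roles and are
therefore computed in both orientations when tabulated. A Pearson/BH
correlation screen across ITH measures and confounders completes the
module.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import v_measure_score

from .reconstruction_core import SubclonalReconstruction

logger = logging.getLogger(__name__)

_DEGENERATE_EPS = 1e-12


class NonComparableError(ValueError):
    """Raised when two reconstructions share too few mutations to compare."""


@dataclass(frozen=True)
class CoClusteringMatrix:
    """Binary mutation co-assignment matrix over an ordered mutation set."""

    mutation_order: tuple[str, ...]
    matrix: np.ndarray  # N x N, {0,1}, symmetric, unit diagonal

    @property
    def n(self) -> int:
        return len(self.mutation_order)

    def labels(self) -> np.ndarray:
        """Integer partition labels recovered from the matrix rows."""
        _, labels = np.unique(self.matrix, axis=0, return_inverse=True)
        return labels.ravel()


@dataclass(frozen=True)
class AgreementCounts:
    """Entrywise confusion counts between two binary matrices."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RawAgreementScores:
    pcc: float
    mcc: float
    v_measure: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pcc, self.mcc, self.v_measure)


def score1B(j1: int, j2: int) -> float:
    """Clone-count adequacy of a prediction J2 against a reference J1."""
    if j1 < 1 or j2 < 1:
        raise ValueError("clone counts must be >= 1")
    return (j1 + 1 - min(j1 + 1, abs(j2 - j1))) / (j1 + 1)


def score1C(
    recon1: SubclonalReconstruction, recon2: SubclonalReconstruction
) -> float:
    """Wasserstein distance between the two weighted CCF distributions.

    Each clone is a point mass at its CCF with weight proportional to its
    number of mutations. Symmetric; 0 iff the distributions coincide.
    Reconstructions without CCFs (consensus-style) are rejected.
    """
    for recon in (recon1, recon2):
        if not recon.has_ccfs:
            raise ValueError("score1C needs cellular prevalences on every clone")
        if recon.n_mutations == 0:
            raise ValueError("score1C needs clones with mutations")
    u = np.array([c.ccf for c in recon1.clones])
    v = np.array([c.ccf for c in recon2.clones])
    uw = np.array([c.n_mutations for c in recon1.clones], dtype=float)
    vw = np.array([c.n_mutations for c in recon2.clones], dtype=float)
    return float(stats.wasserstein_distance(u, v, u_weights=uw, v_weights=vw))


def cocluster_matrix(
    recon: SubclonalReconstruction, mutation_order: Sequence[str]
) -> CoClusteringMatrix:
    """Binary co-assignment matrix restricted to ``mutation_order``."""
    clone_of = recon.clone_of()
    missing = [m for m in mutation_order if m not in clone_of]
    if missing:
        raise ValueError(f"mutations absent from reconstruction: {missing[:3]}")
    labels = np.array([clone_of[m] for m in mutation_order])
    matrix = (labels[:, None] == labels[None, :]).astype(np.int8)
    return CoClusteringMatrix(mutation_order=tuple(mutation_order), matrix=matrix)


def agreement_counts(m1: CoClusteringMatrix, m2: CoClusteringMatrix) -> AgreementCounts:
    """TP/TN/FP/FN entry counts with ``m1`` as reference (diagonal included)."""
    a = m1.matrix.ravel().astype(bool)
    b = m2.matrix.ravel().astype(bool)
    return AgreementCounts(
        tp=int(np.sum(a & b)),
        tn=int(np.sum(~a & ~b)),
        fp=int(np.sum(~a & b)),
        fn=int(np.sum(a & ~b)),
    )


def raw_coclustering_agreement(
    m1: CoClusteringMatrix, m2: CoClusteringMatrix
) -> RawAgreementScores:
    """Pearson, Matthews and V-measure agreement of two co-clustering matrices.

    Pearson and Matthews are computed over all N^2 vectorized entries,
    diagonal included. Degenerate cases: exact entrywise agreement scores
    1 even when the statistic is formally undefined (identical constant
    matrices), while any other zero-variance or zero-denominator case
    returns 0 — a degenerate prediction that differs from the reference
    carries no agreement information. The
    V-measure scores ``m2``'s partition against ``m1``'s as the reference
    classes (natural-log entropies; a component whose reference entropy is
    0 counts as 1).
    """
    if m1.mutation_order != m2.mutation_order:
        raise ValueError("matrices are over different mutation orders")
    if m1.n < 2:
        raise ValueError("need at least 2 mutations")

    a = m1.matrix.ravel().astype(float)
    b = m2.matrix.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        pcc = 1.0 if np.array_equal(a, b) else 0.0
    else:
        pcc = float(np.corrcoef(a, b)[0, 1])

    c = agreement_counts(m1, m2)
    if c.fp == 0 and c.fn == 0:
        mcc = 1.0  # exact agreement, even when a denominator factor is 0
    else:
        denom = (
            float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
        )
        mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)

    v = float(v_measure_score(m1.labels(), m2.labels()))
    return RawAgreementScores(pcc=pcc, mcc=float(mcc), v_measure=v)


def rescale_against_bad(raw: float, raw_allones: float, raw_identity: float) -> float:
    """Rescale a raw agreement score against the better bad scenario.

    ``worst`` is the smaller of the scores the two degenerate predictions
    achieve; the raw score is mapped through ``(raw - worst)/(1 - worst)``
    and clipped to [0, 1]. When the worst scenario already scores ~1 the
    rescaling is degenerate and the result is 1 if the raw score reaches
    it, else 0.
    """
    worst = min(raw_allones, raw_identity)
    if 1.0 - worst < _DEGENERATE_EPS:
        return 1.0 if raw >= worst else 0.0
    return float(np.clip((raw - worst) / (1.0 - worst), 0.0, 1.0))


def score2A(
    recon1: SubclonalReconstruction, recon2: SubclonalReconstruction
) -> float:
    """Co-clustering agreement of ``recon2`` against reference ``recon1``.

    Restricted to the mutations present in both reconstructions; the mean
    of the three rescaled agreement components. Asymmetric in its
    arguments through the V-measure reference role and the bad-scenario
    rescaling.
    """
    common = sorted(recon1.mutation_ids & recon2.mutation_ids)
    if len(common) < 2:
        raise NonComparableError(
            f"only {len(common)} mutation(s) shared between reconstructions"
        )
    m1 = cocluster_matrix(recon1, common)
    m2 = cocluster_matrix(recon2, common)
    n = len(common)
    allones = CoClusteringMatrix(tuple(common), np.ones((n, n), dtype=np.int8))
    identity = CoClusteringMatrix(tuple(common), np.eye(n, dtype=np.int8))

    raw = raw_coclustering_agreement(m1, m2).as_tuple()
    raw_ones = raw_coclustering_agreement(m1, allones).as_tuple()
    raw_id = raw_coclustering_agreement(m1, identity).as_tuple()
    rescaled = [
        rescale_against_bad(r, r1, ri) for r, r1, ri in zip(raw, raw_ones, raw_id)
    ]
    return float(np.mean(rescaled))


# ---------------------------------------------------------------------------
# Tabulation across samples and methods
# ---------------------------------------------------------------------------

def _metric_value(
    metric: str, ref: SubclonalReconstruction, pred: SubclonalReconstruction
) -> float:
    if metric == "1B":
        return score1B(ref.n_clones, pred.n_clones)
    if metric == "1C":
        return score1C(ref, pred)
    if metric == "2A":
        return score2A(ref, pred)
    raise ValueError(f"unknown metric {metric!r}; expected '1B', '1C' or '2A'")


def pairwise_comparison_table(
    recons: Mapping[str, Mapping[str, SubclonalReconstruction]],
    metric: str,
    methods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median per-pair agreement across samples, both orientations.

    ``recons`` maps sample -> method -> reconstruction. Every ordered
    method pair (reference, prediction) gets the median of the metric
    over samples where both methods produced an output; failing samples
    are logged and excluded from the median. Returns a methods x methods
    DataFrame (rows = reference).
    """
    if methods is None:
        methods = sorted({m for per_sample in recons.values() for m in per_sample})
    table = pd.DataFrame(index=list(methods), columns=list(methods), dtype=float)
    for ref_m, pred_m in itertools.product(methods, repeat=2):
        values = []
        for sample, per_method in recons.items():
            if ref_m not in per_method or pred_m not in per_method:
                continue
            try:
                values.append(
                    _metric_value(metric, per_method[ref_m], per_method[pred_m])
                )
            except (ValueError, NonComparableError) as exc:
                logger.warning(
                    "metric %s failed for sample %s (%s vs %s): %s",
                    metric, sample, ref_m, pred_m, exc,
                )
        table.loc[ref_m, pred_m] = np.median(values) if values else np.nan
    return table


def correlation_analysis(
    measures: pd.DataFrame, fdr: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with BH-corrected significance.

    Each column is one per-sample measure (an ITH summary or a potential
    confounder such as purity or mutation load). Correlations use
    pairwise-complete observations; pairs with fewer than 3 complete
    observations or a constant column are excluded (NaN in both outputs).
    The significance mask applies Benjamini-Hochberg at ``fdr`` across the
    off-diagonal pairs jointly; the diagonal is significant by convention.
    """
    from statsmodels.stats.multitest import multipletests

    cols = list(measures.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    pvals = pd.DataFrame(np.nan, index=cols, columns=cols)
    np.fill_diagonal(r.values, 1.0)

    tested: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(cols, 2):
        pair = measures[[a, b]].dropna()
        if len(pair) < 3:
            warnings.warn(f"correlation {a} vs {b}: <3 complete observations")
            continue
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue  # r undefined for a constant column
        res = stats.pearsonr(x, y)
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        tested.append((a, b, float(res.pvalue)))

    significant = pd.DataFrame(False, index=cols, columns=cols)
    np.fill_diagonal(significant.values, True)
    if tested:
        reject, _, _, _ = multipletests(
            [p for _, _, p in tested], alpha=fdr, method="fdr_bh"
        )
        for (a, b, p), rej in zip(tested, reject):
            pvals.loc[a, b] = pvals.loc[b, a] = p
            significant.loc[a, b] = significant.loc[b, a] = bool(rej)
    # constant or under-observed pairs stay excluded from the mask
    significant = significant & ~r.isna()
    return r, significant
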