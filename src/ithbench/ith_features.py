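"""Per-sample summaries of intra-tumor heterogeneity.

Five features summarize a subclonal reconstruction: the number of clones,
the proportion of SNVs in the major clone (the clone with the most SNVs),
the minimal cellular prevalence over clones, the Shannon index of the
clonal distribution (natural log), and the cellular prevalence of the
major clone. The MATH score — 100 x scaled median absolute deviation over
median of the VAF distribution — summarizes heterogeneity without any
reconstruction. Squared-feature augmentation and the inverted immune
signature transform used alongside these features live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reconstruction_core import SubclonalReconstruction

#: consistency constant making the MAD estimate the normal sigma
MAD_SCALE = 1.4826

FEATURE_NAMES = [
    "n_clones",
    "major_clone_snv_fraction",
    "min_clone_prevalence",
    "shannon_index",
    "largest_clone_prevalence",
]


@dataclass(frozen=True)
class ITHFeatures:
    n_clones: int
    major_clone_snv_fraction: float
    min_clone_prevalence: float
    shannon_index: float
    largest_clone_prevalence: float
    math_score: float | None = None

    def as_vector(self) -> np.ndarray:
        """The 5 reconstruction-derived features, in canonical order."""
        return np.array(
            [
                float(self.n_clones),
                self.major_clone_snv_fraction,
                self.min_clone_prevalence,
                self.shannon_index,
                self.largest_clone_prevalence,
            ]
        )


def shannon_index(clone_sizes: Sequence[float]) -> float:
    """Shannon entropy (nats) of the clone-size distribution.

    Zero for a single clone; maximal ``ln K`` when the K clones carry
    equally many mutations.
    """
    sizes = np.asarray(clone_sizes, dtype=float)
    if sizes.size == 0 or np.any(sizes < 0):
        raise ValueError("clone sizes must be nonnegative and non-empty")
    total = sizes.sum()
    if total == 0:
        raise ValueError("all clone sizes are zero")
    p = sizes[sizes > 0] / total
    return float(-(p * np.log(p)).sum())


def extract_ith_features(
    recon: SubclonalReconstruction, exclude_truncal_from_min: bool = False
) -> ITHFeatures:
    """The 5 reconstruction-derived ITH features (MATH not included).

    The major clone is the clone with the most SNVs; ties are broken by
    higher prevalence, then lexicographic clone id. ``min_clone_prevalence``
    spans all clones by default; ``exclude_truncal_from_min`` drops the
    highest-prevalence clone from the minimum (falling back to it when the
    reconstruction is monoclonal).
    """
    if not recon.clones:
        raise ValueError("empty reconstruction")
    if not recon.has_ccfs:
        raise ValueError("reconstruction lacks cellular prevalences")
    sizes = np.array([c.n_mutations for c in recon.clones], dtype=float)
    if sizes.sum() == 0:
        raise ValueError("reconstruction has no mutations")

    major = min(
        recon.clones, key=lambda c: (-c.n_mutations, -c.ccf, c.clone_id)
    )
    ccfs = np.array([c.ccf for c in recon.clones])
    if exclude_truncal_from_min and len(recon.clones) > 1:
        min_prev = float(np.min(np.delete(ccfs, int(np.argmax(ccfs)))))
    else:
        min_prev = float(ccfs.min())
    return ITHFeatures(
        n_clones=recon.n_clones,
        major_clone_snv_fraction=float(major.n_mutations / sizes.sum()),
        min_clone_prevalence=min_prev,
        shannon_index=shannon_index(sizes),
        largest_clone_prevalence=float(major.ccf),
    )


def math_score(vafs: Sequence[float]) -> float:
    """Mutant-allele tumor heterogeneity score of a VAF distribution.

    ``100 * 1.4826 * median(|v - median(v)|) / median(v)``: the width of
    the VAF distribution relative to its center. Invariant under scaling
    all VAFs by a positive constant.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size == 0:
        raise ValueError("math_score needs at least one VAF")
    med = float(np.median(v))
    if med == 0:
        raise ValueError("median VAF is zero; MATH undefined")
    mad = MAD_SCALE * float(np.median(np.abs(v - med)))
    return 100.0 * mad / med


@dataclass(frozen=True)
class SignatureScores:
    """Raw and cohort-inverted per-sample signature values."""

    raw: np.ndarray
    inverted: np.ndarray


def signature_inverse(raw_scores: Sequence[float]) -> SignatureScores:
    """Invert a signature against its cohort maximum.

    ``inverted_i = max_j raw_j - raw_i``, so the transformed value grows
    in the same direction as tumor purity and stays nonnegative; the
    cohort maximum maps to 0.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("empty cohort")
    return SignatureScores(raw=raw, inverted=raw.max() - raw)


def augment_squared(features: np.ndarray) -> np.ndarray:
    """Concatenate features with their elementwise squares.

    Accepts a vector (length p -> 2p) or a matrix (n x p -> n x 2p);
    enables quadratic survival models on top of a linear fit.
    """
    features = np.asarray(features, dtype=float)
    return np.concatenate([features, features**2], axis=-1)
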