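"""Synthetic tumor cohorts with known clone structure and survival.

Each simulated sample carries a ground-truth clone structure: a truncal
clone at cancer cell fraction (CCF) 1 plus subclones at lower CCFs with a
minimum pairwise separation. Read counts follow the standard allele
fraction model: a mutation present in a fraction ``ccf`` of tumor cells,
at multiplicity ``m`` on ``CN_t`` total tumor copies, in a sample of
purity ``rho`` with diploid normal contamination, has expected VAF

    rho * m * ccf / (rho * CN_t + (1 - rho) * 2)

Tumor and normal depths are Poisson (truncated at 1 read), alt counts
binomial. Two nested mutation views emulate the protected/public release
levels of consortium data, and censored survival times can be linked to
the latent ITH features through a log-linear (exponential proportional
hazards) model with uniform censoring. Confounders — purity, mutation
load, and the fraction of copy-number-altered mutations — vary across
samples by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ith_features import extract_ith_features
from .reconstruction_core import Clone, SubclonalReconstruction, write_reconstruction
from .survival_eval import SurvivalDataset
from .variant_filter import VariantRecord, write_records_tsv, write_vcf

NORMAL_ERROR_RATE = 0.001  # per-read alt probability in the matched normal
_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a moderate-coverage WES cohort: ~100x coverage,
    purities 0.3-0.95, up to 5 clones per tumor separated by at least 0.1
    in CCF, and exponential survival on a ~months time scale.
    """

    n_samples: int = 100
    clone_count_range: tuple[int, int] = (1, 5)
    mutations_per_sample_range: tuple[int, int] = (50, 300)
    mean_coverage: float = 100.0
    purity_range: tuple[float, float] = (0.3, 0.95)
    cna_fraction_range: tuple[float, float] = (0.0, 0.5)
    min_ccf_separation: float = 0.1
    survival_coeffs: np.ndarray | None = None  # per latent ITH feature
    baseline_hazard: float = 0.02
    censoring_horizon: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.clone_count_range
        if not (1 <= lo <= hi):
            raise ValueError("clone_count_range must be a non-empty range >= 1")
        lo, hi = self.mutations_per_sample_range
        if not (1 <= lo <= hi):
            raise ValueError("mutations_per_sample_range must be non-empty")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")
        lo, hi = self.cna_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("cna_fraction_range must lie within [0, 1]")
        if not (0 < self.min_ccf_separation <= 0.5):
            raise ValueError("min_ccf_separation must lie in (0, 0.5]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be positive")
        if self.survival_coeffs is not None:
            self.survival_coeffs = np.asarray(self.survival_coeffs, dtype=float)

    def config_hash(self) -> str:
        payload = asdict(self)
        if isinstance(payload.get("survival_coeffs"), np.ndarray):
            payload["survival_coeffs"] = payload["survival_coeffs"].tolist()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class CloneStructure:
    """Ground-truth partition of mutations into clones with CCFs."""

    clone_ids: list[str]
    ccfs: np.ndarray  # aligned with clone_ids, strictly decreasing
    assignment: dict[str, str]  # mutation_id -> clone_id

    def __post_init__(self) -> None:
        self.ccfs = np.asarray(self.ccfs, dtype=float)
        if len(self.clone_ids) != self.ccfs.size:
            raise ValueError("clone_ids and ccfs lengths differ")
        if not np.isclose(self.ccfs.max(), 1.0):
            raise ValueError("no truncal clone at CCF 1.0")
        if np.any(np.diff(self.ccfs) >= 0):
            raise ValueError("ccfs must be strictly decreasing")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def clone_sizes(self) -> dict[str, int]:
        sizes = {cid: 0 for cid in self.clone_ids}
        for cid in self.assignment.values():
            sizes[cid] += 1
        return sizes

    def ccf_of(self) -> dict[str, float]:
        return dict(zip(self.clone_ids, self.ccfs))

    def to_reconstruction(self, purity: float | None = None) -> SubclonalReconstruction:
        """The ground truth viewed as a subclonal reconstruction."""
        members: dict[str, set[str]] = {cid: set() for cid in self.clone_ids}
        for mut, cid in self.assignment.items():
            members[cid].add(mut)
        clones = [
            Clone(clone_id=cid, ccf=float(ccf), mutation_ids=frozenset(members[cid]))
            for cid, ccf in zip(self.clone_ids, self.ccfs)
        ]
        return SubclonalReconstruction(clones=clones, purity=purity)


@dataclass
class SimulatedSample:
    sample_id: str
    variants: list[VariantRecord]
    purity: float
    cn_total: np.ndarray  # per-mutation total tumor copy number
    multiplicity: np.ndarray  # per-mutation mutated copies
    truth: CloneStructure
    features_latent: np.ndarray  # 5 ITH features of the ground truth


def simulate_clone_structure(
    config: SimulationConfig, rng: np.random.Generator
) -> CloneStructure:
    """Draw a clone structure: truncal clone at CCF 1, separated subclones.

    Subclonal CCFs are drawn uniformly on (0, 1 - separation) and
    rejection-sampled until all pairwise gaps of the sorted CCF vector
    reach ``min_ccf_separation``. Mutation counts per clone follow a
    symmetric Dirichlet-multinomial with every clone receiving at least
    one mutation.
    """
    k = int(rng.integers(config.clone_count_range[0], config.clone_count_range[1] + 1))
    n_mut = int(
        rng.integers(
            config.mutations_per_sample_range[0],
            config.mutations_per_sample_range[1] + 1,
        )
    )
    sep = config.min_ccf_separation
    if n_mut < k:
        raise ValueError(f"cannot place {k} clones with only {n_mut} mutations")
    if (k - 1) * sep > 1.0 - sep:
        raise ValueError(
            f"cannot separate {k} clone CCFs in (0, 1] with gaps >= {sep}"
        )

    if k == 1:
        ccfs = np.array([1.0])
    else:
        for _ in range(10_000):
            sub = rng.uniform(sep / 2, 1.0 - sep, size=k - 1)
            ccfs = np.sort(np.concatenate([[1.0], sub]))[::-1]
            if np.all(-np.diff(ccfs) >= sep):
                break
        else:  # pragma: no cover - guarded by the feasibility check above
            raise ValueError(
                f"failed to draw {k} separated CCFs with gaps >= {sep}"
            )

    clone_ids = [f"clone_{i + 1}" for i in range(k)]
    weights = rng.dirichlet(np.full(k, 5.0))
    counts = rng.multinomial(n_mut - k, weights) + 1

    mutation_ids = _draw_mutation_ids(n_mut, rng)
    assignment: dict[str, str] = {}
    start = 0
    for cid, count in zip(clone_ids, counts):
        for mut in mutation_ids[start : start + count]:
            assignment[mut] = cid
        start += count
    return CloneStructure(clone_ids=clone_ids, ccfs=ccfs, assignment=assignment)


def _draw_mutation_ids(n: int, rng: np.random.Generator) -> list[str]:
    """Unique chrom:pos:ref:alt identifiers (1-based positions)."""
    ids: list[str] = []
    seen: set[tuple[int, int]] = set()
    while len(ids) < n:
        chrom = int(rng.integers(1, 23))
        pos = int(rng.integers(1, 50_000_000))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref, alt = rng.choice(4, size=2, replace=False)
        ids.append(f"{chrom}:{pos}:{_BASES[ref]}:{_BASES[alt]}")
    return ids


def expected_vaf(
    ccf: float,
    purity: float,
    cn_total: int,
    multiplicity: int,
    cn_normal: int = 2,
) -> float:
    """Expected variant allele fraction under the allele-counting model.

    ``rho * m * ccf / (rho * CN_t + (1 - rho) * cn_normal)`` — mutated
    copies over all copies at the locus, averaged over tumor and normal
    cells.
    """
    if not (0 < ccf <= 1):
        raise ValueError("ccf must lie in (0, 1]")
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    if cn_total < 1 or cn_normal < 0:
        raise ValueError("copy numbers must be positive")
    if not (1 <= multiplicity <= cn_total):
        raise ValueError("multiplicity must lie in [1, cn_total]")
    vaf = purity * multiplicity * ccf / (purity * cn_total + (1 - purity) * cn_normal)
    return float(min(vaf, 1.0))


def _truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson draws re-sampled to be >= 1 (keeps VAF defined everywhere)."""
    depths = rng.poisson(mean, size=size)
    zero = depths == 0
    while np.any(zero):
        depths[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = depths == 0
    return depths


def simulate_read_counts(
    structure: CloneStructure,
    purity: float,
    cn_total: np.ndarray,
    multiplicity: np.ndarray,
    mean_coverage: float,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Binomial read sampling at every mutation of a clone structure.

    Per mutation: tumor depth ~ Poisson(mean_coverage) truncated at 1,
    tumor alt ~ Binomial(depth, expected VAF); normal depth likewise with
    alt ~ Binomial(depth, 0.001).
    """
    mutation_ids = list(structure.assignment)
    ccf_of = structure.ccf_of()
    n = len(mutation_ids)
    vafs = np.array(
        [
            expected_vaf(
                ccf_of[structure.assignment[mut]],
                purity,
                int(cn_total[i]),
                int(multiplicity[i]),
            )
            for i, mut in enumerate(mutation_ids)
        ]
    )
    tumor_depth = _truncated_poisson(mean_coverage, n, rng)
    tumor_alt = rng.binomial(tumor_depth, vafs)
    normal_depth = _truncated_poisson(mean_coverage, n, rng)
    normal_alt = rng.binomial(normal_depth, NORMAL_ERROR_RATE)
    return [
        VariantRecord(
            mutation_id=mut,
            is_indel=False,
            caller="Mutect2",
            filter_status="PASS",
            normal_depth=int(normal_depth[i]),
            normal_alt=int(normal_alt[i]),
            tumor_depth=int(tumor_depth[i]),
            tumor_alt=int(tumor_alt[i]),
        )
        for i, mut in enumerate(mutation_ids)
    ]


def derive_views(
    variants: Sequence[VariantRecord],
    rng: np.random.Generator,
    public_min_alt: int = 8,
    public_min_vaf: float = 0.1,
    retention_prob: float = 0.9,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split a sample's variants into nested protected/public views.

    The protected view is everything; the public view keeps variants with
    strong evidence (alt reads >= ``public_min_alt`` or VAF >=
    ``public_min_vaf``) and then retains each independently with
    probability ``retention_prob``, emulating the stricter filtering of
    openly released calls. Always ``public subseteq protected``.
    """
    protected = list(variants)
    public = []
    for record in protected:
        if record.tumor_alt >= public_min_alt or record.tumor_vaf >= public_min_vaf:
            if retention_prob >= 1.0 or rng.random() < retention_prob:
                public.append(record)
    return protected, public


def simulate_survival_labels(
    features: np.ndarray,
    coeffs: np.ndarray,
    baseline_hazard: float,
    censoring_horizon: float,
    rng: np.random.Generator,
) -> SurvivalDataset:
    """Exponential proportional-hazards survival with uniform censoring.

    ``T_i ~ Exp(rate = h0 * exp(beta' x_i))``, ``C_i ~ U(0, horizon)``,
    observed time ``min(T_i, C_i)`` with event indicator ``T_i <= C_i``.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (features.shape[1],):
        raise ValueError(
            f"coefficient length {coeffs.shape} does not match "
            f"{features.shape[1]} features"
        )
    rate = baseline_hazard * np.exp(features @ coeffs)
    t = rng.exponential(1.0 / rate)
    c = rng.uniform(0.0, censoring_horizon, size=t.shape)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return SurvivalDataset(features=features, time=time, event=event)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SimulatedSample], SurvivalDataset]:
    """Simulate a full cohort; deterministic given ``config.seed``.

    Per sample: clone structure, purity, copy-number assignment (a random
    fraction of mutations altered, multiplicity uniform over the major
    allele copies), read counts, and the 5 latent ITH features of the
    ground truth. Survival links to the z-scored latent features through
    ``config.survival_coeffs`` (zeros — no link — when unset).
    """
    rng = np.random.default_rng(config.seed)
    samples: list[SimulatedSample] = []
    for s in range(config.n_samples):
        structure = simulate_clone_structure(config, rng)
        purity = float(rng.uniform(*config.purity_range))
        n_mut = len(structure.assignment)

        cna_fraction = float(rng.uniform(*config.cna_fraction_range))
        cn_total = np.full(n_mut, 2, dtype=int)
        altered = rng.random(n_mut) < cna_fraction
        cn_total[altered] = rng.choice([1, 3, 4], size=int(altered.sum()))
        major_copies = np.maximum(1, np.ceil(cn_total / 2).astype(int))
        multiplicity = 1 + (rng.random(n_mut) * major_copies).astype(int)
        multiplicity = np.minimum(multiplicity, major_copies)

        variants = simulate_read_counts(
            structure, purity, cn_total, multiplicity, config.mean_coverage, rng
        )
        latent = extract_ith_features(structure.to_reconstruction(purity)).as_vector()
        samples.append(
            SimulatedSample(
                sample_id=f"S{s:04d}",
                variants=variants,
                purity=purity,
                cn_total=cn_total,
                multiplicity=multiplicity,
                truth=structure,
                features_latent=latent,
            )
        )

    latent = np.vstack([s.features_latent for s in samples])
    coeffs = config.survival_coeffs
    if coeffs is None:
        coeffs = np.zeros(latent.shape[1])
    # z-score the latent features so coefficients are per-sd log hazards
    scale = latent.std(axis=0)
    scale[scale == 0] = 1.0
    z = (latent - latent.mean(axis=0)) / scale
    survival = simulate_survival_labels(
        z, coeffs, config.baseline_hazard, config.censoring_horizon, rng
    )
    return samples, survival


def write_cohort(
    samples: Sequence[SimulatedSample],
    survival: SurvivalDataset,
    out_dir: str | Path,
) -> None:
    """Serialize a cohort: per-sample VCF/TSV observables + truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        sample_dir = out_dir / sample.sample_id
        sample_dir.mkdir(exist_ok=True)
        write_vcf(sample.variants, sample_dir / "variants.vcf")
        write_records_tsv(sample.variants, sample_dir / "variants.tsv")
        write_reconstruction(
            sample.truth.to_reconstruction(sample.purity), sample_dir / "truth"
        )
        meta = {
            "sample_id": sample.sample_id,
            "purity": sample.purity,
            "n_mutations": len(sample.variants),
            "n_clones": sample.truth.n_clones,
        }
        (sample_dir / "sample.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "time": survival.time,
            "event": survival.event,
        }
    ).to_csv(out_dir / "survival.tsv", sep="\t", index=False)
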