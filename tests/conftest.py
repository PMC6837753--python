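"""Shared fixtures: record builders and the hand-crafted filter fixture."""

from __future__ import annotations

import numpy as np
import pytest

from ithbench.reconstruction_core import Clone, SubclonalReconstruction
from ithbench.variant_filter import VariantRecord


def make_record(
    mutation_id: str = "1:100:A:T",
    caller: str = "Mutect2",
    filter_status: str = "PASS",
    normal_depth: int = 50,
    normal_alt: int = 0,
    tumor_depth: int = 60,
    tumor_alt: int = 20,
    **kwargs,
) -> VariantRecord:
    return VariantRecord(
        mutation_id=mutation_id,
        is_indel=kwargs.pop("is_indel", False),
        caller=caller,
        filter_status=filter_status,
        normal_depth=normal_depth,
        normal_alt=normal_alt,
        tumor_depth=tumor_depth,
        tumor_alt=tumor_alt,
        **kwargs,
    )


def make_reconstruction(
    clone_specs: list[tuple[float | None, int]], prefix: str = "c"
) -> SubclonalReconstruction:
    """Build a reconstruction from (ccf, n_mutations) clone specs."""
    clones = []
    counter = 0
    for i, (ccf, n) in enumerate(clone_specs):
        muts = frozenset(f"{prefix}_m{counter + j}" for j in range(n))
        counter += n
        clones.append(Clone(clone_id=f"{prefix}{i + 1}", ccf=ccf, mutation_ids=muts))
    return SubclonalReconstruction(clones=clones)


def reconstruction_from_labels(
    labels: list[int], mutation_ids: list[str] | None = None, ccfs: dict | None = None
) -> SubclonalReconstruction:
    """Reconstruction whose partition is given by per-mutation labels."""
    if mutation_ids is None:
        mutation_ids = [f"m{i}" for i in range(len(labels))]
    groups: dict[int, set[str]] = {}
    for mut, lab in zip(mutation_ids, labels):
        groups.setdefault(lab, set()).add(mut)
    clones = []
    for lab in sorted(groups):
        ccf = (ccfs or {}).get(lab, 1.0 / (1 + sorted(groups).index(lab)))
        clones.append(
            Clone(clone_id=f"k{lab}", ccf=ccf, mutation_ids=frozenset(groups[lab]))
        )
    return SubclonalReconstruction(clones=clones)


# ---------------------------------------------------------------------------
# Hand-crafted 20-record filter fixture: per-rule expected pass/fail pattern.
# Tuples: (record, passes_caller, passes_population, passes_coverage)
# ---------------------------------------------------------------------------

def _fixture_rows() -> list[tuple[VariantRecord, bool, bool, bool]]:
    r = make_record
    return [
        # caller FILTER rule coverage across the four callers
        (r("1:101:A:T", "Mutect2", "PASS"), True, True, True),
        (r("1:102:C:G", "Mutect2", "panel_of_normals"), True, True, True),
        (r("1:103:G:A", "Mutect2", "germline_risk"), False, True, True),
        (r("1:104:T:C", "VarScan2", "PASS"), True, True, True),
        (r("1:105:A:G", "VarScan2", "germline"), False, True, True),
        (r("1:106:C:T", "SomaticSniper", "PASS"), True, True, True),
        (r("1:107:G:C", "SomaticSniper", "LowQual"), False, True, True),
        (r("1:108:T:A", "MuSe", "Tier1"), True, True, True),
        (r("1:109:A:C", "MuSe", "Tier3"), True, True, True),
        (r("1:110:C:A", "MuSe", "Tier5"), True, True, True),
        (r("2:201:G:T", "MuSe", "."), False, True, True),
        # population-frequency rule with COSMIC rescue
        (r("2:202:T:G", af_1000g=0.02), True, False, True),
        (r("2:203:A:T", af_1000g=0.02, in_cosmic=True), True, True, True),
        (r("2:204:C:G", af_exac=0.05), True, False, True),
        (r("2:205:G:A", af_1000g=0.005, af_exac=0.009), True, True, True),
        # coverage rule boundaries
        (r("3:301:T:C", normal_depth=10, normal_alt=0, tumor_depth=8, tumor_alt=3),
         True, True, True),
        (r("3:302:A:G", normal_depth=5, normal_alt=0, tumor_depth=100, tumor_alt=50),
         True, True, False),
        (r("3:303:C:T", normal_depth=200, normal_alt=2, tumor_depth=20, tumor_alt=10),
         True, True, False),
        (r("3:304:G:C", normal_depth=300, normal_alt=2, tumor_depth=30, tumor_alt=10),
         True, True, True),
        (r("3:305:T:A", normal_depth=50, normal_alt=0, tumor_depth=10, tumor_alt=2),
         True, True, False),
    ]


@pytest.fixture(scope="session")
def filter_fixture() -> list[tuple[VariantRecord, bool, bool, bool]]:
    rows = _fixture_rows()
    assert len(rows) == 20
    return rows


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
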