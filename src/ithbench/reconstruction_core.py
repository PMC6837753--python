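"""Common representation of subclonal reconstructions.

A subclonal reconstruction partitions a sample's somatic mutations into
clones, each with a cellular prevalence (CCF, the fraction of tumor cells
carrying the clone's mutations). External tools' outputs reduce to the
same two tables this module reads and writes:

* ``assignment.tsv`` — mutation_id, clone_id
* ``clones.tsv`` — clone_id, ccf, n_mut

The module also provides the standard post-filter (drop clones with fewer
than 5 SNVs, unless no clone reaches 5) and a simple grid-binning baseline
reconstructor used as a reference method in benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_SNVS = 5


@dataclass(frozen=True)
class Clone:
    clone_id: str
    ccf: float | None  # None for consensus-style outputs without prevalences
    mutation_ids: frozenset[str]

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)


@dataclass
class SubclonalReconstruction:
    """A partition of mutations into clones with cellular prevalences."""

    clones: list[Clone]
    purity: float | None = None

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("a reconstruction needs at least one clone")
        seen: set[str] = set()
        ids: set[str] = set()
        for clone in self.clones:
            if clone.clone_id in ids:
                raise ValueError(f"duplicate clone id {clone.clone_id!r}")
            ids.add(clone.clone_id)
            if clone.ccf is not None and not (0 < clone.ccf <= 1):
                raise ValueError(
                    f"clone {clone.clone_id!r}: prevalence {clone.ccf} outside (0, 1]"
                )
            overlap = seen & clone.mutation_ids
            if overlap:
                raise ValueError(
                    f"mutations assigned to multiple clones: {sorted(overlap)[:3]}"
                )
            seen |= clone.mutation_ids

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def mutation_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for clone in self.clones:
            out |= clone.mutation_ids
        return frozenset(out)

    @property
    def n_mutations(self) -> int:
        return sum(c.n_mutations for c in self.clones)

    @property
    def has_ccfs(self) -> bool:
        return all(c.ccf is not None for c in self.clones)

    def clone_of(self) -> dict[str, str]:
        """mutation_id -> clone_id mapping."""
        return {
            mut: clone.clone_id for clone in self.clones for mut in clone.mutation_ids
        }


def postfilter_clones(
    recon: SubclonalReconstruction, min_snvs: int = DEFAULT_MIN_SNVS
) -> SubclonalReconstruction:
    """Drop clones with fewer than ``min_snvs`` mutations.

    If no clone reaches ``min_snvs``, all clones are retained unchanged.
    Mutations of dropped clones are removed from the reconstruction.
    """
    if not recon.clones:
        raise ValueError("empty reconstruction")
    kept = [c for c in recon.clones if c.n_mutations >= min_snvs]
    if not kept:
        kept = list(recon.clones)
    return SubclonalReconstruction(clones=kept, purity=recon.purity)


def baseline_reconstruct(
    values: Sequence[float],
    mutation_ids: Sequence[str] | None = None,
    grid_width: float = 0.1,
    min_snvs: int = DEFAULT_MIN_SNVS,
) -> SubclonalReconstruction:
    """Grid-binning reconstruction from per-mutation VAFs or CCF estimates.

    Values are assigned to the nearest center on a fixed grid of width
    ``grid_width``; occupied bins with fewer than ``min_snvs`` members are merged into the
    nearest heavier occupied bin (nearest by bin center; ties towards the
    heavier bin). Each surviving bin becomes one clone whose prevalence is
    the mean of its member values. This is a deliberately simple reference
    method, not a reimplementation of any published reconstruction tool.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("baseline_reconstruct needs at least one value")
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError("values must be finite and nonnegative")
    if mutation_ids is None:
        mutation_ids = [f"m{i}" for i in range(values.size)]
    if len(mutation_ids) != values.size:
        raise ValueError("mutation_ids length mismatch")

    # nearest grid center, so a mode straddling a bin edge stays together
    idx = np.round(values / grid_width).astype(int)

    members: dict[int, list[int]] = {}
    for pos, b in enumerate(idx):
        members.setdefault(int(b), []).append(pos)

    # iteratively merge undersized bins into their nearest heavier neighbor
    while len(members) > 1:
        sizes = {b: len(m) for b, m in members.items()}
        small = [b for b, s in sizes.items() if s < min_snvs]
        if not small:
            break
        b = min(small, key=lambda b: (sizes[b], b))
        others = [o for o in members if o != b]
        target = min(others, key=lambda o: (abs(o - b), -sizes[o], o))
        members[target].extend(members.pop(b))

    clones = []
    order = sorted(members, key=lambda b: -float(np.mean(values[members[b]])))
    for rank, b in enumerate(order, start=1):
        vals = values[members[b]]
        ccf = float(np.clip(np.mean(vals), 1e-9, 1.0))
        clones.append(
            Clone(
                clone_id=f"clone_{rank}",
                ccf=ccf,
                mutation_ids=frozenset(mutation_ids[i] for i in members[b]),
            )
        )
    return SubclonalReconstruction(clones=clones)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def load_reconstruction(
    assignment: pd.DataFrame, clone_table: pd.DataFrame, purity: float | None = None
) -> SubclonalReconstruction:
    """Build a reconstruction from assignment and clone tables.

    ``assignment`` needs columns mutation_id, clone_id; ``clone_table``
    needs clone_id and ccf (NaN allowed for consensus outputs). Unknown
    clone ids or doubly-assigned mutations raise ``ValueError``.
    """
    if assignment["mutation_id"].duplicated().any():
        dupes = assignment.loc[
            assignment["mutation_id"].duplicated(), "mutation_id"
        ].tolist()
        raise ValueError(f"mutations assigned more than once: {dupes[:3]}")
    known = set(clone_table["clone_id"].astype(str))
    referenced = set(assignment["clone_id"].astype(str))
    missing = referenced - known
    if missing:
        raise ValueError(f"assignment references unknown clones: {sorted(missing)}")

    by_clone: dict[str, set[str]] = {cid: set() for cid in known}
    for row in assignment.itertuples(index=False):
        by_clone[str(row.clone_id)].add(str(row.mutation_id))

    clones = []
    for row in clone_table.itertuples(index=False):
        cid = str(row.clone_id)
        ccf = getattr(row, "ccf", None)
        ccf = None if ccf is None or pd.isna(ccf) else float(ccf)
        clones.append(Clone(clone_id=cid, ccf=ccf, mutation_ids=frozenset(by_clone[cid])))
    return SubclonalReconstruction(clones=clones, purity=purity)


def reconstruction_tables(
    recon: SubclonalReconstruction,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (assignment, clones) DataFrames for a reconstruction."""
    assignment = pd.DataFrame(
        [
            {"mutation_id": mut, "clone_id": clone.clone_id}
            for clone in recon.clones
            for mut in sorted(clone.mutation_ids)
        ],
        columns=["mutation_id", "clone_id"],
    )
    clone_table = pd.DataFrame(
        [
            {"clone_id": c.clone_id, "ccf": c.ccf, "n_mut": c.n_mutations}
            for c in recon.clones
        ],
        columns=["clone_id", "ccf", "n_mut"],
    )
    return assignment, clone_table


def write_reconstruction(recon: SubclonalReconstruction, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignment, clone_table = reconstruction_tables(recon)
    assignment.to_csv(out_dir / "assignment.tsv", sep="\t", index=False)
    clone_table.to_csv(out_dir / "clones.tsv", sep="\t", index=False)


def read_reconstruction(
    in_dir: str | Path, purity: float | None = None
) -> SubclonalReconstruction:
    in_dir = Path(in_dir)
    assignment = pd.read_csv(in_dir / "assignment.tsv", sep="\t")
    clone_table = pd.read_csv(in_dir / "clones.tsv", sep="\t")
    return load_reconstruction(assignment, clone_table, purity=purity)
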