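"""Somatic SNV filtering for protected and public mutation sets.

Tumor/normal variant calls from four callers (MuSe, Mutect2, VarScan2,
SomaticSniper) are reduced to two nested mutation sets:

* **public** — indels removed, then the union of the four callers' SNVs
  (mirroring openly released, high-confidence calls);
* **protected** — indels removed, then per-caller FILTER-status rules,
  a population-frequency rule with a COSMIC rescue, and tumor/normal
  coverage rules, then the union.

Filtering keys on ``chrom:pos:ref:alt`` (1-based positions); duplicate
calls of the same mutation across callers are collapsed to the record
with the highest tumor depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: FILTER values accepted per caller for the protected set.
CALLER_PASS_VALUES: dict[str, frozenset[str]] = {
    "VarScan2": frozenset({"PASS"}),
    "SomaticSniper": frozenset({"PASS"}),
    "Mutect2": frozenset({"PASS", "panel_of_normals"}),
    "MuSe": frozenset({f"Tier{i}" for i in range(1, 6)}),
}

KNOWN_CALLERS = tuple(sorted(CALLER_PASS_VALUES))

MAX_POPULATION_AF = 0.01
MIN_NORMAL_DEPTH = 6
MAX_NORMAL_ALT = 1
MAX_NORMAL_VAF = 0.01
MIN_TUMOR_DEPTH = 8
MIN_TUMOR_ALT = 3
MIN_TUMOR_VAF = 0.2


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel candidate with tumor/normal read evidence.

    ``mutation_id`` is ``chrom:pos:ref:alt`` with a 1-based position.
    Population allele frequencies are ``None`` when the variant is absent
    from the reference panel (treated as frequency 0 by the filters).
    """

    mutation_id: str
    is_indel: bool
    caller: str
    filter_status: str
    normal_depth: int
    normal_alt: int
    tumor_depth: int
    tumor_alt: int
    af_1000g: float | None = None
    af_exac: float | None = None
    in_cosmic: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(
                f"{self.mutation_id}: normal alt count {self.normal_alt} "
                f"outside [0, depth={self.normal_depth}]"
            )
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError(
                f"{self.mutation_id}: tumor alt count {self.tumor_alt} "
                f"outside [0, depth={self.tumor_depth}]"
            )

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0


def caller_filter_pass(record: VariantRecord) -> bool:
    """True iff the record's FILTER status is accepted for its caller.

    Accepted values: "PASS" for VarScan2 and SomaticSniper, "PASS" or
    "panel_of_normals" for Mutect2, "Tier1" through "Tier5" for MuSe.
    """
    try:
        allowed = CALLER_PASS_VALUES[record.caller]
    except KeyError:
        raise ValueError(
            f"unknown caller {record.caller!r}; expected one of {KNOWN_CALLERS}"
        ) from None
    return record.filter_status in allowed


def population_filter_pass(record: VariantRecord) -> bool:
    """Reject common population variants unless catalogued in COSMIC.

    A record fails iff its 1000 Genomes or ExAC allele frequency exceeds
    0.01 and it is not reported in COSMIC. Missing frequencies count as 0.
    """
    af_1000g = record.af_1000g or 0.0
    af_exac = record.af_exac or 0.0
    common = af_1000g > MAX_POPULATION_AF or af_exac > MAX_POPULATION_AF
    return not common or record.in_cosmic


def coverage_filter_pass(record: VariantRecord) -> bool:
    """Tumor/normal read-support rule.

    Normal sample: at least 6 reads, of which at most 1 supports the
    alternative allele (or normal VAF < 0.01). Tumor sample: at least 8
    reads, of which at least 3 support the variant (or tumor VAF > 0.2).
    Both per-sample clauses must hold; zero depth fails rather than errors.
    """
    if record.normal_depth == 0 or record.tumor_depth == 0:
        return False
    normal_ok = record.normal_depth >= MIN_NORMAL_DEPTH and (
        record.normal_alt <= MAX_NORMAL_ALT or record.normal_vaf < MAX_NORMAL_VAF
    )
    tumor_ok = record.tumor_depth >= MIN_TUMOR_DEPTH and (
        record.tumor_alt >= MIN_TUMOR_ALT or record.tumor_vaf > MIN_TUMOR_VAF
    )
    return normal_ok and tumor_ok


def protected_filter_pass(record: VariantRecord) -> bool:
    """Conjunction of the caller, population and coverage rules."""
    return (
        caller_filter_pass(record)
        and population_filter_pass(record)
        and coverage_filter_pass(record)
    )


@dataclass
class FilterReport:
    """Per-rule bookkeeping emitted next to a filtered mutation set."""

    mode: str
    n_input: int = 0
    n_indel_removed: int = 0
    n_caller_fail: int = 0
    n_population_fail: int = 0
    n_coverage_fail: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int | str]:
        return {
            "mode": self.mode,
            "n_input": self.n_input,
            "n_indel_removed": self.n_indel_removed,
            "n_caller_fail": self.n_caller_fail,
            "n_population_fail": self.n_population_fail,
            "n_coverage_fail": self.n_coverage_fail,
            "n_kept": self.n_kept,
        }


def build_mutation_sets(
    records_by_caller: Mapping[str, Sequence[VariantRecord]],
    mode: str,
    report: FilterReport | None = None,
) -> dict[str, VariantRecord]:
    """Union the per-caller calls into one deduplicated mutation set.

    Indels are removed in both modes. ``mode="public"`` applies no further
    filter; ``mode="protected"`` additionally requires the caller-FILTER,
    population-frequency and coverage rules. Duplicated mutation ids keep
    the record with the highest tumor depth.

    Returns a dict mutation_id -> representative :class:`VariantRecord`.
    """
    if mode not in ("protected", "public"):
        raise ValueError(f"mode must be 'protected' or 'public', got {mode!r}")
    if report is None:
        report = FilterReport(mode=mode)
    report.mode = mode

    kept: dict[str, VariantRecord] = {}
    total = 0
    for caller, records in records_by_caller.items():
        for record in records:
            total += 1
            if record.is_indel:
                report.n_indel_removed += 1
                continue
            if mode == "protected":
                if not caller_filter_pass(record):
                    report.n_caller_fail += 1
                    continue
                if not population_filter_pass(record):
                    report.n_population_fail += 1
                    continue
                if not coverage_filter_pass(record):
                    report.n_coverage_fail += 1
                    continue
            previous = kept.get(record.mutation_id)
            if previous is None or record.tumor_depth > previous.tumor_depth:
                kept[record.mutation_id] = record
    report.n_input = total
    report.n_kept = len(kept)
    if total == 0:
        logger.warning("build_mutation_sets(%s): empty input", mode)
    return kept


# ---------------------------------------------------------------------------
# I/O: VCF (via cyvcf2) and MAF-like TSV
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "mutation_id",
    "is_indel",
    "caller",
    "filter_status",
    "normal_depth",
    "normal_alt",
    "tumor_depth",
    "tumor_alt",
    "af_1000g",
    "af_exac",
    "in_cosmic",
]


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        {col: getattr(r, col) for col in TSV_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[VariantRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            VariantRecord(
                mutation_id=str(row.mutation_id),
                is_indel=bool(row.is_indel),
                caller=str(row.caller),
                filter_status=str(row.filter_status),
                normal_depth=int(row.normal_depth),
                normal_alt=int(row.normal_alt),
                tumor_depth=int(row.tumor_depth),
                tumor_alt=int(row.tumor_alt),
                af_1000g=None if pd.isna(row.af_1000g) else float(row.af_1000g),
                af_exac=None if pd.isna(row.af_exac) else float(row.af_exac),
                in_cosmic=bool(row.in_cosmic),
            )
        )
    return records


def write_records_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> list[VariantRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))


def read_vcf(path: str | Path, caller: str) -> list[VariantRecord]:
    """Read a tumor/normal pair VCF into :class:`VariantRecord` objects.

    Expects samples named NORMAL and TUMOR with AD (ref,alt depths) FORMAT
    fields, and optional INFO keys AF1KG, AFEXAC and COSMIC. The caller is
    supplied by the caller argument since GDC VCFs are one file per caller.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        normal_idx = samples.index("NORMAL")
        tumor_idx = samples.index("TUMOR")
    except ValueError as exc:
        raise ValueError(f"{path}: expected NORMAL and TUMOR samples") from exc

    records = []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        ad = v.format("AD")
        n_ref, n_alt = int(ad[normal_idx][0]), int(ad[normal_idx][1])
        t_ref, t_alt = int(ad[tumor_idx][0]), int(ad[tumor_idx][1])
        af_1000g = v.INFO.get("AF1KG")
        af_exac = v.INFO.get("AFEXAC")
        records.append(
            VariantRecord(
                mutation_id=f"{v.CHROM}:{v.POS}:{v.REF}:{alt}",
                is_indel=len(v.REF) != 1 or len(alt) != 1,
                caller=caller,
                filter_status=v.FILTER or "PASS",
                normal_depth=n_ref + n_alt,
                normal_alt=n_alt,
                tumor_depth=t_ref + t_alt,
                tumor_alt=t_alt,
                af_1000g=None if af_1000g is None else float(af_1000g),
                af_exac=None if af_exac is None else float(af_exac),
                in_cosmic=bool(v.INFO.get("COSMIC", False)),
            )
        )
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal tumor/normal VCF (samples NORMAL, TUMOR)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ithbench",
        '##INFO=<ID=AF1KG,Number=1,Type=Float,Description="1000 genomes allele frequency">',
        '##INFO=<ID=AFEXAC,Number=1,Type=Float,Description="ExAC allele frequency">',
        '##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Reported in COSMIC">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for status in sorted({r.filter_status for r in records} - {"PASS"}):
        lines.append(f'##FILTER=<ID={status},Description="caller FILTER status">')
    chroms = []
    for r in records:
        chrom = r.mutation_id.split(":", 1)[0]
        if chrom not in chroms:
            chroms.append(chrom)
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR"
    )
    for r in sorted(records, key=_vcf_sort_key):
        chrom, pos, ref, alt = r.mutation_id.split(":")
        info_parts = []
        if r.af_1000g is not None:
            info_parts.append(f"AF1KG={r.af_1000g:g}")
        if r.af_exac is not None:
            info_parts.append(f"AFEXAC={r.af_exac:g}")
        if r.in_cosmic:
            info_parts.append("COSMIC")
        info = ";".join(info_parts) or "."
        normal = f"{r.normal_depth - r.normal_alt},{r.normal_alt}:{r.normal_depth}"
        tumor = f"{r.tumor_depth - r.tumor_alt},{r.tumor_alt}:{r.tumor_depth}"
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{r.filter_status}\t{info}"
            f"\tAD:DP\t{normal}\t{tumor}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _vcf_sort_key(record: VariantRecord) -> tuple:
    chrom, pos, _, _ = record.mutation_id.split(":")
    return (chrom, int(pos))
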