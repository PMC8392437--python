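"""Per-sample mutation tables and coverage-based sample QC.

A mutation table holds one record per unique variant key with its supporting
consensus-fragment count, the consensus coverage at the variant's start
position, and the resulting frequency ``count / coverage * 100`` (percent).
Counting happens in consensus-fragment space — after UMI collapsing — since
frequencies in the 0.1% range are only meaningful once PCR duplicates have
been collapsed to molecules.

Sample QC removes samples whose mean consensus coverage across the selected
targets falls strictly below a threshold (default 200).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .aligner import Alignment, VariantObservation
from .panel import Panel
from .read_engine import ConsensusFragment

TABLE_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "vclass", "count", "coverage", "frequency",
]


class TableConsistencyError(ValueError):
    """A mutation-table record violates its arithmetic invariants."""


@dataclass(frozen=True)
class MutationRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    count: int
    coverage: int

    def __post_init__(self) -> None:
        if not (0 < self.count <= self.coverage):
            raise TableConsistencyError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: "
                f"need 0 < count ({self.count}) <= coverage ({self.coverage})"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def frequency(self) -> float:
        """Variant frequency in percent: count / coverage * 100."""
        return self.count / self.coverage * 100.0


@dataclass
class SampleTable:
    sample_id: str
    records: list[MutationRecord]
    per_target_mean_coverage: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    mean_coverage_over_select_targets: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.mean_coverage_over_select_targets >= self.threshold


@dataclass
class AlignedFragment:
    """A consensus fragment together with its accepted reference alignment."""

    fragment: ConsensusFragment
    alignment: Alignment

    @property
    def fragment_id(self) -> str:
        return self.fragment.fragment_id

    def covers(self, target_start: int, genomic_pos: int) -> bool:
        lo = target_start + self.alignment.ref_start
        hi = target_start + self.alignment.ref_end
        return lo <= genomic_pos < hi


def tabulate(
    observations: list[VariantObservation],
    fragments: list[AlignedFragment],
    panel: Panel,
    sample_id: str,
) -> SampleTable:
    """Summarize identical genomic alterations into one record per variant key.

    ``count`` is the number of distinct consensus fragments carrying the
    variant; ``coverage`` is the number of distinct fragments whose alignment
    overlaps the variant's (left-normalized) start position. Per-target mean
    coverage is averaged over the target's whitelist positions.
    """
    known = {f.fragment_id for f in fragments}
    for obs in observations:
        if obs.fragment_id not in known:
            raise TableConsistencyError(
                f"observation {obs.chrom}:{obs.pos} references unknown fragment {obs.fragment_id}"
            )
    by_target: dict[str, list[AlignedFragment]] = {}
    for af in fragments:
        by_target.setdefault(af.fragment.target_id, []).append(af)

    coverage_at: dict[tuple[str, int], int] = {}
    per_target_cov: dict[str, float] = {}
    for target in panel.targets:
        afs = by_target.get(target.target_id, [])
        positions = [(v, v.pos) for v in panel.variants_in(target.target_id)]
        covs = []
        for variant, pos in positions:
            cov = sum(1 for af in afs if af.covers(target.start, pos))
            coverage_at[(variant.chrom, pos)] = cov
            covs.append(cov)
        per_target_cov[target.target_id] = float(sum(covs) / len(covs)) if covs else float(len(afs))

    carriers: dict[tuple[str, int, str, str], set[str]] = {}
    vclass_of: dict[tuple[str, int, str, str], str] = {}
    for obs in observations:
        carriers.setdefault(obs.key, set()).add(obs.fragment_id)
        vclass_of[obs.key] = obs.vclass
    records = []
    for key in sorted(carriers):
        chrom, pos, ref, alt = key
        count = len(carriers[key])
        coverage = coverage_at.get((chrom, pos), 0)
        records.append(
            MutationRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                vclass=vclass_of[key], count=count, coverage=coverage,
            )
        )
    return SampleTable(sample_id=sample_id, records=records,
                       per_target_mean_coverage=per_target_cov)


def qc_filter(
    samples: list[SampleTable],
    select_targets: list[str] | None = None,
    threshold: float = 200.0,
) -> tuple[list[SampleTable], list[tuple[SampleTable, QCReport]]]:
    """Split samples into (retained, excluded) by mean coverage over select targets.

    The inequality is strict: ``mean < threshold`` excludes, ``mean ==
    threshold`` retains. ``select_targets`` defaults to all targets present.
    """
    retained, excluded = [], []
    for sample in samples:
        targets = select_targets if select_targets is not None else sorted(sample.per_target_mean_coverage)
        if not targets:
            raise ValueError("select_targets must be non-empty")
        mean = sum(sample.per_target_mean_coverage.get(t, 0.0) for t in targets) / len(targets)
        report = QCReport(sample_id=sample.sample_id,
                          mean_coverage_over_select_targets=mean, threshold=threshold)
        if mean < threshold:
            excluded.append((sample, report))
        else:
            retained.append(sample)
    return retained, excluded


# ---------------------------------------------------------------------------
# I/O


def _format_frequency(value: float) -> str:
    return f"{value:.6g}"


def write_table(table: SampleTable, path) -> None:
    """Canonical mutation-table TSV (frequency at 6 significant digits)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for rec in table.records:
            fh.write(
                f"{table.sample_id}\t{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t"
                f"{rec.vclass}\t{rec.count}\t{rec.coverage}\t{_format_frequency(rec.frequency)}\n"
            )


def read_table(path) -> SampleTable:
    """Read a mutation-table TSV, validating the frequency column on the way in."""
    records = []
    sample_id = ""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TABLE_COLUMNS:
            raise TableConsistencyError(f"{path}: bad header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(TABLE_COLUMNS):
                raise TableConsistencyError(f"{path} line {lineno}: expected {len(TABLE_COLUMNS)} columns")
            try:
                sid, chrom, pos, ref, alt, vclass, count, coverage, freq = fields
                rec = MutationRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                                     vclass=vclass, count=int(count), coverage=int(coverage))
                stated = float(freq)
            except (ValueError, TableConsistencyError) as exc:
                raise TableConsistencyError(f"{path} line {lineno}: {exc}") from exc
            if not math.isclose(stated, rec.frequency, rel_tol=1e-4, abs_tol=1e-9):
                raise TableConsistencyError(
                    f"{path} line {lineno}: frequency {stated} != count/coverage*100 "
                    f"({rec.frequency:.6g})"
                )
            sample_id = sid
            records.append(rec)
    return SampleTable(sample_id=sample_id, records=records)


def tables_to_frame(tables: list[SampleTable]) -> pd.DataFrame:
    rows = []
    for table in tables:
        for rec in table.records:
            rows.append({
                "sample_id": table.sample_id, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alt, "vclass": rec.vclass,
                "count": rec.count, "coverage": rec.coverage, "frequency": rec.frequency,
            })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_vcf(table: SampleTable, path) -> None:
    """Minimal VCF v4.2 export (1-based POS; INFO DP/AD/AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Consensus coverage">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Supporting fragments">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Variant frequency (fraction)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in table.records:
            af = rec.count / rec.coverage
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                f"DP={rec.coverage};AD={rec.count};AF={af:.6g}\n"
            )
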