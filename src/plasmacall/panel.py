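"""Targeted panel definition: regions, primers, amplicon references, variant whitelist.

A panel ties together three files:

* a 5-column BED (``chrom  start  end  target_id  strand``) naming the
  amplified intervals,
* a FASTA keyed by ``target_id`` holding the amplicon reference sequence in
  read-1 orientation (the gene-specific primer is its prefix),
* a whitelist of the variants the caller is allowed to record, as a TSV with
  header ``chrom  pos  ref  alt  vclass`` (0-based ``pos``) or a minimal VCF.

Coordinates are 0-based half-open everywhere inside the package; 1-based
coordinates appear only at VCF import/export. Indels use the VCF-style
anchored representation (ref and alt share their first base) and are kept
left-normalized so that identical genomic alterations collapse to one key.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO

from ._dna import is_dna

MAX_INDEL_LENGTH = 50  # events of |len(ref)-len(alt)| >= 50 are out of scope

VCLASSES = ("SNP", "MNP", "INS", "DEL")


class PanelValidationError(ValueError):
    """A panel record violates an invariant; the message names the record."""


@dataclass(frozen=True)
class TargetRegion:
    """One amplified interval with its gene-specific primer.

    ``amplicon_seq`` is the reference sequence of ``[start, end)`` in read-1
    orientation; ``primer_seq`` is its prefix.
    """

    target_id: str
    chrom: str
    start: int
    end: int
    strand: str
    primer_seq: str
    amplicon_seq: str

    def validate(self) -> None:
        if self.end <= self.start:
            raise PanelValidationError(
                f"target {self.target_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise PanelValidationError(f"target {self.target_id}: bad strand {self.strand!r}")
        if not is_dna(self.amplicon_seq):
            raise PanelValidationError(f"target {self.target_id}: amplicon_seq is not DNA")
        if len(self.amplicon_seq) != self.end - self.start:
            raise PanelValidationError(
                f"target {self.target_id}: amplicon length {len(self.amplicon_seq)} "
                f"!= end-start {self.end - self.start}"
            )
        if not self.amplicon_seq.startswith(self.primer_seq) or not self.primer_seq:
            raise PanelValidationError(
                f"target {self.target_id}: primer_seq must be a non-empty prefix of amplicon_seq"
            )


@dataclass(frozen=True)
class WhitelistVariant:
    """One allowed variant key. ``pos`` is 0-based on the + strand."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        if self.vclass not in VCLASSES:
            raise PanelValidationError(f"variant {self.variant_id}: unknown vclass {self.vclass!r}")
        if not is_dna(self.ref) or not is_dna(self.alt):
            raise PanelValidationError(f"variant {self.variant_id}: ref/alt must be ACGT strings")
        lr, la = len(self.ref), len(self.alt)
        if self.vclass == "SNP" and not (lr == la == 1):
            raise PanelValidationError(f"variant {self.variant_id}: SNP requires len(ref)=len(alt)=1")
        if self.vclass == "MNP" and not (lr == la and lr > 1):
            raise PanelValidationError(f"variant {self.variant_id}: MNP requires len(ref)=len(alt)>1")
        if self.vclass in ("INS", "DEL"):
            if abs(lr - la) < 1:
                raise PanelValidationError(
                    f"variant {self.variant_id}: {self.vclass} requires length change"
                )
            if max(lr, la) >= MAX_INDEL_LENGTH:
                raise PanelValidationError(
                    f"variant {self.variant_id}: indel allele length {max(lr, la)} "
                    f"exceeds the strict <{MAX_INDEL_LENGTH} bp bound"
                )
            if self.vclass == "INS" and lr >= la:
                raise PanelValidationError(f"variant {self.variant_id}: INS requires len(alt)>len(ref)")
            if self.vclass == "DEL" and la >= lr:
                raise PanelValidationError(f"variant {self.variant_id}: DEL requires len(ref)>len(alt)")


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class implied by allele lengths (SNP/MNP/INS/DEL)."""
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class Panel:
    """Validated set of target regions plus the variant whitelist."""

    targets: tuple[TargetRegion, ...]
    whitelist: tuple[WhitelistVariant, ...]

    def __post_init__(self) -> None:
        for t in self.targets:
            t.validate()
        ids = [t.target_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise PanelValidationError("duplicate target_id in panel")
        vids = [v.variant_id for v in self.whitelist]
        if len(set(vids)) != len(vids):
            raise PanelValidationError("duplicate variant_id in whitelist")
        by_target = {}
        for v in self.whitelist:
            v.validate()
            homes = [t for t in self.targets if _contains(t, v)]
            if len(homes) != 1:
                raise PanelValidationError(
                    f"variant {v.variant_id} at {v.chrom}:{v.pos} lies inside "
                    f"{len(homes)} target regions (exactly 1 required)"
                )
            target = homes[0]
            normalized = left_normalize(v, target.amplicon_seq, target.start)
            if normalized.key != v.key:
                raise PanelValidationError(
                    f"variant {v.variant_id} is not left-normalized "
                    f"(canonical position {normalized.pos}, given {v.pos})"
                )
            by_target[v.variant_id] = target.target_id
        object.__setattr__(self, "_variant_target", by_target)

    # -- lookups -----------------------------------------------------------
    def target(self, target_id: str) -> TargetRegion:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(target_id)

    def target_of_variant(self, variant_id: str) -> str:
        return self._variant_target[variant_id]

    def variants_in(self, target_id: str) -> list[WhitelistVariant]:
        return [v for v in self.whitelist if self._variant_target[v.variant_id] == target_id]

    @property
    def whitelist_keys(self) -> dict[tuple[str, int, str, str], WhitelistVariant]:
        return {v.key: v for v in self.whitelist}


def _contains(t: TargetRegion, v: WhitelistVariant) -> bool:
    return t.chrom == v.chrom and t.start <= v.pos and v.pos + len(v.ref) <= t.end


# ---------------------------------------------------------------------------
# left normalization


def left_normalize(variant: WhitelistVariant, amplicon_seq: str, region_start: int) -> WhitelistVariant:
    """Shift an indel maximally left within its repeat context.

    Uses the standard anchored-representation algorithm: while ref and alt
    end with the same base, drop it and prepend the preceding reference base;
    finally trim a shared prefix down to the anchor base. SNP/MNP records are
    returned unchanged (after a reference check). Idempotent.
    """
    local = variant.pos - region_start
    if local < 0 or local + len(variant.ref) > len(amplicon_seq):
        raise PanelValidationError(
            f"variant {variant.variant_id}: position outside the amplicon reference"
        )
    if amplicon_seq[local : local + len(variant.ref)] != variant.ref:
        raise PanelValidationError(
            f"variant {variant.variant_id}: ref allele {variant.ref!r} does not match "
            f"amplicon sequence {amplicon_seq[local:local + len(variant.ref)]!r} at pos {variant.pos}"
        )
    if variant.vclass in ("SNP", "MNP"):
        return variant

    ref, alt, pos = variant.ref, variant.alt, local
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        last = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if len(ref) == 0 or len(alt) == 0:
            if pos == 0:
                ref, alt = ref + last, alt + last  # cannot shift past the amplicon start
                break
            pos -= 1
            base = amplicon_seq[pos]
            ref, alt = base + ref, base + alt
    # trim shared prefix beyond the single anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(variant, pos=pos + region_start, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# I/O


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _load_bed(bed_path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with _open_text(bed_path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PanelValidationError(f"{bed_path} line {i}: expected 5 BED columns")
            chrom, start, end, target_id, strand = fields[:5]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise PanelValidationError(f"{bed_path} line {i}: malformed coordinates") from exc
            rows.append((chrom, start_i, end_i, target_id, strand))
    return rows


def _load_whitelist_tsv(path) -> list[WhitelistVariant]:
    expected = ["chrom", "pos", "ref", "alt", "vclass"]
    variants = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected:
            raise PanelValidationError(f"{path}: whitelist header must be {expected}, got {header}")
        for i, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise PanelValidationError(f"{path} line {i}: expected 5 columns")
            chrom, pos, ref, alt, vclass = fields
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise PanelValidationError(f"{path} line {i}: malformed position {pos!r}") from exc
            variants.append(
                WhitelistVariant(
                    variant_id=f"{chrom}:{pos_i}:{ref}>{alt}",
                    chrom=chrom,
                    pos=pos_i,
                    ref=ref.upper(),
                    alt=alt.upper(),
                    vclass=vclass,
                )
            )
    return variants


def _load_whitelist_vcf(path) -> list[WhitelistVariant]:
    """Minimal VCF v4.2 reader (read-only whitelist dialect); 1-based POS."""
    variants = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PanelValidationError(f"{path} line {i}: expected >=5 VCF columns")
            chrom, pos, _vid, ref, alt = fields[:5]
            if "," in alt:
                raise PanelValidationError(f"{path} line {i}: multi-allelic records not supported")
            try:
                pos0 = int(pos) - 1
            except ValueError as exc:
                raise PanelValidationError(f"{path} line {i}: malformed POS {pos!r}") from exc
            ref, alt = ref.upper(), alt.upper()
            variants.append(
                WhitelistVariant(
                    variant_id=f"{chrom}:{pos0}:{ref}>{alt}",
                    chrom=chrom,
                    pos=pos0,
                    ref=ref,
                    alt=alt,
                    vclass=classify_alleles(ref, alt),
                )
            )
    return variants


def load_panel(bed_path, fasta_path, whitelist_path) -> Panel:
    """Load and validate a panel from BED + FASTA + whitelist (TSV or VCF)."""
    bed_rows = _load_bed(bed_path)
    seqs: dict[str, str] = {}
    primer_lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("primer_len="):
                primer_lengths[rec.id] = int(token.split("=", 1)[1])
    targets = []
    for chrom, start, end, target_id, strand in bed_rows:
        if target_id not in seqs:
            raise PanelValidationError(f"no FASTA record for target {target_id}")
        amplicon = seqs[target_id]
        # primer length comes from a 'primer_len=<n>' token in the FASTA
        # description (written by write_panel); default: first 20 bases.
        primer_len = primer_lengths.get(target_id, min(20, max(1, len(amplicon) - 1)))
        targets.append(
            TargetRegion(
                target_id=target_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                primer_seq=amplicon[:primer_len],
                amplicon_seq=amplicon,
            )
        )
    wl_path = Path(whitelist_path)
    if wl_path.suffix.lower() == ".vcf" or wl_path.name.endswith(".vcf.gz"):
        whitelist = _load_whitelist_vcf(wl_path)
    else:
        whitelist = _load_whitelist_tsv(wl_path)
    panel = Panel(targets=tuple(targets), whitelist=tuple(whitelist))
    return panel


def write_panel(panel: Panel, bed_path, fasta_path, whitelist_path) -> None:
    """Write a panel back to BED + FASTA + whitelist TSV (round-trips load_panel)."""
    with open(bed_path, "w") as bed:
        for t in panel.targets:
            bed.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.target_id}\t{t.strand}\n")
    with open(fasta_path, "w") as fa:
        for t in panel.targets:
            fa.write(f">{t.target_id} primer_len={len(t.primer_seq)}\n{t.amplicon_seq}\n")
    with open(whitelist_path, "w") as wl:
        wl.write("chrom\tpos\tref\talt\tvclass\n")
        for v in panel.whitelist:
            wl.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vclass}\n")
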