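"""From paired FASTQ to per-molecule consensus fragments.

The engine mirrors how UMI-tagged amplicon libraries are structured: read 1
starts with the gene-specific primer followed by genomic sequence; read 2
starts with the unique molecular identifier (UMI) followed by the reverse
complement of the far end of the molecule. Processing steps:

1. read 1 is screened against the panel primers (substitutions only) and the
   primer is trimmed;
2. the UMI is clipped from read 2;
3. read 2 (reverse-complemented) is merged onto read 1 by best ungapped
   overlap, complementing read 1 and extending past its end;
4. reads are consolidated into families keyed by (target, UMI) and each
   family is collapsed to a per-column majority consensus.

Every input read pair is accounted for exactly once across the consensus
members and the per-reason rejection tallies.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import decode, encode, revcomp
from .panel import Panel


class FastqPairError(ValueError):
    """Malformed or inconsistent paired FASTQ input."""


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FastqPairError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class TaggedRead:
    read_id: str
    target_id: str
    umi: str
    merged_seq: str
    merged_qual: str


@dataclass
class ReadFamily:
    target_id: str
    umi: str
    members: list[TaggedRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusFragment:
    """Error-corrected molecule sequence from one (target, UMI) read family."""

    target_id: str
    umi: str
    seq: str
    family_size: int
    per_position_agreement: np.ndarray

    @property
    def fragment_id(self) -> str:
        return f"{self.target_id}:{self.umi}:{self.family_size}"

    @property
    def n_fraction(self) -> float:
        if not self.seq:
            return 0.0
        return self.seq.count("N") / len(self.seq)


@dataclass
class EngineConfig:
    """Tunable knobs of the consensus engine (all surfaced, none hard-coded)."""

    umi_length: int = 12
    max_primer_mismatches: int = 2
    min_overlap: int = 20
    max_overlap_mismatch_fraction: float = 0.1
    q_low: int = 20  # Phred below which a read-1 base yields to a confident read-2 base
    unmerged_policy: str = "keep_read1"  # or "reject"
    min_family_size: int = 3
    min_agreement: float = 0.75
    max_n_fraction: float = 0.10
    merge_umi_one_mismatch: bool = False


# ---------------------------------------------------------------------------
# FASTQ input


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Lazily yield read pairs from two synchronized FASTQ files (gzip ok)."""
    with _open_maybe_gzip(r1_path) as fh1, _open_maybe_gzip(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            index += 1
            if rec1 is None or rec2 is None:
                raise FastqPairError(
                    f"mate-count mismatch between {r1_path} and {r2_path} at pair {index}"
                )
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            yield ReadPair(id1.split()[0], seq1.upper(), q1, seq2.upper(), q2)


# ---------------------------------------------------------------------------
# per-read steps


def extract_umi(pair: ReadPair, umi_length: int) -> tuple[str, ReadPair] | None:
    """Clip the UMI off the start of read 2; None if read 2 is too short."""
    if len(pair.seq2) <= umi_length:
        return None
    umi = pair.seq2[:umi_length]
    trimmed = ReadPair(
        pair.read_id, pair.seq1, pair.qual1,
        pair.seq2[umi_length:], pair.qual2[umi_length:],
    )
    return umi, trimmed


class _PrimerIndex:
    """Exact-prefix dict with a Hamming-distance fallback over all primers."""

    def __init__(self, panel: Panel):
        self.primers = [(t.target_id, t.primer_seq, encode(t.primer_seq)) for t in panel.targets]
        if not self.primers:
            raise ValueError("panel has no primers")
        self.exact = {}
        for target_id, primer, _ in self.primers:
            self.exact.setdefault(primer, []).append(target_id)

    def match(self, seq1: str, max_mismatches: int) -> tuple[str, int] | str:
        """Return (target_id, primer_len) or a rejection reason."""
        # exact fast path: most reads carry an error-free primer
        for target_id, primer, _ in self.primers:
            if seq1.startswith(primer):
                hits = self.exact[primer]
                if len(hits) > 1:
                    return "ambiguous_primer"
                return target_id, len(primer)
        best: list[tuple[str, int]] = []
        best_d = max_mismatches + 1
        arr = None
        for target_id, primer, enc_primer in self.primers:
            L = len(primer)
            if len(seq1) < L:
                continue
            if arr is None or len(arr) < L:
                arr = encode(seq1)
            d = int(np.count_nonzero(arr[:L] != enc_primer))
            if d < best_d:
                best_d, best = d, [(target_id, L)]
            elif d == best_d:
                best.append((target_id, L))
        if best_d > max_mismatches:
            return "no_primer"
        if len(best) > 1:
            return "ambiguous_primer"
        return best[0]


def screen_primer(pair: ReadPair, panel: Panel, max_mismatches: int = 2,
                  index: _PrimerIndex | None = None):
    """Assign the pair to the target whose primer matches the read-1 prefix.

    Returns (target_id, trimmed pair) or a rejection reason string
    ("no_primer" / "ambiguous_primer"). Matching allows substitutions only;
    a tie at the minimum distance is ambiguous and rejected.
    """
    if index is None:
        index = _PrimerIndex(panel)
    hit = index.match(pair.seq1, max_mismatches)
    if isinstance(hit, str):
        return hit
    target_id, primer_len = hit
    trimmed = ReadPair(
        pair.read_id, pair.seq1[primer_len:], pair.qual1[primer_len:],
        pair.seq2, pair.qual2,
    )
    return target_id, trimmed


def merge_pair(pair: ReadPair, config: EngineConfig) -> tuple[str, str] | None:
    """Merge primer/UMI-trimmed mates into one molecule sequence.

    Read 2 is reverse-complemented and slid along read 1 looking for the
    longest ungapped overlap of >= min_overlap bases with a mismatch fraction
    <= max_overlap_mismatch_fraction. Inside the overlap, read-1 bases win
    unless their quality is below q_low while the read-2 base is confident;
    read 2 then extends the merged sequence beyond read 1's end. Returns
    (seq, qual) or None when no acceptable overlap exists.
    """
    seq1, qual1 = pair.seq1, pair.qual1
    seq2 = revcomp(pair.seq2)
    qual2 = pair.qual2[::-1]
    len1, len2 = len(seq1), len(seq2)
    if len1 == 0 or len2 == 0:
        return None
    a1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(seq2.encode(), dtype=np.uint8)
    best_offset = None
    # offset: position in read-1 coordinates where read 2 starts; scanning
    # small offsets first tries the longest overlaps first
    for offset in range(0, len1 - config.min_overlap + 1):
        ov = min(len1 - offset, len2)
        if ov < config.min_overlap:
            break
        mismatches = int(np.count_nonzero(a1[offset : offset + ov] != a2[:ov]))
        if mismatches / ov <= config.max_overlap_mismatch_fraction:
            best_offset = offset
            break
    if best_offset is None:
        return None
    offset = best_offset
    ov = min(len1 - offset, len2)
    q1 = np.frombuffer(qual1.encode(), dtype=np.uint8) - 33
    q2 = np.frombuffer(qual2.encode(), dtype=np.uint8) - 33
    merged = a1.copy()
    take2 = (q1[offset : offset + ov] < config.q_low) & (q2[:ov] >= config.q_low)
    out_qual = np.frombuffer(qual1.encode(), dtype=np.uint8).copy()
    merged[offset : offset + ov][take2] = a2[:ov][take2]
    out_qual[offset : offset + ov][take2] = (q2[:ov][take2] + 33).astype(np.uint8)
    if offset + len2 > len1:  # read 2 extends beyond read 1
        tail = a2[ov:]
        merged = np.concatenate([merged, tail])
        out_qual = np.concatenate([out_qual, (q2[ov:] + 33).astype(np.uint8)])
    return merged.tobytes().decode(), out_qual.tobytes().decode()


# ---------------------------------------------------------------------------
# families and consensus


def group_families(reads: Iterable[TaggedRead], merge_one_mismatch: bool = False) -> list[ReadFamily]:
    """Group tagged reads by exact (target_id, umi); optional directional merge.

    With ``merge_one_mismatch`` a family absorbs a 1-mismatch neighbour when
    its size is at least 2x the neighbour's size minus 1 (directional rule:
    the larger family absorbs the smaller).
    """
    buckets: dict[tuple[str, str], list[TaggedRead]] = defaultdict(list)
    for read in reads:
        buckets[(read.target_id, read.umi)].append(read)
    if merge_one_mismatch:
        by_target: dict[str, list[str]] = defaultdict(list)
        for target_id, umi in buckets:
            by_target[target_id].append(umi)
        for target_id, umis in by_target.items():
            # biggest first; deterministic tie-break on the UMI string
            umis.sort(key=lambda u: (-len(buckets[(target_id, u)]), u))
            absorbed: set[str] = set()
            for big in umis:
                if big in absorbed:
                    continue
                for small in umis:
                    if small == big or small in absorbed:
                        continue
                    nb, ns = len(buckets[(target_id, big)]), len(buckets[(target_id, small)])
                    if ns > nb:
                        continue
                    if nb >= 2 * ns - 1 and _hamming1(big, small):
                        buckets[(target_id, big)].extend(buckets[(target_id, small)])
                        absorbed.add(small)
            for umi in absorbed:
                del buckets[(target_id, umi)]
    families = [
        ReadFamily(target_id=k[0], umi=k[1], members=v)
        for k, v in sorted(buckets.items())
    ]
    return families


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def build_consensus(
    family: ReadFamily,
    min_family_size: int = 3,
    min_agreement: float = 0.75,
    max_n_fraction: float = 0.10,
) -> ConsensusFragment | str:
    """Collapse a family to its per-column majority consensus.

    Columns take the modal base when its fraction among covering members is
    >= min_agreement, else N; a tied mode is also N (never invent a base).
    Returns a rejection reason ("small_family" / "high_n_fraction") instead of
    a fragment when the family is too small or too ambiguous.
    """
    if family.size < min_family_size:
        return "small_family"
    length = max(len(m.merged_seq) for m in family.members)
    counts = np.zeros((5, length), dtype=np.int32)
    coverage = np.zeros(length, dtype=np.int32)
    for member in family.members:
        codes = encode(member.merged_seq)
        L = len(codes)
        coverage[:L] += 1
        # N (code 4) counts as coverage but never votes
        for base in range(4):
            counts[base, :L] += codes == base
    votes = counts[:4]
    top = votes.max(axis=0)
    winners = (votes == top).sum(axis=0)
    voters = votes.sum(axis=0)
    modal = votes.argmax(axis=0).astype(np.uint8)
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(coverage > 0, top / np.maximum(coverage, 1), 0.0)
    is_n = (winners != 1) | (agreement < min_agreement) | (voters == 0)
    modal[is_n] = 4
    seq = decode(modal)
    fragment = ConsensusFragment(
        target_id=family.target_id,
        umi=family.umi,
        seq=seq,
        family_size=family.size,
        per_position_agreement=agreement,
    )
    if fragment.n_fraction > max_n_fraction:
        return "high_n_fraction"
    return fragment


# ---------------------------------------------------------------------------
# end-to-end


@dataclass
class EngineResult:
    fragments: list[ConsensusFragment]
    tally: Counter = field(default_factory=Counter)

    @property
    def consensus_member_reads(self) -> int:
        return self.tally.get("consensus_member", 0)


def consensus_from_pairs(pairs: Iterable[ReadPair], panel: Panel,
                         config: EngineConfig | None = None) -> EngineResult:
    """Run the full engine over an iterable of read pairs.

    The tally accounts for every input pair exactly once, either as
    ``consensus_member`` or under one ``rejected:<reason>`` key.
    """
    if config is None:
        config = EngineConfig()
    index = _PrimerIndex(panel)
    tally: Counter = Counter()
    tagged: list[TaggedRead] = []
    for pair in pairs:
        extracted = extract_umi(pair, config.umi_length)
        if extracted is None:
            tally["rejected:short_read2"] += 1
            continue
        umi, trimmed = extracted
        hit = screen_primer(trimmed, panel, config.max_primer_mismatches, index)
        if isinstance(hit, str):
            tally[f"rejected:{hit}"] += 1
            continue
        target_id, trimmed = hit
        merged = merge_pair(trimmed, config)
        if merged is None:
            if config.unmerged_policy == "reject":
                tally["rejected:no_overlap"] += 1
                continue
            merged = (trimmed.seq1, trimmed.qual1)
        seq, qual = merged
        tagged.append(TaggedRead(pair.read_id, target_id, umi, seq, qual))
    fragments: list[ConsensusFragment] = []
    for family in group_families(tagged, config.merge_umi_one_mismatch):
        result = build_consensus(
            family, config.min_family_size, config.min_agreement, config.max_n_fraction
        )
        if isinstance(result, str):
            tally[f"rejected:{result}"] += family.size
        else:
            tally["consensus_member"] += family.size
            fragments.append(result)
    fragments.sort(key=lambda f: (f.target_id, f.umi))
    return EngineResult(fragments=fragments, tally=tally)


def consensus_from_fastq(r1_path, r2_path, panel: Panel,
                         config: EngineConfig | None = None) -> EngineResult:
    return consensus_from_pairs(read_fastq_pairs(r1_path, r2_path), panel, config)


def write_consensus_fasta(result: EngineResult, path) -> None:
    """Consensus fragments as FASTA (id = target_id:umi:family_size)."""
    with open(path, "w") as fh:
        for fragment in result.fragments:
            fh.write(f">{fragment.fragment_id}\n{fragment.seq}\n")


def write_rejection_tally(result: EngineResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("outcome\tread_pairs\n")
        for key in sorted(result.tally):
            fh.write(f"{key}\t{result.tally[key]}\n")
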