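"""Local alignment of consensus fragments and whitelist-screened variant extraction.

Each error-corrected consensus fragment is aligned to its amplicon reference
with an affine-gap Smith-Waterman (Gotoh) algorithm, and the differences are
converted into SNP / MNP / short-indel observations. Only observations whose
left-normalized key is on the panel whitelist enter the downstream mutation
table; everything else is tallied in a diagnostics channel.

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gapped base pays ``gap_open``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._dna import encode
from .panel import (
    MAX_INDEL_LENGTH,
    Panel,
    TargetRegion,
    WhitelistVariant,
    classify_alleles,
    left_normalize,
)


class AlignmentConsistencyError(RuntimeError):
    """An alignment does not describe the sequences it claims to."""


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("affine contract requires gap_open <= gap_extend <= 0")


@dataclass
class Alignment:
    """Local alignment of a query fragment against an amplicon reference.

    Coordinates are half-open and local to the two sequences; ``ops`` is a
    run-length list over {M (match), X (mismatch), I (insertion in query),
    D (deletion from reference)}.
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ops: list[tuple[str, int]]
    score: int
    target_id: str | None = None

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    def cigar(self) -> str:
        """CIGAR string with M/X collapsed to M (SAM convention)."""
        merged: list[tuple[str, int]] = []
        for op, length in self.ops:
            sam_op = "M" if op in ("M", "X") else op
            if merged and merged[-1][0] == sam_op:
                merged[-1] = (sam_op, merged[-1][1] + length)
            else:
                merged.append((sam_op, length))
        return "".join(f"{length}{op}" for op, length in merged)

    def n_mismatch_bases(self) -> int:
        return sum(length for op, length in self.ops if op in ("X", "I", "D"))


_NEG = np.iinfo(np.int32).min // 4


@njit(cache=True)
def _gotoh_fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = q.shape[0], r.shape[0]
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap consuming query
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap consuming ref
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            # N in the query never matches; score it as a mismatch
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            best_prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best_prev:
                best_prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best_prev:
                best_prev = Iy[i - 1, j - 1]
            if best_prev < 0:
                best_prev = 0
            M[i, j] = best_prev + s
            a = M[i - 1, j] + gap_open
            b = Ix[i - 1, j] + gap_extend
            Ix[i, j] = a if a >= b else b
            a = M[i, j - 1] + gap_open
            b = Iy[i, j - 1] + gap_extend
            Iy[i, j] = a if a >= b else b
    return M, Ix, Iy


def _traceback(M, Ix, Iy, q, r, scheme: ScoringScheme, end_i: int, end_j: int):
    """Trace one co-optimal path from an M end cell; returns (ops, qs, rs, gaps)."""
    ops: list[str] = []
    i, j = end_i, end_j
    state = "M"
    gap_openings = 0
    while i > 0 and j > 0:
        if state == "M":
            s = scheme.match if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else scheme.mismatch
            ops.append("M" if s == scheme.match else "X")
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if prev == 0:
                # local start: co-optimal even when a zero-score prefix exists,
                # and keeps the alignment span minimal
                break
            if i == 0 or j == 0:
                break
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "Ix"
            elif Iy[i, j] == prev:
                state = "Iy"
            else:
                raise AlignmentConsistencyError("traceback lost the optimal path")
        elif state == "Ix":
            ops.append("I")
            if Ix[i, j] == M[i - 1, j] + scheme.gap_open:
                gap_openings += 1
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:  # Iy
            ops.append("D")
            if Iy[i, j] == M[i, j - 1] + scheme.gap_open:
                gap_openings += 1
                state = "M"
            else:
                state = "Iy"
            j -= 1
    ops.reverse()
    return ops, i, j, gap_openings


def smith_waterman(query: str, reference: str, scheme: ScoringScheme | None = None) -> Alignment:
    """Optimal local alignment under affine-gap scoring.

    Among co-optimal alignments the one with the smallest ``ref_start``, then
    smallest ``query_start``, then fewest gap openings is preferred (resolved
    over the co-optimal end cells; ties within one traceback close gaps
    eagerly, which keeps the result deterministic).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not reference:
        raise ValueError("reference must be non-empty")
    if not query:
        return Alignment(0, 0, 0, 0, [], 0)
    q = encode(query)
    r = encode(reference)
    M, Ix, Iy = _gotoh_fill(
        q, r, np.int32(scheme.match), np.int32(scheme.mismatch),
        np.int32(scheme.gap_open), np.int32(scheme.gap_extend),
    )
    best = int(M.max())
    if best <= 0:
        return Alignment(0, 0, 0, 0, [], 0)
    ends = np.argwhere(M == best)
    candidates = []
    for end_i, end_j in ends:
        ops, qs, rs, gaps = _traceback(M, Ix, Iy, q, r, scheme, int(end_i), int(end_j))
        candidates.append((rs, qs, gaps, int(end_j), int(end_i), ops))
    rs, qs, gaps, end_j, end_i, ops = min(candidates, key=lambda c: c[:5])
    run_ops: list[tuple[str, int]] = []
    for op in ops:
        if run_ops and run_ops[-1][0] == op:
            run_ops[-1] = (op, run_ops[-1][1] + 1)
        else:
            run_ops.append((op, 1))
    return Alignment(
        query_start=qs, query_end=end_i, ref_start=rs, ref_end=end_j,
        ops=run_ops, score=best,
    )


@dataclass(frozen=True)
class VariantObservation:
    """One whitelist variant seen in one consensus fragment."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    fragment_id: str
    sample_id: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantDiagnostics:
    """Counts of events screened out before the mutation table."""

    non_whitelist: int = 0
    oversize_indel: int = 0
    n_masked: int = 0
    unanchorable: int = 0
    by_key: dict = field(default_factory=dict)

    def record_non_whitelist(self, key) -> None:
        self.non_whitelist += 1
        self.by_key[key] = self.by_key.get(key, 0) + 1


def _raw_events(aln: Alignment, query: str, reference: str, diagnostics: VariantDiagnostics):
    """Yield raw (local_pos, ref, alt) events from an alignment walk."""
    qpos, rpos = aln.query_start, aln.ref_start
    events = []
    x_run: list[tuple[int, str, str]] = []

    def flush_run():
        if not x_run:
            return
        pos0 = x_run[0][0]
        events.append((pos0, "".join(c[1] for c in x_run), "".join(c[2] for c in x_run)))
        x_run.clear()

    for op, length in aln.ops:
        if op == "M":
            flush_run()
            for k in range(length):
                if query[qpos + k] != "N" and query[qpos + k] != reference[rpos + k]:
                    raise AlignmentConsistencyError("M column disagrees with sequences")
            qpos += length
            rpos += length
        elif op == "X":
            for k in range(length):
                qb, rb = query[qpos + k], reference[rpos + k]
                if qb == "N":
                    diagnostics.n_masked += 1
                    flush_run()
                    continue
                if x_run and x_run[-1][0] != rpos + k - 1:
                    flush_run()
                x_run.append((rpos + k, rb, qb))
            qpos += length
            rpos += length
        elif op == "I":
            flush_run()
            inserted = query[qpos : qpos + length]
            if "N" in inserted:
                diagnostics.n_masked += 1
            elif rpos == 0:
                diagnostics.unanchorable += 1
            else:
                anchor = reference[rpos - 1]
                events.append((rpos - 1, anchor, anchor + inserted))
            qpos += length
        elif op == "D":
            flush_run()
            if rpos == 0:
                diagnostics.unanchorable += 1
            else:
                anchor = reference[rpos - 1]
                events.append((rpos - 1, anchor + reference[rpos : rpos + length], anchor))
            rpos += length
        else:
            raise AlignmentConsistencyError(f"unknown op {op!r}")
    flush_run()
    if qpos != aln.query_end or rpos != aln.ref_end:
        raise AlignmentConsistencyError("ops do not span the stated alignment interval")
    return events


def extract_variants(
    aln: Alignment,
    fragment_seq: str,
    target: TargetRegion,
    panel: Panel,
    fragment_id: str,
    diagnostics: VariantDiagnostics | None = None,
) -> list[VariantObservation]:
    """Turn alignment differences into whitelist-screened variant observations.

    Maximal runs of adjacent substitutions merge into one MNP; substitutions
    are never merged with indels. Indels are anchored and left-normalized
    against the amplicon so keys match the whitelist representation. Columns
    where the fragment has N produce no call; events spanning >= 50 bases are
    discarded.
    """
    if diagnostics is None:
        diagnostics = VariantDiagnostics()
    whitelist = panel.whitelist_keys
    observations = []
    for local_pos, ref, alt in _raw_events(aln, fragment_seq, target.amplicon_seq, diagnostics):
        if max(len(ref), len(alt)) >= MAX_INDEL_LENGTH:
            diagnostics.oversize_indel += 1
            continue
        vclass = classify_alleles(ref, alt)
        raw = WhitelistVariant(
            variant_id="obs",
            chrom=target.chrom,
            pos=target.start + local_pos,
            ref=ref,
            alt=alt,
            vclass=vclass,
        )
        if vclass in ("INS", "DEL"):
            raw = left_normalize(raw, target.amplicon_seq, target.start)
        key = (raw.chrom, raw.pos, raw.ref, raw.alt)
        if key in whitelist:
            observations.append(
                VariantObservation(
                    chrom=raw.chrom, pos=raw.pos, ref=raw.ref, alt=raw.alt,
                    vclass=whitelist[key].vclass, fragment_id=fragment_id,
                )
            )
        else:
            diagnostics.record_non_whitelist(key)
    return observations


def write_sam(alignments, panel: Panel, path) -> None:
    """Export fragment alignments as SAM (CIGAR from ops, NM tag)."""
    targets = list(panel.targets)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for t in targets:
            fh.write(f"@SQ\tSN:{t.target_id}\tLN:{len(t.amplicon_seq)}\n")
        for fragment_id, seq, aln in alignments:
            cigar = aln.cigar() if aln.ops else "*"
            softclip_left = f"{aln.query_start}S" if aln.query_start else ""
            softclip_right = (
                f"{len(seq) - aln.query_end}S" if aln.query_end < len(seq) else ""
            )
            full_cigar = f"{softclip_left}{cigar}{softclip_right}" if cigar != "*" else "*"
            fh.write(
                f"{fragment_id}\t0\t{aln.target_id}\t{aln.ref_start + 1}\t60\t"
                f"{full_cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{aln.n_mismatch_bases()}\n"
            )
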