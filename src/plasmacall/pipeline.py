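"""End-to-end targeted calling: paired FASTQ to a per-sample mutation table."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .aligner import (
    ScoringScheme,
    VariantDiagnostics,
    extract_variants,
    smith_waterman,
)
from .mutation_table import AlignedFragment, SampleTable, tabulate
from .panel import Panel
from .read_engine import EngineConfig, EngineResult, consensus_from_fastq, consensus_from_pairs

# fragments whose best local alignment covers less of the fragment than this
# are treated as unalignable (chimeras, severe artefacts) and dropped
MIN_FRAGMENT_ALIGNED_FRACTION = 0.8


@dataclass
class CallResult:
    table: SampleTable
    engine: EngineResult
    aligned_fragments: list[AlignedFragment]
    observations: list
    diagnostics: VariantDiagnostics
    align_tally: Counter = field(default_factory=Counter)


def call_from_engine_result(
    engine_result: EngineResult,
    panel: Panel,
    sample_id: str,
    scheme: ScoringScheme | None = None,
) -> CallResult:
    """Align consensus fragments, extract whitelist variants, tabulate."""
    if scheme is None:
        scheme = ScoringScheme()
    diagnostics = VariantDiagnostics()
    aligned: list[AlignedFragment] = []
    observations = []
    align_tally: Counter = Counter()
    targets = {t.target_id: t for t in panel.targets}
    for fragment in engine_result.fragments:
        target = targets[fragment.target_id]
        aln = smith_waterman(fragment.seq, target.amplicon_seq, scheme)
        aln.target_id = target.target_id
        aligned_fraction = aln.query_span / len(fragment.seq) if fragment.seq else 0.0
        if aligned_fraction < MIN_FRAGMENT_ALIGNED_FRACTION:
            align_tally["unalignable"] += 1
            continue
        align_tally["aligned"] += 1
        af = AlignedFragment(fragment=fragment, alignment=aln)
        aligned.append(af)
        observations.extend(
            extract_variants(aln, fragment.seq, target, panel, af.fragment_id, diagnostics)
        )
    table = tabulate(observations, aligned, panel, sample_id)
    return CallResult(
        table=table,
        engine=engine_result,
        aligned_fragments=aligned,
        observations=observations,
        diagnostics=diagnostics,
        align_tally=align_tally,
    )


def call_sample(
    r1_path,
    r2_path,
    panel: Panel,
    sample_id: str,
    engine_config: EngineConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> CallResult:
    """Full pipeline from a paired FASTQ to a mutation table."""
    engine_result = consensus_from_fastq(r1_path, r2_path, panel, engine_config)
    return call_from_engine_result(engine_result, panel, sample_id, scheme)


def call_pairs(
    pairs,
    panel: Panel,
    sample_id: str,
    engine_config: EngineConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> CallResult:
    """Full pipeline from in-memory read pairs (simulator output)."""
    engine_result = consensus_from_pairs(pairs, panel, engine_config)
    return call_from_engine_result(engine_result, panel, sample_id, scheme)
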