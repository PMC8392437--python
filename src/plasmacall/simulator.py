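"""Synthetic data with the statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_reads` emits UMI-tagged paired amplicon reads — per-target
  template molecules, Bernoulli spike-in variants at a configured VAF, family
  expansion under a zero-truncated Poisson size law, and iid substitution
  errors — together with a molecule-level truth table. This exercises the
  read engine, aligner and mutation table end to end, down to spike-ins in
  the 0.1% VAF range.
* :func:`simulate_cohort` emits per-sample mutation-frequency matrices with a
  sparse zero-inflated-exponential background and a planted multiplicative
  cancer signal that scales with organ-specific variant pools and tumour
  stage. This exercises the classifier and evaluator.

Neither generator claims biological realism beyond this structure; see the
methods note for what that implies about test coverage.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import revcomp
from .panel import Panel, TargetRegion, WhitelistVariant, left_normalize
from .read_engine import ReadPair

ORGANS = ("bladder", "prostate", "lung", "liver", "pancreas", "colorectal", "breast")
STAGES = ("I", "II", "III", "IV")


# ---------------------------------------------------------------------------
# synthetic panels


def random_panel(
    n_targets: int = 20,
    amplicon_length: int = 140,
    primer_length: int = 20,
    variants_per_target: int = 2,
    indel_fraction: float = 0.2,
    seed: int = 0,
) -> Panel:
    """A random but valid panel: primers unique, whitelist left-normalized."""
    rng = _random.Random(seed)
    targets = []
    variants = []
    primers: set[str] = set()
    pos_cursor = 1000
    for t in range(n_targets):
        while True:
            amplicon = "".join(rng.choice("ACGT") for _ in range(amplicon_length))
            primer = amplicon[:primer_length]
            # primers must be mutually distinguishable even with 2 mismatches
            if all(sum(a != b for a, b in zip(primer, p)) > 5 for p in primers):
                break
        primers.add(primer)
        target_id = f"T{t:04d}"
        target = TargetRegion(
            target_id=target_id, chrom="chrS", start=pos_cursor,
            end=pos_cursor + amplicon_length, strand="+",
            primer_seq=primer, amplicon_seq=amplicon,
        )
        targets.append(target)
        # whitelist positions clear of the primer and the amplicon ends
        lo, hi = primer_length + 5, amplicon_length - 10
        chosen: set[int] = set()
        for v in range(variants_per_target):
            while True:
                local = rng.randrange(lo, hi)
                if all(abs(local - c) > 4 for c in chosen):
                    break
            chosen.add(local)
            ref_base = amplicon[local]
            if rng.random() < indel_fraction:
                if rng.random() < 0.5:
                    ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
                    raw = WhitelistVariant(
                        variant_id="tmp", chrom="chrS", pos=pos_cursor + local,
                        ref=ref_base, alt=ref_base + ins, vclass="INS",
                    )
                else:
                    dlen = rng.randint(1, 3)
                    if local + 1 + dlen >= amplicon_length - 2:
                        dlen = 1
                    raw = WhitelistVariant(
                        variant_id="tmp", chrom="chrS", pos=pos_cursor + local,
                        ref=amplicon[local : local + 1 + dlen], alt=ref_base, vclass="DEL",
                    )
                raw = left_normalize(raw, amplicon, pos_cursor)
                if raw.pos - pos_cursor < lo - 4:  # normalized into the primer zone
                    continue
                variant = WhitelistVariant(
                    variant_id=f"{target_id}_v{v}", chrom="chrS", pos=raw.pos,
                    ref=raw.ref, alt=raw.alt, vclass=raw.vclass,
                )
            else:
                alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
                variant = WhitelistVariant(
                    variant_id=f"{target_id}_v{v}", chrom="chrS",
                    pos=pos_cursor + local, ref=ref_base, alt=alt_base, vclass="SNP",
                )
            if any(_overlaps(variant, w) for w in variants):
                continue
            variants.append(variant)
        pos_cursor += amplicon_length + 100
    return Panel(targets=tuple(targets), whitelist=tuple(variants))


def _overlaps(a: WhitelistVariant, b: WhitelistVariant) -> bool:
    if a.chrom != b.chrom:
        return False
    return a.pos < b.pos + len(b.ref) and b.pos < a.pos + len(a.ref)


# ---------------------------------------------------------------------------
# read-level simulation


@dataclass
class ReadSimConfig:
    """Conditions for read-level simulation.

    The study-scale reference is a ~200,000x raw depth over 3062 targets; the
    desk-scale default of <= 5,000 molecules per target keeps simulations
    tractable while preserving the per-molecule structure.
    """

    panel: Panel
    molecules_per_target: int = 2000
    family_size_mean: float = 6.0  # zero-truncated Poisson mean
    per_base_error: float = 0.005
    umi_length: int = 12
    spike_ins: list = field(default_factory=list)  # [(WhitelistVariant, vaf)]
    read_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_error <= 0.1:
            raise ValueError("per_base_error must be in [0, 0.1]")
        keys = {v.key for v in self.panel.whitelist}
        for variant, vaf in self.spike_ins:
            if not 0 <= vaf <= 1:
                raise ValueError("vaf must be in [0, 1]")
            if variant.key not in keys:
                raise ValueError(f"spike-in {variant.variant_id} is not on the panel whitelist")


def apply_variant(amplicon: str, variant: WhitelistVariant, region_start: int) -> str:
    """Apply one whitelist variant to an amplicon reference sequence."""
    local = variant.pos - region_start
    assert amplicon[local : local + len(variant.ref)] == variant.ref
    return amplicon[:local] + variant.alt + amplicon[local + len(variant.ref):]


def _zt_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (resample zeros)."""
    out = rng.poisson(mean, size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.poisson(mean, int(zeros.sum()))
        zeros = out == 0
    return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


@dataclass
class ReadSimOutput:
    pairs: list[ReadPair]
    truth_molecules: pd.DataFrame  # molecule_id, target_id, umi, variant_ids
    truth_reads: int


def simulate_reads(config: ReadSimConfig) -> ReadSimOutput:
    """Generate UMI-tagged read pairs plus the molecule-level truth table."""
    rng = np.random.default_rng(config.seed)
    pairs: list[ReadPair] = []
    records = []
    spike_by_target: dict[str, list[tuple[WhitelistVariant, float]]] = {}
    key_map = config.panel.whitelist_keys
    for variant, vaf in config.spike_ins:
        canonical = key_map[variant.key]
        tid = config.panel.target_of_variant(canonical.variant_id)
        spike_by_target.setdefault(tid, []).append((canonical, vaf))
    qual_hi = "I"  # Phred 40
    U = config.umi_length
    R = config.read_length
    for target in config.panel.targets:
        spikes = spike_by_target.get(target.target_id, [])
        n_mol = config.molecules_per_target
        family_sizes = _zt_poisson(rng, config.family_size_mean, n_mol)
        carrier_draws = {
            v.variant_id: rng.random(n_mol) < vaf for v, vaf in spikes
        }
        umis = ["".join("ACGT"[b] for b in rng.integers(0, 4, U)) for _ in range(n_mol)]
        for mol in range(n_mol):
            carried = [v for v, _ in spikes if carrier_draws[v.variant_id][mol]]
            template = target.amplicon_seq
            for variant in carried:
                template = apply_variant(template, variant, target.start)
            umi = umis[mol]
            molecule_id = f"{target.target_id}:m{mol:06d}"
            records.append(
                {
                    "molecule_id": molecule_id,
                    "target_id": target.target_id,
                    "umi": umi,
                    "variant_ids": ",".join(v.variant_id for v in carried),
                    "family_size": int(family_sizes[mol]),
                }
            )
            r1_clean = template[:R]
            r2_clean = umi + revcomp(template)[: R - U]
            for copy in range(int(family_sizes[mol])):
                seq1 = _add_errors(r1_clean, rng, config.per_base_error)
                seq2 = _add_errors(r2_clean, rng, config.per_base_error)
                pairs.append(
                    ReadPair(
                        f"{molecule_id}:r{copy}",
                        seq1, qual_hi * len(seq1),
                        seq2, qual_hi * len(seq2),
                    )
                )
    truth = pd.DataFrame.from_records(
        records, columns=["molecule_id", "target_id", "umi", "variant_ids", "family_size"]
    )
    return ReadSimOutput(pairs=pairs, truth_molecules=truth, truth_reads=len(pairs))


def write_fastq_pair(output: ReadSimOutput, r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for pair in output.pairs:
            f1.write(f"@{pair.read_id}\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.read_id}\n{pair.seq2}\n+\n{pair.qual2}\n")


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass
class CohortSimConfig:
    """Conditions for cohort-level simulation.

    Background mutation frequencies are zero-inflated exponential (percent
    scale). Each cancer sample boosts ``signal_variants_per_cancer`` variants
    drawn from its organ's signal pool by ``effect_size`` times the stage
    multiplier; the zero-inflation Bernoulli is shared with the background so
    ``effect_size = 1`` reduces exactly to the control distribution.
    """

    n_control: int = 60
    n_cancer: int = 60
    organ_mix: dict = field(default_factory=lambda: {o: 1 / len(ORGANS) for o in ORGANS})
    stage_mix: dict = field(default_factory=lambda: {s: 0.25 for s in STAGES})
    n_variants: int = 200
    background_zero_prob: float = 0.3
    background_mean_freq: float = 0.05  # percent
    signal_variants_per_cancer: int = 5
    shared_pool_size: int = 5  # pan-cancer hotspots (TP53-like recurrence)
    signal_pool_per_organ: int = 2  # organ-private hotspots
    effect_size: float = 20.0
    stage_gradient: dict = field(default_factory=lambda: {"I": 1.0, "II": 1.0, "III": 1.0, "IV": 1.0})
    batch: str = "automated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.n_variants < self.signal_variants_per_cancer:
            raise ValueError("n_variants must be >= signal_variants_per_cancer")
        if self.shared_pool_size + self.signal_pool_per_organ < self.signal_variants_per_cancer:
            raise ValueError("hotspot pool smaller than signal_variants_per_cancer")
        for mix in (self.organ_mix, self.stage_mix):
            total = sum(mix.values())
            if not np.isclose(total, 1.0):
                raise ValueError("mix proportions must sum to 1")


@dataclass
class CohortSimOutput:
    frequencies: pd.DataFrame  # samples x variants, percent
    labels: pd.DataFrame  # label, organ, stage, sex, batch per sample
    truth_signal: dict  # sample_id -> list of signal variant ids


def simulate_cohort(config: CohortSimConfig) -> CohortSimOutput:
    """Generate a cancer/control mutation-frequency matrix with planted signal."""
    rng = np.random.default_rng(config.seed)
    variant_ids = [f"v{i:04d}" for i in range(config.n_variants)]
    organs = list(config.organ_mix)
    organ_probs = np.array([config.organ_mix[o] for o in organs])
    stages = list(config.stage_mix)
    stage_probs = np.array([config.stage_mix[s] for s in stages])
    # hotspot structure: a shared pan-cancer pool every tumour can draw from,
    # plus a small organ-private pool, mirroring recurrent-variant panels
    perm = rng.permutation(config.n_variants)
    shared_n = min(config.shared_pool_size, config.n_variants)
    shared_pool = perm[:shared_n]
    pools = {}
    cursor = shared_n
    organ_n = config.signal_pool_per_organ
    for organ in organs:
        take = [perm[(cursor + k) % config.n_variants] for k in range(organ_n)]
        cursor += organ_n
        pools[organ] = np.concatenate([shared_pool, np.array(take, dtype=int)])

    n_total = config.n_control + config.n_cancer
    nonzero = rng.random((n_total, config.n_variants)) >= config.background_zero_prob
    magnitude = rng.exponential(config.background_mean_freq, (n_total, config.n_variants))
    values = nonzero * magnitude

    rows = []
    truth_signal: dict[str, list[str]] = {}
    sample_ids = []
    for i in range(n_total):
        is_cancer = i >= config.n_control
        sample_id = f"{'ca' if is_cancer else 'ct'}{i:04d}"
        sample_ids.append(sample_id)
        if not is_cancer:
            rows.append({"sample_id": sample_id, "label": "control", "organ": "none",
                         "stage": "not_applicable",
                         "sex": "male" if rng.random() < 0.5 else "female",
                         "batch": config.batch})
            truth_signal[sample_id] = []
            continue
        organ = organs[rng.choice(len(organs), p=organ_probs)]
        stage = stages[rng.choice(len(stages), p=stage_probs)]
        if organ == "prostate":
            sex = "male"
        elif organ == "breast":
            sex = "female"
        else:
            sex = "male" if rng.random() < 0.5 else "female"
        chosen = rng.choice(pools[organ], size=config.signal_variants_per_cancer, replace=False)
        multiplier = config.effect_size * config.stage_gradient.get(stage, 1.0)
        values[i, chosen] *= multiplier
        rows.append({"sample_id": sample_id, "label": "cancer", "organ": organ,
                     "stage": stage, "sex": sex, "batch": config.batch})
        truth_signal[sample_id] = [variant_ids[j] for j in sorted(chosen)]
    frequencies = pd.DataFrame(values, index=sample_ids, columns=variant_ids)
    frequencies.index.name = "sample_id"
    labels = pd.DataFrame(rows).set_index("sample_id")
    return CohortSimOutput(frequencies=frequencies, labels=labels, truth_signal=truth_signal)
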