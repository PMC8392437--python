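import pytest

from plasmacall.panel import Panel, TargetRegion, WhitelistVariant
from plasmacall.simulator import random_panel


@pytest.fixture(scope="session")
def toy_panel() -> Panel:
    """Two hand-built targets with three whitelist variants.

    T0: amplicon of 60 bp at chr1:100-160, primer = first 10 bp.
    T1: amplicon of 50 bp at chr2:500-550, primer = first 10 bp.
    """
    amp0 = "ACGTACGTTG" + "GATTACAGAT" + "CCCAAATTTG" + "GCGCGCGCAT" + "TGCATGCATG" + "AACCGGTTAA"
    amp1 = "TTGGCCAATT" + "AGAGAGACCC" + "TTTTTAAAAA" + "CATCATCATG" + "GTACGTACGT"
    t0 = TargetRegion("T0", "chr1", 100, 160, "+", amp0[:10], amp0)
    t1 = TargetRegion("T1", "chr2", 500, 550, "+", amp1[:10], amp1)
    variants = (
        # SNP inside T0 at local offset 15 (genomic 115): ref A
        WhitelistVariant("snp_T0", "chr1", 115, amp0[15], "T" if amp0[15] != "T" else "G", "SNP"),
        # MNP inside T0 at local 30-31 (genomic 130): GC -> TA
        WhitelistVariant("mnp_T0", "chr1", 130, amp0[30:32], "TA", "MNP"),
        # SNP inside T1 at local 25 (genomic 525): A -> C
        WhitelistVariant("snp_T1", "chr2", 525, amp1[25], "C", "SNP"),
    )
    return Panel(targets=(t0, t1), whitelist=variants)


@pytest.fixture(scope="session")
def small_random_panel() -> Panel:
    return random_panel(n_targets=4, variants_per_target=2, seed=7)
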