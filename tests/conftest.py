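import numpy as np
import pytest

from ploidyscope import synthio


@pytest.fixture(scope="session")
def sim400():
    """A 400 kb diploid simulation with the default state plan, long reads at
    30x and error-free truth alignments; shared read-only across tests."""
    gcfg = synthio.SyntheticGenomeConfig(haploid_size=400_000, seed=7)
    hap_a, hap_b, truth = synthio.generate_diploid_genome(gcfg)
    contigs, state_bed = synthio.generate_assembly(hap_a, hap_b, truth)
    rcfg = synthio.ReadSimConfig(platform="long", depth=30.0, seed=71)
    reads = synthio.simulate_reads((hap_a, hap_b), rcfg, truth=truth,
                                   with_sequences=False)
    aln = synthio.truth_align(reads, truth)
    return {
        "hap_a": hap_a, "hap_b": hap_b, "truth": truth,
        "contigs": contigs, "state_bed": state_bed,
        "reads": reads, "aln": aln,
    }


@pytest.fixture(scope="session")
def sim_paired():
    """A 300 kb simulation with three surviving copies per repeat family and
    paired short reads, for multi-site and pairing tests."""
    gcfg = synthio.SyntheticGenomeConfig(
        haploid_size=300_000, repeat_fraction=0.12, repeat_family_count=2,
        repeat_unit_len=6_000, seed=13)
    hap_a, hap_b, truth = synthio.generate_diploid_genome(gcfg)
    contigs, state_bed = synthio.generate_assembly(
        hap_a, hap_b, truth,
        state_plan={"HAP_SEP": 0.5, "COLLAPSED": 0.38, "REPEAT_UNDERREP": 0.12},
        survivors_per_family=3)
    rcfg = synthio.ReadSimConfig(platform="short_paired", depth=12.0,
                                 error_rate=0.002, seed=131)
    reads = synthio.simulate_reads((hap_a, hap_b), rcfg, truth=truth,
                                   with_sequences=False)
    aln = synthio.truth_align(reads, truth)
    return {"hap_a": hap_a, "hap_b": hap_b, "truth": truth,
            "contigs": contigs, "reads": reads, "aln": aln}
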