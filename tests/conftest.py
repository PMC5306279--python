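import numpy as np
import pytest

import srnapipe as sp


def random_genome(seed: int = 7, length: int = 2000, n_plasmids: int = 0) -> sp.Genome:
    rng = np.random.default_rng(seed)
    def seq(n):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
    replicons = [sp.Replicon("chr", seq(length), "chromosome")]
    for i in range(n_plasmids):
        replicons.append(sp.Replicon(f"p{i+1}", seq(length // 4), "plasmid"))
    return sp.Genome(replicons)


def make_unit(replicon_id="chr", strand="+", start=100, end=199, read_count=20,
              total_count=None, uid="u1", condition=""):
    length = end - start + 1
    total = total_count if total_count is not None else read_count
    return sp.TranscriptUnit(
        id=uid, replicon_id=replicon_id, strand=strand, start=start, end=end,
        read_count=min(read_count, total), total_count=total,
        representative_sequence="N" * length, condition=condition,
    )


def make_candidate(srna_class="IGR", assoc="", **unit_kwargs):
    return sp.Candidate(unit=make_unit(**unit_kwargs), srna_class=srna_class,
                        associated_feature_id=assoc)


@pytest.fixture(scope="session")
def default_config():
    return sp.ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def default_scenario(default_config):
    """The noiseless default synthetic scenario (deterministic counts, no errors)."""
    return sp.generate_scenario(default_config)


@pytest.fixture(scope="session")
def default_result(default_scenario, default_config):
    """Full pipeline run on the default scenario."""
    sc = default_scenario
    return sp.run_pipeline(sc.nl_reads, sc.hl_reads, sc.genome, sc.features,
                           default_config.adapter_3p)


@pytest.fixture(scope="session")
def default_report(default_scenario, default_result):
    res = default_result
    return sp.evaluate_against_truth(res.nl.candidates, res.hl.candidates,
                                     res.calls, default_scenario.manifest)
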