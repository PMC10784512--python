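import pytest

from poresift import quantify, simulate, synthesize


@pytest.fixture(scope="session")
def ivt_pool():
    return synthesize.make_ivt_pool()


@pytest.fixture(scope="session")
def length_ladder():
    """Deterministic depletion benchmark with targets in every length bin."""
    return synthesize.make_length_ladder()


def truth_assignment(output):
    """read_id -> (true transcript, sequenced bases) for a simulated run."""
    return {
        r.read_id: (r.true_transcript, r.sequenced_length)
        for r in output.reads
    }


def run_pools(output, q_min=7.0):
    """Count tables (bulk, accepted, rejected) for a simulated run."""
    cfg = output.config
    assignment = truth_assignment(output)
    passing = quantify.qc_filter(output.summary, q_min)
    bulk_ids, as_ids = quantify.split_by_channel(
        [r for r in output.summary if r.read_id in passing],
        cfg.as_channels, cfg.n_channels
    )
    accepted, rejected = quantify.pool_by_decision(as_ids, output.decisions)
    return (
        quantify.count_reads_bases(bulk_ids, assignment, "bulk"),
        quantify.count_reads_bases(accepted, assignment, "as_accepted"),
        quantify.count_reads_bases(rejected, assignment, "as_rejected"),
    )
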