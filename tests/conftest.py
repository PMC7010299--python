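import pytest

from retrocirc import synthetic as syn
from retrocirc.align import FragmentAligner

CONS_SEED = 7


@pytest.fixture(scope="session")
def cons():
    """Default CRM1-like consensus element (85/253/269 donor region)."""
    return syn.build_consensus(CONS_SEED)


@pytest.fixture(scope="session")
def consensus_set(cons):
    return {cons.id: cons}


@pytest.fixture(scope="session")
def aligner(consensus_set):
    return FragmentAligner(consensus_set)


@pytest.fixture(scope="session")
def templates(cons):
    return syn.make_transcripts(cons, syn.default_isoform_specs(cons))


@pytest.fixture(scope="session")
def true_junction(cons):
    return (cons.backsplice_acceptor, cons.backsplice_donor)


def template_by_id(templates, tid):
    return next(t for t in templates if t.id == tid)


# Acceptor-side extent constraints making every implied consensus
# segment at least the aligner word long (see docs/methods.md on
# identifiability of partial-retention circles).
EXT_RANGES = {
    "circ277": [(19, 10**9)],
    "circ296": [(11, 27), (38, 10**9)],
}


def ext_ranges_for(tid: str):
    for prefix, ranges in EXT_RANGES.items():
        if tid.startswith(prefix):
            return ranges
    return None
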