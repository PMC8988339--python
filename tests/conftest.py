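import logging

import pytest

from findit.calc_rp import RPConfig, calc_rp_region
from findit.fixtures import FixtureSpec, make_genome, make_signal, make_tf_world
from findit.mm_anno import mm_gene_scan


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("findit").setLevel(logging.WARNING)
    yield


@pytest.fixture(scope="session")
def world():
    """One fully-built synthetic world shared across tests (seed 0)."""
    spec = FixtureSpec(seed=0)
    genes, peaks = make_genome(spec)
    links = mm_gene_scan(peaks, genes)
    peak_signal, gene_expr = make_signal(spec, links, genes, peaks)
    tf_world = make_tf_world(spec, peaks, genes, links)
    profile = calc_rp_region(links, peak_signal, RPConfig(), genes)
    return {
        "spec": spec,
        "genes": genes,
        "peaks": peaks,
        "links": links,
        "peak_signal": peak_signal,
        "gene_expr": gene_expr,
        "tf_world": tf_world,
        "profile": profile,
    }
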