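import pytest

from pancodon import pipeline, simulate
from pancodon.cds_io import CdsRecord, RawRecord, validate_cds


def make_record(seq: str, gene_id: str = "g") -> CdsRecord:
    out = validate_cds(RawRecord(gene_id, seq))
    assert isinstance(out, CdsRecord), f"fixture CDS rejected: {out}"
    return out


@pytest.fixture(scope="session")
def gryllus_sim():
    """One AT-background recovery simulation reused across test modules."""
    cfg = simulate.preset("gryllus_like", n_genes=2000, seed=7)
    return simulate.generate_transcriptome(cfg)


@pytest.fixture(scope="session")
def gryllus_records(gryllus_sim):
    recs = [validate_cds(RawRecord(g, s)) for g, s in gryllus_sim.sequences]
    assert all(isinstance(r, CdsRecord) for r in recs)
    return recs


@pytest.fixture(scope="session")
def gryllus_report(gryllus_records, gryllus_sim):
    return pipeline.analyze_records(gryllus_records, gryllus_sim.read_counts)
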