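"""Shared fixtures: panels, tag sets and simulated datasets.

Everything is generated in memory from fixed seeds; no data files ship with
the tests.
"""

from __future__ import annotations

import pytest

import museumharvest as mh
from museumharvest.assemble import Read
from museumharvest.simulate import DegradationModel, reference_from_barcodes


@pytest.fixture(scope="session")
def ngs_panel():
    return mh.load_panel("ngs_tiled")


@pytest.fixture(scope="session")
def sanger_panel():
    return mh.load_panel("sanger2")


@pytest.fixture(scope="session")
def tagset():
    return mh.default_tagset()


@pytest.fixture(scope="session")
def noiseless_run(ngs_panel, tagset):
    """95 fresh specimens, error-free reads, assembled end to end."""
    barcodes = mh.simulate_barcodes(95, seed=7, collection_years=[2017] * 95)
    plates = mh.barcodes_to_plates(barcodes)
    reference = reference_from_barcodes(barcodes)
    model = DegradationModel(base_error_rate=0.0, indel_rate=0.0)
    readset = mh.simulate_reads(barcodes, ngs_panel, tagset, model, depth=1, seed=3)
    reads = [Read(r.id, r.sequence, r.mean_qv) for r in readset.reads]
    result = mh.run_pipeline(reads, plates[0], ngs_panel, tagset, reference)
    return {
        "barcodes": barcodes,
        "plate": plates[0],
        "reference": reference,
        "readset": readset,
        "reads": reads,
        "result": result,
    }


def as_reads(readset) -> list[Read]:
    return [Read(r.id, r.sequence, r.mean_qv) for r in readset.reads]
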