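import numpy as np
import pytest

from prioriseq.pedigree import (
    AFFECTED,
    Individual,
    ObservedGenotypes,
    Pedigree,
    UNAFFECTED,
)
from prioriseq.risk_model import VariantPanel


@pytest.fixture
def one_locus_panel():
    return VariantPanel(["rs1"], ["A"], ["G"], [0.3], [np.log(2)], "logOR")


@pytest.fixture
def trio():
    """Father, mother, one child."""
    return Pedigree(
        members=[
            Individual("dad", None, None, 1, UNAFFECTED),
            Individual("mum", None, None, 2, UNAFFECTED),
            Individual("kid", "dad", "mum", 1, AFFECTED),
        ],
        family_id="TRIO",
    )


def make_observed(ped, locus_ids, dose_by_iid):
    L = len(locus_ids)
    return ObservedGenotypes(
        locus_ids=list(locus_ids),
        dosages={
            iid: np.asarray(d, dtype=float).reshape(L)
            for iid, d in dose_by_iid.items()
        },
    )


@pytest.fixture
def observe():
    return make_observed


def random_observation(ped, truth, keep_mask, locus_ids=("L1",)):
    """Mask a complete single-locus configuration down to observed entries."""
    dos = {
        ped.ids[k]: np.array([float(truth[k])])
        for k in range(ped.n)
        if keep_mask[k]
    }
    return ObservedGenotypes(locus_ids=list(locus_ids), dosages=dos)
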