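import numpy as np
import pytest

from phenoclass.curation import ActivityRecord, CompoundEntry


def make_record(**kw) -> ActivityRecord:
    """An ActivityRecord that passes every curation filter by default."""
    base = dict(
        compound_id="C1", smiles="CC(=O)Oc1ccccc1C(=O)O", assay_id="A1",
        document_id="D1", cell_line="PC3", assay_type="MTT", incubation_h=72,
        standard_type="IC50", standard_relation="=", standard_value=10000.0,
        standard_units="nM",
    )
    base.update(kw)
    return ActivityRecord(**base)


def make_entry(compound_id="C1", pactivity=5.0, smiles="CC(=O)Oc1ccccc1C(=O)O",
               cell_line="PC3", mw=None, n_source_records=1) -> CompoundEntry:
    return CompoundEntry(compound_id=compound_id, smiles=smiles,
                         cell_line=cell_line, pactivity=pactivity, mw=mw,
                         n_source_records=n_source_records)


def entries_from_pactivities(values, prefix="C") -> list[CompoundEntry]:
    return [make_entry(compound_id=f"{prefix}{i}", pactivity=float(v))
            for i, v in enumerate(values)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
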