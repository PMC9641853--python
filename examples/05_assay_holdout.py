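"""Leave-one-assay-document-out external validation.

All compounds reported by one (synthetic) publication form the test
set; the model never sees them during training or calibration.
"""

import numpy as np

from phenoclass import assay_holdout, default_algorithms
from phenoclass.simulate import GeneratorConfig, gen_labelled_feature_data
from phenoclass.validation import eligible_documents

cfg = GeneratorConfig(n_compounds=300, n_features=10, signal_strength=1.2,
                      seed=17)
dataset, features = gen_labelled_feature_data(cfg)
rng = np.random.default_rng(0)
documents = {e.compound_id: f"DOC{rng.integers(0, 6)}"
             for e in dataset.entries}

rf = default_algorithms({"RF": {"n_estimators": [100]}})["RF"]
for doc in eligible_documents(dataset, documents, min_records=30):
    res = assay_holdout(dataset, features, documents, doc, algorithm=rf,
                        seed=0)
    r = res.report.rounded()
    print(f"{doc}: n={res.n_compounds:3d} "
          f"({res.n_active} active / {res.n_inactive} inactive)  "
          f"accuracy={r['accuracy']}  tpr={r['tpr']}  tnr={r['tnr']}")
# A rate printed as None is undefined for that document (its truth
# contains a single class, so the complementary rate has no denominator).
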