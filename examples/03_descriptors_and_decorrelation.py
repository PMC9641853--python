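"""Compute the pinned 123-descriptor block and remove correlated features.

Descriptors are computed with RDKit for a handful of drug molecules and
then filtered greedily at decreasing Pearson-correlation thresholds.
"""

from phenoclass import compute_descriptors, decorrelate
from phenoclass.simulate import load_smiles_library

names, smiles = zip(*load_smiles_library()[:60])
fm = compute_descriptors(list(smiles), list(names))
print(f"descriptor matrix: {fm.n_compounds} compounds x "
      f"{fm.n_descriptors} descriptors")

for t in (0.95, 0.85, 0.75):
    kept = decorrelate(fm, t)
    print(f"PCC <= {t:.2f}: {kept.n_descriptors:3d} descriptors retained")
# Lower thresholds remove more redundancy; every retained pair of
# descriptors correlates at most at the stated threshold.
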