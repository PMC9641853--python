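"""Filter compound-target potency records and flag disease-linked targets.

A toy association table is filtered to direct, potent, human binding
records; targets are then flagged against a prostate-cancer accession
list and summarised by how many active compounds each one binds.
"""

from phenoclass import (annotate_pca, filter_target_records,
                        target_frequency)
from phenoclass.targets import TargetAssociation

records = (
    [TargetAssociation(f"C{i}", "HDAC1", 50.0, uniprot_id="Q13547")
     for i in range(12)]
    + [TargetAssociation("C0", "HSP90", 900.0, uniprot_id="P07900"),
       TargetAssociation("C1", "HSP90", 1500.0, uniprot_id="P07900"),
       TargetAssociation("C2", "OFFT", 10.0, uniprot_id="P00001",
                         assay_class="functional"),
       TargetAssociation("STAU", "HDAC1", 1.0, uniprot_id="Q13547")]
)

kept = filter_target_records(records, exclusion_list=["STAU"])
kept = annotate_pca(kept, ["Q13547", "P07900"])
print(f"records kept after filtering: {len(kept)} of {len(records)}")

actives = [f"C{i}" for i in range(10)]
table, freq = target_frequency(kept, actives)
print(table.to_string(index=False))
print("frequency bins:", {k: round(v, 2) for k, v in freq.items()})
# Dropped records: potency > 1000 nM, non-binding assay class, or the
# promiscuous excluded compound. Counts are distinct active compounds.
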