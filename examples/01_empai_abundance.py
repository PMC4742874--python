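"""emPAI abundance from identification evidence.

Builds a three-protein inventory, filters it at the identification
score threshold (score > 54), digests each sequence in silico and
computes PAI / emPAI / relative emPAI.
"""

import pandas as pd

from spermatophore import DigestParams, compute_abundance, filter_identifications

proteome = {
    "SERPIN": "MKAVLLTFLVAAAKAADDKEEVLKSSPNAARFFGKHHEEMKAAPLLRTTVVK",
    "OBP": "MSSKLLAVFAARDDPKGGHHKEEYYRNNAAKVVMMK",
    "TRANSFERRIN": "MEEKAARLLPPKDDFFKGGSSRHHTTKAAEEVVKRNNLLK",
}
evidence = pd.DataFrame(
    {
        "protein_id": ["SERPIN", "OBP", "TRANSFERRIN"],
        "score": [310.0, 88.0, 54.0],  # 54 is *not* above the threshold
        "n_observed": [4, 2, 1],
    }
)

retained = filter_identifications(evidence, score_threshold=54.0)
print(f"retained {len(retained)}/{len(evidence)} proteins (score > 54)")

abundances = compute_abundance(retained, proteome, DigestParams(min_da=400, max_da=6000))
print(abundances[["protein_id", "n_observed", "n_observable", "pai", "empai",
                  "relative_empai"]].to_string(index=False))
print(
    "\nemPAI = 10^(observed/observable) - 1; relative emPAI is each protein's\n"
    "percent of the summed emPAI, i.e. its share of the inventory's abundance."
)
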