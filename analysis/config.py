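"""Shared configuration for the numbered analysis scripts.

A desk-scale rendition of the study design: 3 strains, a 16-substrate
nitrogen panel over a shared glucose backbone, 10-member ensembles each
trained on a random 6 growth / 3 no-growth subset, 4-replicate LFQ
proteomes across the 5 focal nitrogen treatments.  All scripts share one
output directory so later stages reuse earlier stage outputs.
"""

from pathlib import Path

from nitrofba.pipeline import RunConfig

OUTDIR = Path("results") / "pipeline"

CONFIG = RunConfig(
    seed=7,
    ensemble_size=10,
    n_pos=6,
    n_neg=3,
    n_metabolites=60,
    n_db_reactions=140,
    n_strains=3,
    n_sources=16,
    deletion_fraction=0.2,
    n_proteins=400,
    n_replicates=4,
)
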