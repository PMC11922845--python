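"""Published transcriptome SNP summary counts for the seven-conifer study
system.

These are the per-species summary count columns for the seven North American
conifer transcriptome datasets the package is designed around (white and
black spruce, jack and eastern white pine, balsam fir, tamarack, eastern
white cedar).  The derived columns — mean SNPs per polymorphic transcript
and proportion of polymorphic transcripts, both after length/depth
adjustment — are NOT stored; they are recomputed from these counts by
:func:`coniferdiv.diversity.summarize_from_counts` in the worked example and
the reproduction script.
"""

from __future__ import annotations

import pandas as pd

# diversity group labels reflect the three-way partition recovered from the
# adjusted per-transcript SNP distributions (highest / intermediate / lowest)
CONIFER_SNP_COUNTS = pd.DataFrame(
    [
        ("Picea glauca",      "highest",      18060, 105778, 100128, 16581),
        ("Picea mariana",     "highest",      20534, 114771, 108019, 18558),
        ("Pinus banksiana",   "intermediate", 19510,  90985,  87011, 16441),
        ("Abies balsamea",    "intermediate", 19487,  91311,  86564, 16521),
        ("Larix laricina",    "intermediate", 20950,  94359,  89877, 16935),
        ("Pinus strobus",     "lowest",       21795,  71576,  69867, 15412),
        ("Thuja occidentalis","lowest",       19543,  64872,  62749, 13834),
    ],
    columns=[
        "species", "diversity_group", "n_transcripts", "n_snps_raw",
        "n_snps_adjusted", "n_transcripts_with_snps_adjusted",
    ],
)

#: published per-species mean adjusted SNPs per polymorphic transcript,
#: used as the default magnitudes the synthetic generator emulates
SPECIES_MEAN_SNPS = (6.0, 5.8, 5.3, 5.2, 5.3, 4.5, 4.5)

#: the three-group diversity partition (species indices into the table rows)
DIVERSITY_GROUPS = ({0, 1}, {2, 3, 4}, {5, 6})
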