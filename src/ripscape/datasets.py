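"""Published reference statistics used as inputs to the grouping rule.

``FUNGAL_GENOME_TABLE`` holds, for twelve well-assembled fungal genomes,
the published mean +/- SD of 500 bp-window GC content and the number of
long (>= 3 kb) AT-rich blocks, together with the architecture group each
genome belongs to: Group I (filamentous ascomycetes with many long
AT-rich blocks and biphasic local AT content), Group II (basidiomycetes
with similar average GC but almost no long blocks), Group III (strongly
AT-rich hemiascomycete yeasts).  These printed values are inputs for
:func:`ripscape.atblocks.classify_genome_group`, not something this
package recomputes.
"""

from __future__ import annotations

import pandas as pd

FUNGAL_GENOME_TABLE = pd.DataFrame(
    [
        # species, genome (Mb), chromosomes, GC mean, GC sd, long blocks, group
        ("Trichoderma reesei", 34.9, 7, 51.1, 11.6, 167, "I"),
        ("Neurospora crassa", 41.1, 7, 48.3, 10.0, 345, "I"),
        ("Fusarium fujikuroi", 43.8, 12, 47.5, 7.3, 128, "I"),
        ("Mycosphaerella graminicola", 39.7, 21, 52.1, 5.5, 570, "I"),
        ("Penicillium chrysogenum", 32.5, 4, 49.0, 5.3, 84, "I"),
        ("Aspergillus nidulans", 29.8, 8, 50.4, 4.5, 59, "I"),
        ("Ustilago maydis", 19.7, 23, 54.0, 3.8, 1, "II"),
        ("Cryptococcus neoformans", 19.1, 14, 51.7, 4.3, 0, "II"),
        ("Coprinopsis cinerea", 36.2, 13, 48.5, 3.6, 7, "II"),
        ("Saccharomyces cerevisiae", 12.2, 16, 38.3, 4.1, 0, "III"),
        ("Schizosaccharomyces pombe", 12.6, 3, 36.1, 4.8, 6, "III"),
        ("Candida glabrata", 12.3, 13, 38.6, 5.8, 18, "III"),
    ],
    columns=[
        "species", "genome_mb", "n_chromosomes", "gc_mean", "gc_sd",
        "long_blocks", "group",
    ],
)
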