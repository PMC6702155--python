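"""Reference constants of the harmonized global soil 16S dataset.

The pipeline targets the meta-analysis that merged the EMBL, EMP and
ZHOU soil 16S rRNA surveys: 844 valid samples aggregated into 320
representative 0.1-degree sites, with 256,620 unique ASVs before
filtering.  The per-continent site census below is used for
bookkeeping sanity checks of the aggregation stage.
"""

from __future__ import annotations

#: representative 0.1-degree sites per continent after aggregation
SITES_BY_CONTINENT = {
    "AF": 27,
    "AS": 42,
    "AU": 30,
    "EU": 55,
    "NA": 104,
    "SA": 62,
}

#: total representative sites (the continental census must sum to this)
TOTAL_SITES = 320

#: valid samples before 0.1-degree aggregation
TOTAL_SAMPLES = 844

#: unique ASVs detected across all samples before filtering
TOTAL_ASVS = 256_620

#: realized rarefaction depth of the source analysis (grid 2,500-15,000)
DEFAULT_RAREFACTION_DEPTH = 7_500
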