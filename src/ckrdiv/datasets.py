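"""Published inputs for the chemokine-receptor divergence comparisons.

The ten two-group comparisons (traditional CKRs against five decoy-receptor
groups and five viral-receptor groups) were reported with, per comparison,
the number of top-5% KL sites mapped onto CXCR4 and how many of those fall
in the CASTp ligand-binding pocket.  Those printed counts are inputs to the
pocket-enrichment analysis; the region definitions for CXCR4/3ODU chain A
ship as a packaged YAML config.
"""

from __future__ import annotations

from importlib import resources

from .structure import RegionConfig

DECOY_GROUPS = ("CCRL1", "CCRL2", "CCBP2", "CXCR7", "DARC")
VIRAL_GROUPS = ("E1", "ORF74", "UL33", "betaHV", "pox")

#: selected sites per comparison (rows of the published per-group site lists)
SELECTED_SITE_TOTALS = {
    "CCRL1": 14, "CCRL2": 13, "CCBP2": 11, "CXCR7": 14, "DARC": 14,
    "E1": 9, "ORF74": 13, "UL33": 14, "betaHV": 11, "pox": 14,
}

#: of those, sites lying in the CXCR4 ligand-binding pocket
POCKET_SITE_COUNTS = {
    "CCRL1": 2, "CCRL2": 2, "CCBP2": 0, "CXCR7": 1, "DARC": 1,
    "E1": 3, "ORF74": 2, "UL33": 5, "betaHV": 3, "pox": 4,
}


def pocket_ratio_inputs():
    """(decoy counts, decoy totals, viral counts, viral totals), group order fixed."""
    return (
        [POCKET_SITE_COUNTS[g] for g in DECOY_GROUPS],
        [SELECTED_SITE_TOTALS[g] for g in DECOY_GROUPS],
        [POCKET_SITE_COUNTS[g] for g in VIRAL_GROUPS],
        [SELECTED_SITE_TOTALS[g] for g in VIRAL_GROUPS],
    )


def cxcr4_region_config() -> RegionConfig:
    """Packaged region definitions for CXCR4 on 3ODU chain A."""
    ref = resources.files("ckrdiv.data").joinpath("cxcr4_regions.yaml")
    with resources.as_file(ref) as path:
        return RegionConfig.from_yaml(path)
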