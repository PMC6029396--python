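"""Sequential-ChIP (reChIP) validation statistics.

reChIP enriches chromatin carrying both assayed marks simultaneously, so a
genuine bivalent domain shows elevated reChIP density at co-marked regions
relative to an input control, while single-mark regions stay at background.
The module contrasts reChIP vs input RPKM distributions per region class and
measures the overlap of co-marked regions with reChIP peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccupancy import overlap_fraction
from .core_io import RegionSet, TagCollection
from .quantify import five_number_summary, region_density
from .stats import KsResult, ks_two_sample


@dataclass
class RechipReport:
    """Per-region-set reChIP/input density summaries and KS contrasts."""

    summaries: dict[str, dict[str, dict[str, float]]]  # set -> track -> summary
    densities: dict[str, dict[str, np.ndarray]]        # set -> track -> RPKM sample
    ks: dict[str, KsResult]                            # set -> reChIP-vs-input KS


def rechip_contrast(rechip_tags: TagCollection, input_tags: TagCollection,
                    region_sets: dict[str, RegionSet]) -> RechipReport:
    """Contrast reChIP against input density at each region class.

    ``region_sets`` should include the co-marked set and the two single-mark
    ("only") sets from co-occupancy classification. No input subtraction is
    performed; the tracks are compared side by side.
    """
    summaries, densities, ks = {}, {}, {}
    for name, rs in region_sets.items():
        if len(rs) == 0:
            raise ValueError(f"region set {name!r} is empty")
        d_re = region_density(rechip_tags, rs)["rpkm"].to_numpy()
        d_in = region_density(input_tags, rs)["rpkm"].to_numpy()
        summaries[name] = {
            "rechip": {"n": len(rs), **five_number_summary(d_re)},
            "input": {"n": len(rs), **five_number_summary(d_in)},
        }
        densities[name] = {"rechip": d_re, "input": d_in}
        ks[name] = ks_two_sample(d_re, d_in)
    return RechipReport(summaries=summaries, densities=densities, ks=ks)


def rechip_peak_overlap(co_regions: RegionSet, rechip_islands: RegionSet) -> float:
    """Percent of co-occupied regions overlapping >= 1 reChIP island."""
    if len(co_regions) == 0:
        raise ValueError("co_regions is empty")
    if len(rechip_islands) == 0:
        return 0.0
    return 100.0 * overlap_fraction(co_regions, rechip_islands)
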