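"""Shared fixtures: hand-built genealogies with known event traces."""

import pytest

from protrax.simulate import Genealogy, LineageRecord, ProtractedParams


def _lineage(lid, parent, origin, end, fate, species, conversion=None, founder=False, side=0):
    lin = LineageRecord(lid, parent, origin, species_id=species, species_founder=founder, crown_side=side)
    lin.end_time = end
    lin.fate = fate
    lin.conversion_time = conversion
    return lin


@pytest.fixture
def three_species_genealogy():
    """Genealogy with three extant species, one represented by two populations.

    Timeline (duration 6):
      L0 crown good founder of species 0, extant
      L1 crown incipient, converts at t=2 -> founds species 1, extant
      L2 daughter of L0 at t=1, incipient species 0, extant
         (species 0 survives through L0 and L2)
      L3 daughter of L1 at t=3 (after L1's conversion), converts at t=4
         -> founds species 2, extant
      L4 daughter of L3 at t=4.5, incipient species 2, extant
         (species 2 has two populations)
      L5 daughter of L0 at t=2, incipient species 0, extirpated at t=5
    """
    params = ProtractedParams.symmetric(0.5, 0.3, 0.2, 6.0)
    lineages = [
        _lineage(0, None, 0.0, 6.0, "extant", 0, founder=True, side=0),
        _lineage(1, None, 0.0, 6.0, "extant", 1, conversion=2.0, founder=True, side=1),
        _lineage(2, 0, 1.0, 6.0, "extant", 0, side=0),
        _lineage(3, 1, 3.0, 6.0, "extant", 2, conversion=4.0, founder=True, side=1),
        _lineage(4, 3, 4.5, 6.0, "extant", 2, side=1),
        _lineage(5, 0, 2.0, 5.0, "extirpated", 0, side=0),
    ]
    return Genealogy(params=params, lineages=lineages, seed=None, conditioning="none")


@pytest.fixture
def root_extinct_genealogy():
    """Root species fully extirpated; two converted species survive.

    L0 (good, species 0) dies at t=3; L1 converts at t=1 (species 1);
    L2, daughter of L0 at t=0.5, converts at t=2 (species 2).  Extant
    lineages are L1 and L2, so richness is 2 and species 0 is gone.
    """
    params = ProtractedParams.symmetric(0.5, 0.3, 0.2, 6.0)
    lineages = [
        _lineage(0, None, 0.0, 3.0, "extirpated", 0, founder=True, side=0),
        _lineage(1, None, 0.0, 6.0, "extant", 1, conversion=1.0, founder=True, side=1),
        _lineage(2, 0, 0.5, 6.0, "extant", 2, conversion=2.0, founder=True, side=0),
    ]
    return Genealogy(params=params, lineages=lineages, seed=None, conditioning="none")
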