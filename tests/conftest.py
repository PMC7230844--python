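import pytest

from ssrbank.core import Fingerprint, Layer, LocusGenotype, MarkerDef


def fp(entity_id, genotypes, layer=Layer.EXPERIMENT, weight=1.0, name="", synonyms=()):
    """Build a fingerprint from {marker: (low, high) | None} shorthand."""
    g = {
        m: LocusGenotype(m) if v is None else LocusGenotype(m, float(min(v)), float(max(v)))
        for m, v in genotypes.items()
    }
    return Fingerprint(entity_id, layer, g, weight=weight,
                       name=name or entity_id, synonyms=tuple(synonyms))


@pytest.fixture
def panel3():
    return [
        MarkerDef("M1", "P1", 2, 90.0, 130.0),
        MarkerDef("M2", "P1", 2, 140.0, 180.0),
        MarkerDef("M3", "P1", 2, 190.0, 240.0),
    ]


@pytest.fixture
def trio(panel3):
    """Three small fingerprints on the 3-marker panel."""
    a = fp("A", {"M1": (100, 102), "M2": (150, 150), "M3": (200, 204)})
    b = fp("B", {"M1": (100, 102), "M2": (150, 152), "M3": (200, 204)})
    c = fp("C", {"M1": (110, 112), "M2": (160, 162), "M3": (220, 224)})
    return [a, b, c]
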