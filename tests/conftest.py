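import pytest

from gmomatrix.model import ElementDescriptor, GmoEvent, ScreeningMatrix, TriState

P, A, U = TriState.PRESENT, TriState.ABSENT, TriState.UNKNOWN


def make_matrix(elements, rows, version=""):
    """Compact matrix builder: elements as (name, section), rows as
    (trade, uid, crop, type, status, {element: TriState})."""
    els = [ElementDescriptor(n, s) for n, s in elements]
    evs = [
        GmoEvent(trade_name=t, unique_id=u, crop_species=c, event_type=ty,
                 eu_status=st, profile=prof)
        for t, u, c, ty, st, prof in rows
    ]
    return ScreeningMatrix(elements=els, events=evs, version_tag=version)


@pytest.fixture
def small_matrix():
    """Six hand-built events over five GM elements and one endogenous target.

    Profiles chosen so that AND/OR queries, comparison, coverage and mixture
    splitting all have hand-checkable answers.
    """
    elements = [
        ("p35S", "promoter"), ("pFMV", "promoter"),
        ("tNOS", "terminator"),
        ("pat", "orf"), ("bar", "orf"),
        ("zSSIIb", "endogenous"),
    ]
    rows = [
        ("EvA", "AAA-00001-1", "maize", "single", "authorized",
         {"p35S": P, "pFMV": A, "tNOS": P, "pat": P, "bar": A, "zSSIIb": P}),
        ("EvB", "BBB-00002-2", "maize", "single", "not_authorized",
         {"p35S": P, "pFMV": A, "tNOS": A, "pat": A, "bar": P, "zSSIIb": P}),
        ("EvC", "CCC-00003-3", "maize", "single", "authorized",
         {"p35S": A, "pFMV": P, "tNOS": A, "pat": A, "bar": A, "zSSIIb": P}),
        ("EvD", "DDD-00004-4", "soybean", "single", "authorized",
         {"p35S": P, "pFMV": P, "tNOS": P, "pat": A, "bar": A, "zSSIIb": A}),
        ("EvStack", "EEE-00005-5", "maize", "stacked", "not_authorized",
         {"p35S": P, "pFMV": A, "tNOS": P, "pat": P, "bar": P, "zSSIIb": P}),
        ("EvU", "FFF-00006-6", "soybean", "single", "llp_619_2011",
         {"p35S": U, "pFMV": A, "tNOS": P, "pat": A, "bar": A, "zSSIIb": A}),
    ]
    return make_matrix(elements, rows, version="test-1")
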