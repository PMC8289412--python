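import pytest

import alkrepair as ak


@pytest.fixture(scope="session")
def mnu():
    return ak.spectrum_for_agent("MNU")


@pytest.fixture(scope="session")
def mms():
    return ak.spectrum_for_agent("MMS")


@pytest.fixture(scope="session")
def pbr322():
    return ak.BUILTIN_PLASMIDS["pBR322"]


@pytest.fixture(scope="session")
def pel97():
    return ak.BUILTIN_PLASMIDS["pEL97"]


@pytest.fixture(scope="session")
def ratio10_spectrum():
    """Spectrum with an exact N-alkyl : O6mG ratio of 10."""
    return ak.AdductSpectrum("ratio10", 0.75, 0.075, 0.0825, 0.0925)


@pytest.fixture(scope="session")
def calibrated_params(pel97, mnu):
    """p_nick_open calibrated so the 2 mM / pEL97 linear fraction is 6%."""
    p = ak.calibrate_nick_availability(0.06, pel97, 1 / 250, mnu, ak.RepairParams())
    return ak.RepairParams(p_nick_open=p)


def oracle_dsb_count(event_set: ak.RepairEventSet, params: ak.RepairParams) -> int:
    """Brute-force per-nucleotide DSB oracle, independent of detect_dsb.

    Scans every strand-nucleotide of each open gap for an open nick on the
    opposite strand; one DSB per such gap.  Nick/nick DSBs enumerated
    pairwise.
    """
    L = event_set.plasmid.length_bp
    nick_sets = [set(), set()]
    for e in event_set.events:
        if e.kind == "BER_nick" and e.open:
            nick_sets[e.strand].add(e.start % L)
    count = 0
    for e in event_set.events:
        if e.kind != "MMR_gap" or not e.open:
            continue
        opposite = nick_sets[1 - e.strand]
        hit = False
        for k in range(min(e.length, L)):
            if (e.start + k) % L in opposite:
                hit = True
                break
        count += int(hit)
    if params.nick_nick_dsb_threshold > 0:
        for p in nick_sets[0]:
            for q in nick_sets[1]:
                d = abs(p - q) % L
                if min(d, L - d) <= params.nick_nick_dsb_threshold:
                    count += 1
    return count


@pytest.fixture(scope="session")
def dsb_oracle():
    return oracle_dsb_count
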