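"""Monte Carlo engine for BER/MMR crosstalk on single plasmid molecules.

Implements the two-hit double-strand-break mechanism: BER initiates nicks
at N-alkyl adducts, MMR excises several-hundred-nt tracks at O6mG:C sites,
and a DSB is called when an open MMR gap reaches an open BER nick on the
opposite strand.  The model is a *snapshot*: instead of time-resolved
kinetics, every potential event is sampled as simultaneously open with a
stated probability, matching end-point gel readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .lesions import (
    ADDUCT_3MA,
    ADDUCT_7MG,
    ADDUCT_O6MG,
    AdductSpectrum,
    LesionMap,
    PlasmidSpec,
    expected_counts,
    _sample_lesion_arrays,
)

TOPOLOGY_CCC = "ccc"
TOPOLOGY_OC = "oc"
TOPOLOGY_LINEAR = "linear"


@dataclass(frozen=True)
class RepairParams:
    """Snapshot probabilities and geometry of the two repair pathways.

    Notes
    -----
    ``p_engage_base`` defaults to the *effective* MMR engagement of an
    O6mG:C site in the presence of N-alkyl adducts (the ~30% inferred from
    the mGC/mGT comparison, measured on MMS-co-treated constructs).  The
    ``stimulation_factor`` multiplier is therefore only applied when
    ``apply_stimulation`` is True, which models the single-O6mG
    reconstitution scenario (unstimulated base engagement x fold-change
    when a BER nick lies within ``stimulation_window``); applying both to
    the default base value would double-count the stimulation.

    ``p_nick_open`` defaults to 0.015, the value obtained by calibrating
    the analytic DSB fraction to a 6% linear fraction for an 11.3 kb
    plasmid at one N-alkyl adduct per 250 nt (see
    :func:`calibrate_nick_availability`).
    """

    p_engage_base: float = 0.30
    stimulation_factor: float = 2.9
    stimulation_window: int = 1000
    apply_stimulation: bool = False
    track_length: int = 500
    track_length_model: str = "fixed"  # or "exponential"
    track_placement: str = "uniform_cover"  # or "centered"
    p_nick_open: float = 0.015
    p_mmr_gap_open: float = 0.75
    ber_long_patch_fraction: float = 0.4
    ber_long_patch_mean: float = 5.0
    nick_nick_dsb_threshold: int = 0  # 0 disables direct nick/nick DSBs

    def __post_init__(self) -> None:
        for name in ("p_engage_base", "p_nick_open", "p_mmr_gap_open",
                     "ber_long_patch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.stimulation_factor < 1.0:
            raise ValueError("stimulation_factor must be >= 1")
        if self.track_length <= 0 or self.stimulation_window <= 0:
            raise ValueError("lengths must be positive")
        if self.ber_long_patch_mean <= 0:
            raise ValueError("ber_long_patch_mean must be positive")
        if self.track_length_model not in ("fixed", "exponential"):
            raise ValueError(f"unknown track_length_model {self.track_length_model!r}")
        if self.track_placement not in ("uniform_cover", "centered"):
            raise ValueError(f"unknown track_placement {self.track_placement!r}")
        if self.nick_nick_dsb_threshold < 0:
            raise ValueError("nick_nick_dsb_threshold must be >= 0")


#: Experimental-condition presets: depletions/supplements as parameter maps.
PARAM_PRESETS = {
    "mlh1_depleted": {"p_engage_base": 0.0},
    "pms2_depleted": {"p_engage_base": 0.0},
    "aag_deficient_hss": {"p_nick_open": 0.0, "ber_long_patch_fraction": 0.0},
}


def apply_preset(params: RepairParams, preset: str) -> RepairParams:
    if preset not in PARAM_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; known: {sorted(PARAM_PRESETS)}")
    return replace(params, **PARAM_PRESETS[preset])


@dataclass(frozen=True)
class RepairEvent:
    """One repair event active (or completed) at the snapshot.

    ``interval`` is a circular half-open interval (start, length); length 0
    denotes a pure nick (open-nick geometry).  ``synthesis_nt`` is the
    resynthesis tally when the event completes.
    """

    kind: str  # "BER_nick" | "MMR_gap"
    strand: int
    start: int
    length: int
    synthesis_nt: int
    open: bool
    origin_lesion: int


@dataclass
class RepairEventSet:
    plasmid: PlasmidSpec
    events: list = field(default_factory=list)

    def open_nicks(self, strand: int) -> np.ndarray:
        return np.array(
            [e.start for e in self.events
             if e.kind == "BER_nick" and e.open and e.strand == strand],
            dtype=np.int64,
        )

    def open_gaps(self) -> list:
        return [e for e in self.events if e.kind == "MMR_gap" and e.open]


@dataclass(frozen=True)
class PlasmidOutcome:
    topology: str
    dsb_count: int
    open_nicks_top: int
    open_nicks_bottom: int
    open_gaps: int
    synthesized_nt: int
    o6mg_attributed_nt: int


@dataclass(frozen=True)
class BatchSummary:
    n_molecules: int
    frac_ccc: float
    frac_oc: float
    frac_linear: float
    se_ccc: float
    se_oc: float
    se_linear: float
    n_ccc: int
    n_oc: int
    n_linear: int
    mean_synthesized_nt: float
    mean_o6mg_attributed_nt: float
    uds_percent_replication: float


def classify_topology(dsb_count: int, open_nick_or_gap_count: int) -> str:
    """Topology class: linear iff >=1 DSB, else oc iff >=1 open nick/gap."""
    if dsb_count >= 1:
        return TOPOLOGY_LINEAR
    if open_nick_or_gap_count >= 1:
        return TOPOLOGY_OC
    return TOPOLOGY_CCC


def _circ_contains(start: int, length: int, pos: np.ndarray, L: int) -> np.ndarray:
    return (pos - start) % L < length


def _circ_distance(a: np.ndarray, b: int, L: int) -> np.ndarray:
    d = np.abs(a - b) % L
    return np.minimum(d, L - d)


def _repair_kernel(
    rng: np.random.Generator,
    L: int,
    positions: np.ndarray,
    strands: np.ndarray,
    classes: np.ndarray,
    params: RepairParams,
):
    """Sample one repair snapshot for one molecule.

    Draw order is fixed (nick openness, patch sizes, engagement, gap
    strand/length/offset/openness) so that seeded runs are bit-stable.
    """
    nal = (classes == ADDUCT_7MG) | (classes == ADDUCT_3MA)
    nal_pos = positions[nal]
    nal_strand = strands[nal]
    n_nal = nal_pos.size

    nick_open = rng.random(n_nal) < params.p_nick_open
    long_patch = rng.random(n_nal) < params.ber_long_patch_fraction
    # long patches are 2-8 nt (mean ber_long_patch_mean when symmetric)
    lo = max(2, int(round(2 * params.ber_long_patch_mean)) - 8)
    hi = int(round(2 * params.ber_long_patch_mean)) - lo
    patch = np.where(long_patch, rng.integers(lo, hi + 1, size=n_nal), 1)

    o6_idx = np.flatnonzero(classes == ADDUCT_O6MG)
    o6_pos = positions[o6_idx]
    n_o6 = o6_pos.size

    if params.apply_stimulation and n_o6:
        half = params.stimulation_window // 2
        open_nick_pos = nal_pos[nick_open]
        has_near = np.array(
            [
                open_nick_pos.size > 0
                and bool((_circ_distance(open_nick_pos, int(p), L) <= half).any())
                for p in o6_pos
            ]
        )
        p_eng = np.where(
            has_near,
            min(1.0, params.p_engage_base * params.stimulation_factor),
            params.p_engage_base,
        )
    else:
        p_eng = np.full(n_o6, params.p_engage_base)
    engaged = rng.random(n_o6) < p_eng

    eng_pos = o6_pos[engaged]
    n_eng = eng_pos.size
    gap_strand = rng.integers(0, 2, size=n_eng).astype(np.int8)
    if params.track_length_model == "exponential":
        gap_len = np.maximum(1, np.rint(rng.exponential(params.track_length, n_eng)))
    else:
        gap_len = np.full(n_eng, params.track_length, dtype=np.int64)
    gap_len = np.minimum(gap_len.astype(np.int64), L)
    if params.track_placement == "centered":
        gap_start = (eng_pos - gap_len // 2) % L
    else:  # uniform among covering positions
        offset = (rng.random(n_eng) * gap_len).astype(np.int64)
        gap_start = (eng_pos - offset) % L
    gap_open = rng.random(n_eng) < params.p_mmr_gap_open

    # DSB: open gap whose interval contains an open nick on the opposite strand
    dsb_count = 0
    dsb_gap_idx = []
    for j in range(n_eng):
        if not gap_open[j]:
            continue
        opp = 1 - gap_strand[j]
        nicks = nal_pos[nick_open & (nal_strand == opp)]
        if nicks.size and _circ_contains(int(gap_start[j]), int(gap_len[j]), nicks, L).any():
            dsb_count += 1
            dsb_gap_idx.append(j)

    if params.nick_nick_dsb_threshold > 0:
        top = nal_pos[nick_open & (nal_strand == 0)]
        bot = nal_pos[nick_open & (nal_strand == 1)]
        for p in top:
            dsb_count += int(
                (_circ_distance(bot, int(p), L) <= params.nick_nick_dsb_threshold).sum()
            )

    synth_ber = int(patch.sum())
    synth_mmr = int(gap_len.sum())
    open_nicks_top = int((nick_open & (nal_strand == 0)).sum())
    open_nicks_bottom = int((nick_open & (nal_strand == 1)).sum())
    open_gap_count = int(gap_open.sum())
    topology = classify_topology(
        dsb_count, open_nicks_top + open_nicks_bottom + open_gap_count
    )
    outcome = PlasmidOutcome(
        topology=topology,
        dsb_count=dsb_count,
        open_nicks_top=open_nicks_top,
        open_nicks_bottom=open_nicks_bottom,
        open_gaps=open_gap_count,
        synthesized_nt=synth_ber + synth_mmr,
        o6mg_attributed_nt=synth_mmr,
    )
    detail = {
        "nal_idx": np.flatnonzero(nal),
        "nal_pos": nal_pos,
        "nal_strand": nal_strand,
        "nick_open": nick_open,
        "patch": patch,
        "o6_idx": o6_idx,
        "engaged": engaged,
        "gap_strand": gap_strand,
        "gap_start": gap_start,
        "gap_len": gap_len,
        "gap_open": gap_open,
        "dsb_gap_idx": dsb_gap_idx,
    }
    return outcome, detail


def simulate_repair(
    lesion_map: LesionMap,
    params: RepairParams,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> tuple[RepairEventSet, PlasmidOutcome]:
    """Sample one repair snapshot on one molecule.

    Every N-alkyl lesion contributes completed-BER synthesis (1 nt short
    patch or a 2-8 nt long patch) and independently carries an open nick
    with ``p_nick_open``; each O6mG engages MMR with the effective
    engagement probability, creating an excision-track interval on a
    uniformly chosen strand that covers the O6mG, open as a gap with
    ``p_mmr_gap_open``.  DSBs are called per :func:`detect_dsb` and the
    outcome classified per :func:`classify_topology`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = lesion_map.plasmid.length_bp
    outcome, d = _repair_kernel(
        rng, L, lesion_map.positions, lesion_map.strands, lesion_map.classes, params
    )
    events = []
    for i in range(d["nal_pos"].size):
        events.append(
            RepairEvent(
                kind="BER_nick",
                strand=int(d["nal_strand"][i]),
                start=int(d["nal_pos"][i]),
                length=0 if d["nick_open"][i] else int(d["patch"][i]),
                synthesis_nt=int(d["patch"][i]),
                open=bool(d["nick_open"][i]),
                origin_lesion=int(d["nal_idx"][i]),
            )
        )
    eng_origin = d["o6_idx"][d["engaged"]]
    for j in range(d["gap_start"].size):
        events.append(
            RepairEvent(
                kind="MMR_gap",
                strand=int(d["gap_strand"][j]),
                start=int(d["gap_start"][j]),
                length=int(d["gap_len"][j]),
                synthesis_nt=int(d["gap_len"][j]),
                open=bool(d["gap_open"][j]),
                origin_lesion=int(eng_origin[j]),
            )
        )
    return RepairEventSet(lesion_map.plasmid, events), outcome


@dataclass(frozen=True)
class DsbCalls:
    count: int
    positions: tuple  # gap start positions of DSB-causing gaps


def detect_dsb(events: RepairEventSet, params: RepairParams) -> DsbCalls:
    """Call DSBs on one molecule's event set.

    One DSB per open MMR gap whose circular interval contains at least one
    open nick on the opposite strand (regardless of nick multiplicity).
    If ``nick_nick_dsb_threshold`` > 0, two open nicks on opposite strands
    within that distance also call a DSB.
    """
    L = events.plasmid.length_bp
    count = 0
    positions = []
    for gap in events.open_gaps():
        nicks = events.open_nicks(1 - gap.strand)
        if nicks.size and _circ_contains(gap.start, gap.length, nicks, L).any():
            count += 1
            positions.append(gap.start)
    if params.nick_nick_dsb_threshold > 0:
        top = events.open_nicks(0)
        bot = events.open_nicks(1)
        for p in top:
            close = _circ_distance(bot, int(p), L) <= params.nick_nick_dsb_threshold
            count += int(close.sum())
            positions.extend(int(p) for _ in range(int(close.sum())))
    return DsbCalls(count, tuple(positions))


def uds_signal(
    outcomes: Sequence[PlasmidOutcome],
    plasmid: PlasmidSpec,
    attr: str = "synthesized_nt",
) -> float:
    """Repair synthesis as percent of one full replication round (2L nt)."""
    if len(outcomes) == 0:
        raise ValueError("empty outcome batch")
    mean_synth = float(np.mean([getattr(o, attr) for o in outcomes]))
    return 100.0 * mean_synth / (2.0 * plasmid.length_bp)


def labeled_synthesis_nt(events: RepairEventSet, lesion_map: LesionMap) -> int:
    """Synthesis visible to the dATP label.

    Short-patch (1 nt) BER at 7mG incorporates no labelled A (a C goes in
    opposite the G) and is invisible; all longer patches and MMR tracks
    count in full.  This is a reporting mode only — the default UDS
    arithmetic counts all synthesis.
    """
    total = 0
    for e in events.events:
        if (
            e.kind == "BER_nick"
            and e.synthesis_nt == 1
            and lesion_map.classes[e.origin_lesion] == ADDUCT_7MG
        ):
            continue
        total += e.synthesis_nt
    return total


@dataclass(frozen=True)
class FragmentActivity:
    start: int
    length: int
    signal_nt: float
    specific_activity: float


def fragment_specific_activity(
    event_sets: Sequence[RepairEventSet], cut_positions: Sequence[int]
) -> list[FragmentActivity]:
    """Apportion repair-synthesis signal to restriction fragments.

    Fragments are computed between sorted cut positions on the circle; each
    event's ``synthesis_nt`` is apportioned pro rata of the circular overlap
    of its interval with each fragment.  Specific activity is signal per
    fragment length.
    """
    cuts = sorted(int(c) for c in cut_positions)
    if len(cuts) < 2:
        raise ValueError("need at least 2 cut positions on the circle")
    if len(set(cuts)) != len(cuts):
        raise ValueError("duplicate cut positions")
    if not event_sets:
        raise ValueError("empty event-set batch")
    L = event_sets[0].plasmid.length_bp
    frag_bounds = []
    for i, c in enumerate(cuts):
        nxt = cuts[(i + 1) % len(cuts)]
        length = (nxt - c) % L
        if length == 0:
            length = L
        frag_bounds.append((c, length))
    signals = np.zeros(len(frag_bounds))
    for es in event_sets:
        if es.plasmid.length_bp != L:
            raise ValueError("all event sets must share one plasmid")
        for e in es.events:
            ivl_len = max(e.length, 1) if e.synthesis_nt > 0 else 0
            if ivl_len == 0:
                continue
            for k, (fs, fl) in enumerate(frag_bounds):
                ov = _circular_overlap(e.start, ivl_len, fs, fl, L)
                if ov:
                    signals[k] += e.synthesis_nt * ov / ivl_len
    return [
        FragmentActivity(fs, fl, float(sig), float(sig) / fl)
        for (fs, fl), sig in zip(frag_bounds, signals)
    ]


def _circular_overlap(a_start: int, a_len: int, b_start: int, b_len: int, L: int) -> int:
    """Overlap length of two circular half-open intervals on a circle of size L."""
    # shift coordinates so b starts at 0; a may wrap into <=2 linear parts
    a_len = min(a_len, L)
    a0 = (a_start - b_start) % L
    parts = [(a0, min(a_len, L - a0))]
    rem = a_len - (L - a0)
    if rem > 0:
        parts.append((0, rem))
    total = 0
    for s, ln in parts:
        total += max(0, min(s + ln, b_len) - s)
    return total


def analytic_dsb_fraction(
    plasmid: PlasmidSpec,
    nalkyl_density: float,
    spectrum: AdductSpectrum,
    params: RepairParams,
) -> float:
    """Closed-form expected linear fraction in the rare-event regime.

    E[O6mG per plasmid] x p_engage_effective x p_mmr_gap_open x
    (1 - exp(-track_length x density x p_nick_open)), capped at 1.
    Results above 0.2 are outside the rare-event regime where the
    expected-count = probability identification holds.
    """
    exp = expected_counts(plasmid, nalkyl_density, spectrum)
    if params.apply_stimulation:
        # chance of >=1 open nick within the centered window (both strands)
        lam = 2 * params.stimulation_window * nalkyl_density * params.p_nick_open
        p_near = 1.0 - math.exp(-lam)
        p_eng = (
            params.p_engage_base * (1 - p_near)
            + min(1.0, params.p_engage_base * params.stimulation_factor) * p_near
        )
    else:
        p_eng = params.p_engage_base
    track = min(params.track_length, plasmid.length_bp)
    p_hit = 1.0 - math.exp(-track * nalkyl_density * params.p_nick_open)
    return min(1.0, exp.n_o6mg * p_eng * params.p_mmr_gap_open * p_hit)


def calibrate_nick_availability(
    target_linear_fraction: float,
    plasmid: PlasmidSpec,
    nalkyl_density: float,
    spectrum: AdductSpectrum,
    params: RepairParams,
    rel_tol: float = 1e-6,
) -> float:
    """Invert :func:`analytic_dsb_fraction` for ``p_nick_open`` by bisection.

    The analytic fraction is monotone increasing in ``p_nick_open``;
    bisection converges to ``rel_tol`` relative tolerance.  Raises if the
    target exceeds the attainable maximum (at p_nick_open = 1).
    """
    if not 0.0 < target_linear_fraction < 1.0:
        if target_linear_fraction == 0.0:
            return 0.0
        raise ValueError("target must be in [0, 1)")

    def f(p: float) -> float:
        return analytic_dsb_fraction(
            plasmid, nalkyl_density, spectrum, replace(params, p_nick_open=p)
        )

    fmax = f(1.0)
    if target_linear_fraction > fmax:
        raise ValueError(
            f"target {target_linear_fraction} unreachable; attainable maximum "
            f"is {fmax:.6g} at p_nick_open=1"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > rel_tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if f(mid) < target_linear_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def batch_simulate(
    plasmid: PlasmidSpec,
    nalkyl_density: float,
    spectrum: AdductSpectrum,
    params: RepairParams,
    n: int,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    return_outcomes: bool = False,
):
    """Simulate ``n`` independent molecules and summarize topology fractions.

    Uses the same sampling kernels as :func:`~alkrepair.lesions.place_lesions`
    and :func:`simulate_repair`, driven by one seeded generator, so results
    are bit-reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= nalkyl_density <= 0.5:
        raise ValueError(f"nalkyl_density must be in [0, 0.5], got {nalkyl_density}")
    total_density = nalkyl_density / spectrum.nalkyl_fraction
    if rng is None:
        rng = np.random.default_rng(seed)
    class_cum = np.cumsum(spectrum.class_probs())
    L = plasmid.length_bp
    counts = {TOPOLOGY_CCC: 0, TOPOLOGY_OC: 0, TOPOLOGY_LINEAR: 0}
    synth_sum = 0.0
    o6_sum = 0.0
    outcomes = [] if return_outcomes else None
    for _ in range(n):
        pos, strands, classes = _sample_lesion_arrays(rng, L, total_density, class_cum)
        outcome, _detail = _repair_kernel(rng, L, pos, strands, classes, params)
        counts[outcome.topology] += 1
        synth_sum += outcome.synthesized_nt
        o6_sum += outcome.o6mg_attributed_nt
        if return_outcomes:
            outcomes.append(outcome)

    def frac_se(k: int) -> tuple[float, float]:
        f = k / n
        return f, math.sqrt(f * (1 - f) / n)

    f_ccc, se_ccc = frac_se(counts[TOPOLOGY_CCC])
    f_oc, se_oc = frac_se(counts[TOPOLOGY_OC])
    f_lin, se_lin = frac_se(counts[TOPOLOGY_LINEAR])
    mean_synth = synth_sum / n
    summary = BatchSummary(
        n_molecules=n,
        frac_ccc=f_ccc,
        frac_oc=f_oc,
        frac_linear=f_lin,
        se_ccc=se_ccc,
        se_oc=se_oc,
        se_linear=se_lin,
        n_ccc=counts[TOPOLOGY_CCC],
        n_oc=counts[TOPOLOGY_OC],
        n_linear=counts[TOPOLOGY_LINEAR],
        mean_synthesized_nt=mean_synth,
        mean_o6mg_attributed_nt=o6_sum / n,
        uds_percent_replication=100.0 * mean_synth / (2.0 * L),
    )
    if return_outcomes:
        return summary, outcomes
    return summary
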