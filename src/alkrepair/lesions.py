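"""Adduct spectra, dose calibration, and stochastic lesion placement on plasmids.

This module generates the synthetic input state for everything downstream:
given a plasmid, an alkylating-agent adduct spectrum and a per-strand
N-alkyl adduct density, it places individual lesions (7mG, 3mA, O6mG,
other) on the two strands of a circular duplex.

Conventions
-----------
* Coordinates are 0-based; intervals are half-open; circular arithmetic is
  modulo ``length_bp``.
* Densities are **per strand-nucleotide**: a plasmid of L bp exposes 2L
  strand-nucleotides.  The calibrating cleavage assay measures per-strand
  cleavage spacing, so "one adduct every 500 nt" means density 1/500 on
  each strand, i.e. 2L/500 adducts per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

TOP = 0
BOTTOM = 1
STRAND_NAMES = ("top", "bottom")

ADDUCT_7MG = 0
ADDUCT_3MA = 1
ADDUCT_O6MG = 2
ADDUCT_OTHER = 3
ADDUCT_NAMES = ("7mG", "3mA", "O6mG", "other")

#: classes converted to strand breaks by the heat/alkali cleavage assay
NALKYL_CLASSES = (ADDUCT_7MG, ADDUCT_3MA)

_IUPAC = frozenset("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base required on the lesion's own strand, by adduct class (None = any)
_REQUIRED_BASE = {ADDUCT_7MG: "G", ADDUCT_O6MG: "G", ADDUCT_3MA: "A", ADDUCT_OTHER: None}


@dataclass(frozen=True)
class PlasmidSpec:
    """A plasmid substrate.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"pBR322"``.
    length_bp : int
        Duplex length in base pairs (> 0).
    circular : bool, optional
        Covalently closed circle (default).  All built-in plasmids are
        circular.
    sequence : str, optional
        Top-strand sequence, 5'->3', IUPAC DNA.  If given, its length must
        equal ``length_bp``.
    """

    name: str
    length_bp: int
    circular: bool = True
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.length_bp:
                raise ValueError(
                    f"sequence length {len(seq)} != length_bp {self.length_bp}"
                )
            bad = set(seq) - _IUPAC
            if bad:
                raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
            object.__setattr__(self, "sequence", seq)


#: Built-in plasmid substrates (pBR322 is exactly 4363 bp, the others
#: are only known to kb precision).
BUILTIN_PLASMIDS = {
    "pAS200.2": PlasmidSpec("pAS200.2", 2100),
    "pBR322": PlasmidSpec("pBR322", 4363),
    "pAS04": PlasmidSpec("pAS04", 6500),
    "pEL97": PlasmidSpec("pEL97", 11300),
}


@dataclass(frozen=True)
class AdductSpectrum:
    """Class fractions of total alkyl adducts for one agent.

    Fractions must lie in [0, 1] and sum to 1 within 1e-9.
    """

    agent: str
    frac_7mg: float
    frac_3ma: float
    frac_o6mg: float
    frac_other: float

    def __post_init__(self) -> None:
        fracs = (self.frac_7mg, self.frac_3ma, self.frac_o6mg, self.frac_other)
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"spectrum fraction out of [0,1]: {f}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"spectrum fractions must sum to 1, got {sum(fracs)}")

    @property
    def nalkyl_fraction(self) -> float:
        """Fraction of adducts that are N-alkyl (7mG + 3mA)."""
        return self.frac_7mg + self.frac_3ma

    @property
    def n_to_o_ratio(self) -> float:
        """N-alkyl : O6mG ratio; ~10 for MNU-like agents."""
        if self.frac_o6mg == 0:
            return float("inf")
        return self.nalkyl_fraction / self.frac_o6mg

    def class_probs(self) -> np.ndarray:
        return np.array(
            [self.frac_7mg, self.frac_3ma, self.frac_o6mg, self.frac_other]
        )


_SPECTRA: dict[str, AdductSpectrum] = {
    # SN1 agent: ~70-75% 7mG, 8-12% 3mA, 8-9% O6mG
    "MNU": AdductSpectrum("MNU", 0.725, 0.10, 0.085, 0.09),
    # SN2 agent: <0.3% O6mG, similarly high N-alkyl load
    "MMS": AdductSpectrum("MMS", 0.82, 0.105, 0.003, 0.072),
    # ENU behaves like MNU in the repair-synthesis assays; same default spectrum
    "ENU": AdductSpectrum("ENU", 0.725, 0.10, 0.085, 0.09),
}


def register_spectrum(spectrum: AdductSpectrum) -> None:
    """Register a custom agent spectrum (validated by the dataclass)."""
    _SPECTRA[spectrum.agent] = spectrum


def spectrum_for_agent(agent: str) -> AdductSpectrum:
    """Return the registered adduct spectrum for ``agent``.

    Raises
    ------
    KeyError
        If ``agent`` is not registered; the message lists known agents.
    """
    try:
        return _SPECTRA[agent]
    except KeyError:
        raise KeyError(
            f"unknown agent {agent!r}; registered agents: {sorted(_SPECTRA)}"
        ) from None


@dataclass(frozen=True)
class DoseCalibration:
    """Linear dose -> N-alkyl density calibration.

    ``density_per_mM`` is N-alkyl adducts per strand-nucleotide per mM.
    The default 1/500 makes 1 mM correspond to one adduct every 500 nt
    (and 2 mM to one every 250 nt).
    """

    density_per_mM: float = 1.0 / 500.0

    def __post_init__(self) -> None:
        if self.density_per_mM <= 0:
            raise ValueError("density_per_mM must be positive")


DEFAULT_CALIBRATION = DoseCalibration()


def dose_to_density(dose_mM: float, cal: DoseCalibration = DEFAULT_CALIBRATION) -> float:
    """N-alkyl adducts per strand-nucleotide at ``dose_mM``."""
    if dose_mM < 0:
        raise ValueError(f"dose must be non-negative, got {dose_mM}")
    return dose_mM * cal.density_per_mM


@dataclass(frozen=True)
class LesionMap:
    """Adducts on one plasmid molecule.

    ``positions``, ``strands`` and ``classes`` are parallel integer arrays;
    at most one lesion per (position, strand).
    """

    plasmid: PlasmidSpec
    positions: np.ndarray
    strands: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        strands = np.asarray(self.strands, dtype=np.int8)
        classes = np.asarray(self.classes, dtype=np.int8)
        if not (pos.shape == strands.shape == classes.shape):
            raise ValueError("positions/strands/classes must have equal length")
        L = self.plasmid.length_bp
        if pos.size:
            if pos.min() < 0 or pos.max() >= L:
                raise ValueError("lesion position out of range")
            if not np.isin(strands, (TOP, BOTTOM)).all():
                raise ValueError("strand must be 0 (top) or 1 (bottom)")
            if classes.min() < 0 or classes.max() > ADDUCT_OTHER:
                raise ValueError("unknown adduct class code")
            site = strands.astype(np.int64) * L + pos
            if np.unique(site).size != site.size:
                raise ValueError("duplicate lesion at same (position, strand)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "strands", strands)
        object.__setattr__(self, "classes", classes)

    def __len__(self) -> int:
        return self.positions.size

    def __iter__(self) -> Iterator[tuple[int, str, str]]:
        for p, s, c in zip(self.positions, self.strands, self.classes):
            yield int(p), STRAND_NAMES[s], ADDUCT_NAMES[c]

    @property
    def nalkyl_mask(self) -> np.ndarray:
        return (self.classes == ADDUCT_7MG) | (self.classes == ADDUCT_3MA)

    def count(self, adduct_class: int) -> int:
        return int((self.classes == adduct_class).sum())

    @property
    def nalkyl_count(self) -> int:
        return int(self.nalkyl_mask.sum())

    def validate_sequence_compatibility(self) -> None:
        """Check base/class compatibility (sequence-aware maps only)."""
        seq = self.plasmid.sequence
        if seq is None:
            raise ValueError("plasmid has no sequence")
        bottom = seq.translate(_COMPLEMENT)
        for p, s, c in zip(self.positions, self.strands, self.classes):
            need = _REQUIRED_BASE[int(c)]
            if need is None:
                continue
            base = seq[p] if s == TOP else bottom[p]
            if base != need:
                raise ValueError(
                    f"{ADDUCT_NAMES[c]} at {STRAND_NAMES[s]}:{p} sits on {base},"
                    f" requires {need}"
                )


def _distinct_uniform(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform draws from range(n) (exact, via rejection)."""
    if k > n:
        raise ValueError(f"cannot draw {k} distinct sites from {n}")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k * k > n:  # dense regime: rejection would thrash
        return rng.permutation(n)[:k].astype(np.int64)
    while True:
        draw = rng.integers(0, n, size=k)
        uniq = np.unique(draw)
        if uniq.size == k:
            return uniq


def _sample_lesion_arrays(
    rng: np.random.Generator,
    length_bp: int,
    total_density: float,
    class_cum: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli-per-strand-nucleotide placement (binomial count + distinct sites)."""
    n_sites = 2 * length_bp
    k = int(rng.binomial(n_sites, total_density))
    sites = _distinct_uniform(rng, n_sites, k)
    strands = (sites // length_bp).astype(np.int8)
    positions = (sites % length_bp).astype(np.int64)
    classes = np.searchsorted(class_cum, rng.random(k)).astype(np.int8)
    return positions, strands, classes


def place_lesions(
    plasmid: PlasmidSpec,
    nalkyl_density: float,
    spectrum: AdductSpectrum,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    sequence_aware: bool = False,
) -> LesionMap:
    """Place adducts stochastically on both strands of a plasmid.

    Each strand-nucleotide independently carries an adduct with probability
    ``nalkyl_density / spectrum.nalkyl_fraction`` (the *total* adduct
    density); classes are drawn from the spectrum.  ``nalkyl_density`` is
    the density of cleavable N-alkyl adducts, matching what the alkaline
    cleavage assay measures.

    Parameters
    ----------
    nalkyl_density : float
        N-alkyl adducts per strand-nucleotide, in [0, 0.5].
    seed : int, optional
        Seeds a fresh generator; ignored when ``rng`` is given.
    sequence_aware : bool, optional
        Restrict classes to compatible bases (7mG/O6mG on G, 3mA on A of
        their strand) by redrawing the position; requires a sequence.
        Note this shifts local density on skewed base compositions.
    """
    if not 0.0 <= nalkyl_density <= 0.5:
        raise ValueError(f"nalkyl_density must be in [0, 0.5], got {nalkyl_density}")
    if spectrum.nalkyl_fraction <= 0:
        raise ValueError("spectrum has no N-alkyl fraction; cannot scale density")
    if sequence_aware and plasmid.sequence is None:
        raise ValueError("sequence-aware placement requires a plasmid sequence")
    total_density = nalkyl_density / spectrum.nalkyl_fraction
    if total_density > 1.0:
        raise ValueError("total adduct density exceeds 1 per strand-nucleotide")
    if rng is None:
        rng = np.random.default_rng(seed)
    class_cum = np.cumsum(spectrum.class_probs())
    positions, strands, classes = _sample_lesion_arrays(
        rng, plasmid.length_bp, total_density, class_cum
    )
    if sequence_aware and positions.size:
        positions = _reposition_for_sequence(
            rng, plasmid, positions, strands, classes
        )
    return LesionMap(plasmid, positions, strands, classes)


def _reposition_for_sequence(rng, plasmid, positions, strands, classes):
    """Redraw incompatible positions (same strand & class) until compatible."""
    seq = plasmid.sequence
    L = plasmid.length_bp
    top = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    bottom = np.frombuffer(seq.translate(_COMPLEMENT).encode(), dtype="S1").astype("U1")
    strand_bases = (top, bottom)
    for s in (TOP, BOTTOM):
        for c, need in _REQUIRED_BASE.items():
            if need is None:
                continue
            if ((strands == s) & (classes == c)).any() and need not in strand_bases[s]:
                raise ValueError(
                    f"strand {STRAND_NAMES[s]} has no {need}; cannot place "
                    f"{ADDUCT_NAMES[c]} sequence-aware"
                )
    occupied = set(zip(strands.tolist(), positions.tolist()))
    positions = positions.copy()
    for i in range(positions.size):
        need = _REQUIRED_BASE[int(classes[i])]
        if need is None:
            continue
        s = int(strands[i])
        p = int(positions[i])
        if strand_bases[s][p] == need:
            continue
        occupied.discard((s, p))
        while True:
            p = int(rng.integers(0, L))
            if strand_bases[s][p] == need and (s, p) not in occupied:
                break
        positions[i] = p
        occupied.add((s, p))
    return positions


@dataclass(frozen=True)
class ExpectedCounts:
    """Closed-form twin of :func:`place_lesions` (per-molecule means)."""

    total: float
    n_alkyl: float
    n_7mg: float
    n_3ma: float
    n_o6mg: float
    n_other: float


def expected_counts(
    plasmid: PlasmidSpec, nalkyl_density: float, spectrum: AdductSpectrum
) -> ExpectedCounts:
    """Expected per-class adduct counts per molecule.

    Expected N-alkyl count is ``2 * length_bp * nalkyl_density``; the
    expected O6mG count is the N-alkyl count divided by the spectrum's
    N:O ratio.
    """
    if not 0.0 <= nalkyl_density <= 0.5:
        raise ValueError(f"nalkyl_density must be in [0, 0.5], got {nalkyl_density}")
    if spectrum.nalkyl_fraction <= 0:
        raise ValueError("spectrum has no N-alkyl fraction; cannot scale density")
    n_alkyl = 2.0 * plasmid.length_bp * nalkyl_density
    total = n_alkyl / spectrum.nalkyl_fraction
    return ExpectedCounts(
        total=total,
        n_alkyl=n_alkyl,
        n_7mg=total * spectrum.frac_7mg,
        n_3ma=total * spectrum.frac_3ma,
        n_o6mg=total * spectrum.frac_o6mg,
        n_other=total * spectrum.frac_other,
    )
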