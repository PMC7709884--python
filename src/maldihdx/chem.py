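"""Peptide chemistry for HDX-MS: compositions, exchangeable sites, isotopic envelopes.

The central object is the *basis* of theoretical isotopic envelopes, one per
possible number of incorporated backbone-amide deuteriums k = 0..N.  Each
envelope is the natural isotope pattern of the peptide ion, rigidly shifted by
k deuterium-for-protium substitutions on the backbone, convolved with a
binomial occupancy model for the fast-exchanging side-chain/terminal sites
(which equilibrate with the quench solvent and therefore carry no structural
information).  Observed spectra are later fit as non-negative mixtures of
these basis envelopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeptideFragment",
    "ElementalComposition",
    "ExchangeSiteCounts",
    "IsotopicEnvelope",
    "composition_from_sequence",
    "count_exchange_sites",
    "natural_isotopic_distribution",
    "deuterated_envelope",
    "basis_envelopes",
    "PROTON_MASS",
    "DEUTERIUM_MASS_SHIFT",
]

# CIAAW / IUPAC standard atomic isotope masses (Da) and abundances.
# Each entry: list of (neutron offset from lightest isotope, mass, abundance).
ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177785, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.00335483507, 0.0107)],
    "N": [(0, 14.00307400443, 0.99636), (1, 15.00010889888, 0.00364)],
    "O": [
        (0, 15.99491461957, 0.99757),
        (1, 16.99913175650, 0.00038),
        (2, 17.99915961286, 0.00205),
    ],
    "S": [
        (0, 31.9720711744, 0.9499),
        (1, 32.9714589098, 0.0075),
        (2, 33.967867004, 0.0425),
        (4, 35.96708071, 0.0001),
    ],
}

PROTON_MASS = 1.00727646688
HYDROGEN_MASS = ISOTOPES["H"][0][1]
#: Mass difference between deuterium and protium (Da); one incorporated
#: deuterium shifts the envelope by exactly this amount.
DEUTERIUM_MASS_SHIFT = ISOTOPES["H"][1][1] - ISOTOPES["H"][0][1]  # 1.006277

# Residue formulas (monomer residues, i.e. amino acid minus water), CHNOS.
_RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

# Fast-exchanging (labile) side-chain hydrogens per residue, neutral forms.
# These sites re-equilibrate with the quench solvent (H:D per the run's
# solvent deuterium fraction) and are removed from the structural signal.
_SIDE_CHAIN_LABILE: dict[str, int] = {
    "R": 4, "K": 2, "H": 1, "D": 1, "E": 1, "S": 1, "T": 1,
    "N": 2, "Q": 2, "Y": 1, "W": 1, "C": 1,
}

_N_TERM_LABILE = 2  # alpha-amine
_C_TERM_LABILE = 1  # carboxyl


@dataclass(frozen=True)
class PeptideFragment:
    """A peptic peptide observed as a singly protonated MALDI ion.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence (20 standard residues).
    name : str
        Label used in reports; defaults to the sequence.
    range_start, range_end : int, optional
        1-based inclusive residue indices in the parent protein.
    charge : int
        Fixed at 1; MALDI of peptides yields predominantly singly charged ions
        and the deconvolution model assumes [M+H]+.
    """

    sequence: str
    name: str = ""
    range_start: int | None = None
    range_end: int | None = None
    charge: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in _RESIDUE_FORMULAS:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i + 1} in sequence "
                    f"{self.sequence!r}"
                )
        if self.charge != 1:
            raise ValueError("only singly charged (charge=1) ions are supported")
        if (self.range_start is None) != (self.range_end is None):
            raise ValueError("range_start and range_end must be given together")
        if self.range_start is not None:
            span = self.range_end - self.range_start + 1
            if span != len(self.sequence):
                raise ValueError(
                    f"residue range {self.range_start}-{self.range_end} spans "
                    f"{span} residues but sequence has {len(self.sequence)}"
                )
        if not self.name:
            object.__setattr__(self, "name", self.sequence)


@dataclass(frozen=True)
class ElementalComposition:
    """CHNOS atom counts of a neutral peptide."""

    C: int
    H: int
    N: int
    O: int
    S: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "S"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ("C", "H", "N", "O", "S")}

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass (all-light isotopologue), Da."""
        return sum(
            n * ISOTOPES[el][0][1] for el, n in self.as_dict().items() if n
        )

    def replace(self, **changes: int) -> "ElementalComposition":
        d = self.as_dict()
        d.update(changes)
        return ElementalComposition(**d)


@dataclass(frozen=True)
class ExchangeSiteCounts:
    """Partition of a peptide's hydrogens by exchange behaviour.

    ``n_amide`` backbone amide hydrogens carry the HDX signal; ``n_side``
    side-chain and terminal hydrogens exchange completely during the acid
    quench and are modelled as solvent-equilibrated; ``n_fixed`` carbon-bound
    hydrogens never exchange.  Counts refer to the neutral peptide; the
    ionizing proton is accounted for separately.
    """

    n_amide: int
    n_side: int
    n_fixed: int

    def __post_init__(self) -> None:
        if min(self.n_amide, self.n_side, self.n_fixed) < 0:
            raise ValueError("site counts must be non-negative")


def composition_from_sequence(fragment: PeptideFragment) -> ElementalComposition:
    """Elemental composition of the neutral peptide: residue formulas + H2O."""
    c = h = n = o = s = 0
    for aa in fragment.sequence:
        dc, dh, dn, do, ds = _RESIDUE_FORMULAS[aa]
        c += dc
        h += dh
        n += dn
        o += do
        s += ds
    return ElementalComposition(C=c, H=h + 2, N=n, O=o + 1, S=s)


def count_exchange_sites(fragment: PeptideFragment) -> ExchangeSiteCounts:
    """Count exchangeable sites of a peptide.

    Backbone amides: one per peptide bond, minus prolines (whose backbone
    nitrogen carries no hydrogen); the N-terminal residue has an amine, not an
    amide.  Labile side-chain counts follow standard HDX practice for neutral
    side chains, plus 2 for the N-terminal amine and 1 for the C-terminal
    carboxyl.
    """
    seq = fragment.sequence
    n_amide = len(seq) - 1 - sum(1 for aa in seq[1:] if aa == "P")
    n_side = (
        sum(_SIDE_CHAIN_LABILE.get(aa, 0) for aa in seq)
        + _N_TERM_LABILE
        + _C_TERM_LABILE
    )
    total_h = composition_from_sequence(fragment).H
    n_fixed = total_h - n_amide - n_side
    return ExchangeSiteCounts(n_amide=n_amide, n_side=n_side, n_fixed=n_fixed)


@dataclass(frozen=True)
class IsotopicEnvelope:
    """Normalized isotopic envelope: peaks at ~1 Da spacing.

    ``mz`` holds the abundance-weighted mean mass of each nominal-mass bin;
    ``nominal`` the bin index (neutrons + deuteriums beyond the all-light
    species), used to align envelopes on a common grid.
    """

    mz: np.ndarray
    abundance: np.ndarray
    nominal: np.ndarray
    species_label: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        ab = np.asarray(self.abundance, dtype=float)
        nom = np.asarray(self.nominal, dtype=int)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "abundance", ab)
        object.__setattr__(self, "nominal", nom)
        if not (len(mz) == len(ab) == len(nom)):
            raise ValueError("mz, abundance, nominal must have equal length")
        if len(mz) == 0:
            raise ValueError("empty envelope")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 within 1e-9")

    @property
    def centroid(self) -> float:
        """Abundance-weighted mean mass, Da."""
        return float(np.dot(self.mz, self.abundance))

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.abundance.tolist()))


# ---------------------------------------------------------------------------
# Convolution engine.  A distribution is a dict: nominal bin -> (probability,
# probability-weighted mass).  Bin masses therefore stay exact weighted means
# under convolution, which merges the fine isotopic structure the way a
# reflectron-TOF instrument does.
# ---------------------------------------------------------------------------

_Dist = dict[int, tuple[float, float]]

_CONV_PRUNE = 0.0  # binning keeps dists small; keep all non-underflowed terms


def _element_dist(element: str) -> _Dist:
    return {off: (p, p * m) for off, m, p in ISOTOPES[element]}


def _convolve(a: _Dist, b: _Dist) -> _Dist:
    out: _Dist = {}
    for i, (pa, wa) in a.items():
        ma = wa / pa
        for j, (pb, wb) in b.items():
            p = pa * pb
            if p <= _CONV_PRUNE:
                continue
            mass = ma + wb / pb
            key = i + j
            p0, w0 = out.get(key, (0.0, 0.0))
            out[key] = (p0 + p, w0 + p * mass)
    return out


def _dist_power(base: _Dist, n: int) -> _Dist:
    """n-fold self-convolution by binary exponentiation."""
    result: _Dist = {0: (1.0, 0.0)}
    sq = base
    while n:
        if n & 1:
            result = _convolve(result, sq)
        n >>= 1
        if n:
            sq = _convolve(sq, sq)
    return result


def _formula_dist(composition: ElementalComposition) -> _Dist:
    dist: _Dist = {0: (1.0, 0.0)}
    for el, count in composition.as_dict().items():
        if count:
            dist = _convolve(dist, _dist_power(_element_dist(el), count))
    return dist


def _dist_to_envelope(
    dist: _Dist,
    prune_threshold: float,
    label: str,
    mass_offset: float = 0.0,
    nominal_offset: int = 0,
) -> IsotopicEnvelope:
    """Trim tail bins below threshold, renormalize, emit sorted envelope."""
    keys = sorted(dist)
    probs = np.array([dist[k][0] for k in keys])
    # trim only leading/trailing sub-threshold bins so spacing stays ~1 Da
    keep = probs >= prune_threshold if prune_threshold > 0 else probs > 0
    if not keep.any():
        raise ValueError("prune threshold removed every peak")
    lo, hi = np.flatnonzero(keep)[[0, -1]]
    keys = keys[lo : hi + 1]
    probs = probs[lo : hi + 1]
    masses = np.array([dist[k][1] / dist[k][0] for k in keys]) + mass_offset
    probs = probs / probs.sum()
    return IsotopicEnvelope(
        mz=masses,
        abundance=probs,
        nominal=np.asarray(keys, dtype=int) + nominal_offset,
        species_label=label,
    )


def natural_isotopic_distribution(
    composition: ElementalComposition,
    prune_threshold: float = 1e-6,
) -> IsotopicEnvelope:
    """Natural isotope pattern of a neutral composition.

    Computed by iterative convolution of elemental isotope patterns,
    aggregated into nominal-mass bins (nearest-integer neutron count); each
    bin's reported m/z is the abundance-weighted mean mass of its
    isotopologues.  Bins below ``prune_threshold`` are trimmed from the tails
    and the envelope renormalized.
    """
    if not (0 <= prune_threshold < 1e-3):
        raise ValueError("prune_threshold must be in [0, 1e-3)")
    if all(v == 0 for v in composition.as_dict().values()):
        raise ValueError("empty composition")
    return _dist_to_envelope(
        _formula_dist(composition), prune_threshold, label="natural"
    )


def _binomial_dist(n: int, p: float) -> _Dist:
    """Side-chain deuterium occupancy: j of n labile sites carry D.

    Mass contribution per site: protium restores the stripped hydrogen; a
    deuterium adds the D-H shift on top.
    """
    out: _Dist = {}
    for j in range(n + 1):
        pj = math.comb(n, j) * p**j * (1 - p) ** (n - j)
        if pj < _CONV_PRUNE:
            continue
        mass = n * HYDROGEN_MASS + j * DEUTERIUM_MASS_SHIFT
        out[j] = (pj, pj * mass)
    return out


def peptide_base_envelope(
    fragment: PeptideFragment,
    sites: ExchangeSiteCounts | None = None,
    prune_threshold: float = 1e-6,
) -> IsotopicEnvelope:
    """Envelope of [M+H]+ with the labile side-chain hydrogens stripped.

    The ionizing proton (1.007276 Da) is added once as a non-exchanging mass
    offset; side-chain sites are restored later by the binomial occupancy
    convolution.
    """
    if sites is None:
        sites = count_exchange_sites(fragment)
    comp = composition_from_sequence(fragment)
    stripped = comp.replace(H=comp.H - sites.n_side)
    return _dist_to_envelope(
        _formula_dist(stripped),
        prune_threshold,
        label=f"{fragment.name} base",
        mass_offset=PROTON_MASS,
    )


def deuterated_envelope(
    base: IsotopicEnvelope,
    k_amide_D: int,
    sites: ExchangeSiteCounts,
    solvent_D_fraction: float = 0.9,
    prune_threshold: float = 1e-6,
) -> IsotopicEnvelope:
    """Envelope of the species carrying exactly ``k_amide_D`` backbone deuteriums.

    The stripped base envelope is rigidly shifted by k x 1.006277 Da (k amide
    protiums replaced by deuterium), then convolved with the
    binomial(n_side, solvent_D_fraction) side-chain occupancy distribution so
    that the mixture index k counts only backbone amide deuteriums.
    """
    if not 0 <= k_amide_D <= sites.n_amide:
        raise ValueError(
            f"k_amide_D={k_amide_D} outside [0, n_amide={sites.n_amide}]"
        )
    if not 0 < solvent_D_fraction <= 1:
        raise ValueError("solvent_D_fraction must be in (0, 1]")
    shift = k_amide_D * DEUTERIUM_MASS_SHIFT
    dist: _Dist = {
        int(nom): (p, p * (m + shift))
        for nom, m, p in zip(base.nominal, base.mz, base.abundance)
    }
    if sites.n_side:
        dist = _convolve(dist, _binomial_dist(sites.n_side, solvent_D_fraction))
    return _dist_to_envelope(
        dist,
        prune_threshold,
        label=f"k={k_amide_D}",
        nominal_offset=k_amide_D,
    )


def basis_envelopes(
    fragment: PeptideFragment,
    solvent_D_fraction: float = 0.9,
    prune_threshold: float = 1e-6,
) -> list[IsotopicEnvelope]:
    """One envelope per amide deuterium count k = 0..n_amide, on a common grid.

    The common grid is the union of the components' nominal-mass bins; each
    grid bin's m/z is the abundance-weighted mean mass across components, and
    components are zero-padded onto it.
    """
    sites = count_exchange_sites(fragment)
    base = peptide_base_envelope(fragment, sites, prune_threshold)
    comps = [
        deuterated_envelope(base, k, sites, solvent_D_fraction, prune_threshold)
        for k in range(sites.n_amide + 1)
    ]
    all_bins = sorted(set().union(*(set(e.nominal.tolist()) for e in comps)))
    index = {b: i for i, b in enumerate(all_bins)}
    n_bins = len(all_bins)
    ab = np.zeros((len(comps), n_bins))
    wmass = np.zeros(n_bins)
    for ci, env in enumerate(comps):
        for nom, m, p in zip(env.nominal, env.mz, env.abundance):
            j = index[int(nom)]
            ab[ci, j] += p
            wmass[j] += p * m
    tot = ab.sum(axis=0)
    # grid m/z: abundance-weighted mean over components sharing a bin
    grid_mz = np.where(tot > 0, wmass / np.maximum(tot, 1e-300), 0.0)
    # fill any all-zero bin (cannot occur with contiguous envelopes) by spacing
    nominal = np.asarray(all_bins, dtype=int)
    return [
        IsotopicEnvelope(
            mz=grid_mz,
            abundance=ab[ci] / ab[ci].sum(),
            nominal=nominal,
            species_label=f"{fragment.name} k={ci}",
        )
        for ci in range(len(comps))
    ]
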